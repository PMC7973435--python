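"""Item response theory core: guess-floored logistic models.

Implements the two dichotomous models used for lexical-decision data, where
chance performance on a two-alternative forced choice fixes the lower
asymptote at c = 0.5:

* ``rasch_g`` — one common discrimination (slope) shared by all items, a
  per-item difficulty ``b``, and a fixed guessing floor ``c``.
* ``twopl_g`` — per-item discrimination ``a`` and difficulty ``b``, fixed
  guessing floor ``c``.

Estimation is marginal maximum likelihood via the EM algorithm on a fixed
quadrature grid (Bock–Aitkin), with a standard-normal latent prior.  Ability
is recovered by expected-a-posteriori (EAP) scoring on the same grid.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("lexirt")

__all__ = [
    "FittedModel",
    "AbilityEstimates",
    "irf",
    "item_information",
    "test_information",
    "fit_model",
    "estimate_abilities",
    "fit_statistics",
    "marginal_reliability",
    "marginal_loglik",
    "response_matrix",
]

# Parameter boxes: keep quasi-degenerate items finite rather than dropping them.
A_BOUNDS = (0.05, 5.0)
B_BOUNDS = (-8.0, 8.0)
# Dense reference grid used for the reported marginal log-likelihood.
DENSE_NODES = 2001
DENSE_RANGE = (-8.0, 8.0)


def irf(theta, a, b, c=0.5):
    """Guess-floored logistic item response function.

    P(correct) = c + (1 - c) / (1 + exp(-a (theta - b))).

    Broadcasts over array inputs.  With ``a = 0`` the item is flat at the
    midpoint ``c + (1 - c)/2``.
    """
    theta = np.asarray(theta, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    z = a * (theta - b)
    p = 1.0 / (1.0 + np.exp(-z))
    return c + (1.0 - c) * p


def item_information(a, b, c, theta):
    """Fisher information of one item at ability ``theta`` (logits^-2).

    I(theta) = a^2 * ((P - c) / (1 - c))^2 * (1 - P) / P, the standard form
    for the guess-floored logistic.  At theta = b with c = 0.5 this reduces
    to a^2 / 12.
    """
    a = np.asarray(a, dtype=float)
    P = irf(theta, a, b, c)
    pstar = (P - c) / (1.0 - c)
    return a**2 * pstar**2 * (1.0 - P) / P


def _quad_grid(n_nodes, lo, hi, prior_mean=0.0, prior_sd=1.0):
    nodes = np.linspace(lo, hi, n_nodes)
    w = np.exp(-0.5 * ((nodes - prior_mean) / prior_sd) ** 2)
    return nodes, w / w.sum()


def response_matrix(responses: pd.DataFrame):
    """Pivot a long response table to a persons x items 0/1 matrix.

    Returns ``(X, mask, person_ids, item_ids)`` where ``X`` holds 0/1 with
    zeros at unobserved cells and ``mask`` flags observed cells.
    """
    pivot = responses.pivot(index="person_id", columns="item_id", values="correct")
    mask = pivot.notna().to_numpy()
    X = pivot.fillna(0).to_numpy(dtype=float)
    return X, mask, pivot.index.to_numpy(), pivot.columns.to_numpy()


@dataclass
class FittedModel:
    """Estimated item parameters plus estimation metadata."""

    model_kind: str
    item_ids: np.ndarray
    a: np.ndarray
    b: np.ndarray
    c_fixed: float
    prior_mean: float
    prior_sd: float
    n_nodes: int
    node_range: tuple
    loglik: float
    loglik_path: list = field(default_factory=list, repr=False)
    n_iterations: int = 0
    converged: bool = True
    bounded_items: list = field(default_factory=list)

    def __post_init__(self):
        self.item_ids = np.asarray(self.item_ids)
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)

    @classmethod
    def from_parameters(cls, item_ids, a, b, c_fixed=0.5, prior_mean=0.0,
                        prior_sd=1.0, n_nodes=61, node_range=(-6.0, 6.0),
                        model_kind="twopl_g"):
        """Build a model object from known parameters (no estimation)."""
        a = np.broadcast_to(np.asarray(a, dtype=float), (len(item_ids),)).copy()
        return cls(model_kind=model_kind, item_ids=np.asarray(item_ids), a=a,
                   b=np.asarray(b, dtype=float), c_fixed=c_fixed,
                   prior_mean=prior_mean, prior_sd=prior_sd, n_nodes=n_nodes,
                   node_range=tuple(node_range), loglik=np.nan)

    def grid(self):
        return _quad_grid(self.n_nodes, *self.node_range, self.prior_mean, self.prior_sd)

    def item_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "item_id": self.item_ids,
            "a_hat": self.a,
            "b_hat": self.b,
            "c_fixed": self.c_fixed,
            "bounded": np.isin(self.item_ids, self.bounded_items),
        })

    def subset(self, item_ids) -> "FittedModel":
        idx = pd.Index(self.item_ids).get_indexer(np.asarray(item_ids))
        if (idx < 0).any():
            raise KeyError("unknown item ids in subset request")
        sub = FittedModel.from_parameters(
            np.asarray(item_ids), self.a[idx], self.b[idx], self.c_fixed,
            self.prior_mean, self.prior_sd, self.n_nodes, self.node_range,
            model_kind=self.model_kind)
        return sub

    def to_json(self, path=None):
        obj = {
            "model_kind": self.model_kind,
            "c_fixed": self.c_fixed,
            "prior": {"mean": self.prior_mean, "sd": self.prior_sd},
            "quadrature": {"nodes": self.n_nodes, "range": list(self.node_range)},
            "loglik": None if np.isnan(self.loglik) else self.loglik,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "bounded_items": list(map(str, self.bounded_items)),
            "items": [
                {"item_id": str(i), "a_hat": float(a), "b_hat": float(b)}
                for i, a, b in zip(self.item_ids, self.a, self.b)
            ],
        }
        text = json.dumps(obj, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source):
        if isinstance(source, str) and source.lstrip().startswith("{"):
            obj = json.loads(source)
        else:
            with open(source) as fh:
                obj = json.load(fh)
        items = obj["items"]
        model = cls(
            model_kind=obj["model_kind"],
            item_ids=np.array([it["item_id"] for it in items]),
            a=np.array([it["a_hat"] for it in items]),
            b=np.array([it["b_hat"] for it in items]),
            c_fixed=obj["c_fixed"],
            prior_mean=obj["prior"]["mean"],
            prior_sd=obj["prior"]["sd"],
            n_nodes=obj["quadrature"]["nodes"],
            node_range=tuple(obj["quadrature"]["range"]),
            loglik=np.nan if obj["loglik"] is None else obj["loglik"],
            n_iterations=obj["n_iterations"],
            converged=obj["converged"],
            bounded_items=obj["bounded_items"],
        )
        return model


@dataclass
class AbilityEstimates:
    """Per-person latent ability estimates."""

    table: pd.DataFrame  # person_id, theta_hat, se_theta
    method: str = "EAP"

    def series(self) -> pd.Series:
        return self.table.set_index("person_id")["theta_hat"]


def marginal_loglik(X, mask, a, b, c, nodes, weights):
    """Marginal log-likelihood of a 0/1 response matrix on a quadrature grid.

    The latent density is the (normalized) prior weight at each node; the
    integral is the weighted sum over nodes of the conditional likelihood.
    """
    P = irf(nodes[None, :], np.asarray(a)[:, None], np.asarray(b)[:, None], c)  # J x K
    P = np.clip(P, 1e-12, 1 - 1e-12)
    logP = np.log(P)
    log1P = np.log1p(-P)
    Xm = X * mask
    X1m = (1.0 - X) * mask
    LL = Xm @ logP + X1m @ log1P  # N x K
    LW = LL + np.log(weights)[None, :]
    m = LW.max(axis=1, keepdims=True)
    return float((np.log(np.exp(LW - m).sum(axis=1)) + m[:, 0]).sum())


def _q_per_item(a, b, c, nodes, r_jk, n_jk):
    """Expected complete-data log-likelihood, one value per item."""
    P = irf(nodes[None, :], np.asarray(a)[:, None], np.asarray(b)[:, None], c)
    P = np.clip(P, 1e-12, 1 - 1e-12)
    return (r_jk * np.log(P) + (n_jk - r_jk) * np.log1p(-P)).sum(axis=1)


def _grad_per_item(a, b, c, nodes, r_jk, n_jk, wrt):
    """Analytic gradient of the per-item expected log-likelihood."""
    a = np.asarray(a, dtype=float)[:, None]
    b = np.asarray(b, dtype=float)[:, None]
    th = nodes[None, :]
    p = 1.0 / (1.0 + np.exp(-a * (th - b)))
    P = np.clip(c + (1.0 - c) * p, 1e-12, 1 - 1e-12)
    core = r_jk / P - (n_jk - r_jk) / (1.0 - P)
    pq = (1.0 - c) * p * (1.0 - p)
    if wrt == "b":
        dP = -a * pq
    else:  # "a"
        dP = (th - b) * pq
    return (core * dP).sum(axis=1)


def _newton_coord(a, b, c, nodes, r_jk, n_jk, wrt, bounds, n_steps=4):
    """Safeguarded per-item Newton ascent on one parameter vector.

    Vectorized across items; backtracks until the per-item objective does not
    decrease, so the enclosing EM is a generalized EM with a monotone
    marginal likelihood.
    """
    lo, hi = bounds
    x = (b if wrt == "b" else a).copy()

    def qv(xv):
        if wrt == "b":
            return _q_per_item(a, xv, c, nodes, r_jk, n_jk)
        return _q_per_item(xv, b, c, nodes, r_jk, n_jk)

    def gv(xv):
        if wrt == "b":
            return _grad_per_item(a, xv, c, nodes, r_jk, n_jk, "b")
        return _grad_per_item(xv, b, c, nodes, r_jk, n_jk, "a")

    h = 1e-5
    for _ in range(n_steps):
        g = gv(x)
        H = (gv(x + h) - gv(x - h)) / (2 * h)
        step = np.where(H < -1e-10, -g / np.where(H < -1e-10, H, -1.0),
                        np.sign(g) * 0.25)
        step = np.clip(step, -1.5, 1.5)
        q0 = qv(x)
        xn = np.clip(x + step, lo, hi)
        for _bt in range(12):
            qn = qv(xn)
            bad = qn < q0 - 1e-12
            if not bad.any():
                break
            step = np.where(bad, step * 0.5, step)
            xn = np.where(bad, np.clip(x + step, lo, hi), xn)
        qn = qv(xn)
        x = np.where(qn >= q0, xn, x)
    return x


def fit_model(responses: pd.DataFrame, model_kind: str = "rasch_g",
              c_fixed: float = 0.5, quadrature_nodes: int = 61,
              node_range: tuple = (-6.0, 6.0), prior_mean: float = 0.0,
              prior_sd: float = 1.0, tol: float = 1e-4,
              max_iter: int = 500) -> FittedModel:
    """Fit a guess-floored Rasch or 2PL model by marginal maximum likelihood.

    EM over a fixed quadrature grid with a Normal(prior_mean, prior_sd)
    latent density.  Convergence when the largest absolute parameter change
    falls below ``tol``.  Items driven to a parameter bound (e.g. answered
    correctly by everyone) are flagged in ``bounded_items``.

    The reported ``loglik`` is recomputed on a dense reference grid
    (2001 nodes on [-8, 8]) at the returned parameters; ``loglik_path``
    holds the per-iteration values on the fitting grid.
    """
    if model_kind not in ("rasch_g", "twopl_g"):
        raise ValueError(f"unknown model kind: {model_kind!r}")
    vals = responses["correct"].to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("responses must be coded 0/1")
    X, mask, person_ids, item_ids = response_matrix(responses)
    N, J = X.shape
    if N < 2 or J < 2:
        raise ValueError("need at least 2 persons and 2 items")
    if (mask.sum(axis=0) < 1).any():
        raise ValueError("every item needs at least one observed response")
    overlap = (mask[:, None, :] & mask[None, :, :]).sum(axis=2) if N <= 200 else None
    if overlap is not None and N > 1:
        off = overlap[~np.eye(N, dtype=bool)]
        if off.size and off.max() < 2:
            logger.warning("persons share <2 common items; estimates may be unidentified")

    nodes, weights = _quad_grid(quadrature_nodes, *node_range, prior_mean, prior_sd)

    # Moment-based starting values from corrected proportions correct.
    p_obs = (X * mask).sum(axis=0) / mask.sum(axis=0)
    p_adj = np.clip((p_obs - c_fixed) / (1.0 - c_fixed), 1e-3, 1 - 1e-3)
    b = np.clip(-np.log(p_adj / (1.0 - p_adj)), *B_BOUNDS)
    a = np.ones(J)

    Xm = X * mask
    X1m = (1.0 - X) * mask
    logw = np.log(weights)

    loglik_path = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step
        P = irf(nodes[None, :], a[:, None], b[:, None], c_fixed)
        P = np.clip(P, 1e-12, 1 - 1e-12)
        LL = Xm @ np.log(P) + X1m @ np.log1p(-P)
        LW = LL + logw[None, :]
        m = LW.max(axis=1, keepdims=True)
        post = np.exp(LW - m)
        norm = post.sum(axis=1, keepdims=True)
        loglik_path.append(float((np.log(norm[:, 0]) + m[:, 0]).sum()))
        post /= norm
        n_jk = mask.T.astype(float) @ post
        r_jk = Xm.T @ post

        a_old, b_old = a.copy(), b.copy()
        # M-step
        b = _newton_coord(a, b, c_fixed, nodes, r_jk, n_jk, "b", B_BOUNDS)
        if model_kind == "twopl_g":
            a = _newton_coord(a, b, c_fixed, nodes, r_jk, n_jk, "a", A_BOUNDS)
        else:
            # common slope: 1-d safeguarded Newton on the summed objective
            def qa(av):
                return _q_per_item(np.full(J, av), b, c_fixed, nodes, r_jk, n_jk).sum()

            def ga(av):
                return _grad_per_item(np.full(J, av), b, c_fixed, nodes, r_jk,
                                      n_jk, "a").sum()

            x = a[0]
            for _ in range(4):
                g = ga(x)
                H = (ga(x + 1e-5) - ga(x - 1e-5)) / 2e-5
                step = -g / H if H < -1e-10 else np.sign(g) * 0.1
                step = float(np.clip(step, -1.0, 1.0))
                q0 = qa(x)
                xn = float(np.clip(x + step, *A_BOUNDS))
                for _bt in range(12):
                    if qa(xn) >= q0 - 1e-12:
                        break
                    step *= 0.5
                    xn = float(np.clip(x + step, *A_BOUNDS))
                if qa(xn) >= q0:
                    x = xn
            a = np.full(J, x)

        delta = max(np.abs(a - a_old).max(), np.abs(b - b_old).max())
        if delta < tol:
            converged = True
            break

    if not converged:
        logger.warning("EM did not converge in %d iterations (last change tracked)", max_iter)

    bounded = [str(i) for i, bb, aa in zip(item_ids, b, a)
               if bb <= B_BOUNDS[0] + 1e-6 or bb >= B_BOUNDS[1] - 1e-6
               or aa <= A_BOUNDS[0] + 1e-6 or aa >= A_BOUNDS[1] - 1e-6]
    if bounded:
        logger.info("%d item(s) at parameter bounds: %s", len(bounded), bounded[:10])

    dn, dw = _quad_grid(DENSE_NODES, *DENSE_RANGE, prior_mean, prior_sd)
    loglik = marginal_loglik(X, mask, a, b, c_fixed, dn, dw)

    return FittedModel(
        model_kind=model_kind, item_ids=item_ids, a=a, b=b, c_fixed=c_fixed,
        prior_mean=prior_mean, prior_sd=prior_sd, n_nodes=quadrature_nodes,
        node_range=tuple(node_range), loglik=loglik, loglik_path=loglik_path,
        n_iterations=it, converged=converged, bounded_items=bounded)


def estimate_abilities(model: FittedModel, responses: pd.DataFrame,
                       method: str = "EAP") -> AbilityEstimates:
    """Score persons on the model's quadrature grid.

    EAP: posterior mean and sd under the latent prior.  ML (diagnostics
    only): grid argmax of the conditional likelihood; its ``se_theta`` is
    the curvature-based approximation and is unreliable for extreme scores.
    Persons with zero scored trials get no row (logged).
    """
    resp = responses[responses["item_id"].isin(model.item_ids)]
    dropped = responses.loc[~responses["item_id"].isin(model.item_ids), "item_id"].unique()
    if len(dropped):
        logger.info("ignoring %d items absent from the model", len(dropped))
    if resp.empty:
        raise ValueError("no responses overlap the model's items")
    X, mask, person_ids, item_ids = response_matrix(resp)
    idx = pd.Index(model.item_ids).get_indexer(item_ids)
    a, b = model.a[idx], model.b[idx]
    nodes, weights = model.grid()
    P = np.clip(irf(nodes[None, :], a[:, None], b[:, None], model.c_fixed),
                1e-12, 1 - 1e-12)
    LL = (X * mask) @ np.log(P) + ((1 - X) * mask) @ np.log1p(-P)
    n_used = mask.sum(axis=1)
    if method == "EAP":
        LW = LL + np.log(weights)[None, :]
    elif method == "ML":
        LW = LL
    else:
        raise ValueError(f"unknown scoring method: {method!r}")
    m = LW.max(axis=1, keepdims=True)
    post = np.exp(LW - m)
    post /= post.sum(axis=1, keepdims=True)
    theta_hat = post @ nodes
    var = post @ nodes**2 - theta_hat**2
    se = np.sqrt(np.clip(var, 0, None))
    if method == "ML":
        theta_hat = nodes[np.argmax(LL, axis=1)]
    keep = n_used > 0
    if (~keep).any():
        logger.warning("%d person(s) had zero scored trials; no estimate", int((~keep).sum()))
    table = pd.DataFrame({
        "person_id": person_ids[keep],
        "theta_hat": theta_hat[keep],
        "se_theta": se[keep],
        "n_items": n_used[keep],
    })
    return AbilityEstimates(table=table, method=method)


def fit_statistics(model: FittedModel, responses: pd.DataFrame,
                   abilities: AbilityEstimates, eps: float = 1e-6) -> pd.DataFrame:
    """Infit and outfit mean-square item-fit statistics.

    With standardized residual z = (x - P) / sqrt(P (1 - P)) at the person's
    point ability estimate:

    * outfit_j = mean(z^2) over the item's responses (unweighted);
    * infit_j  = sum((x - P)^2) / sum(P (1 - P)) (information weighted).

    Both have expectation 1 under the fitted model.  ``P`` uses the
    guess-floored response function and is clipped away from 0/1.
    """
    theta = abilities.series()
    resp = responses[responses["person_id"].isin(theta.index)
                     & responses["item_id"].isin(model.item_ids)].copy()
    missing = responses.loc[~responses["person_id"].isin(theta.index), "person_id"].nunique()
    if missing:
        logger.warning("fit statistics skip %d person(s) without ability estimates", missing)
    par = pd.DataFrame({"a": model.a, "b": model.b}, index=model.item_ids)
    th = theta.loc[resp["person_id"]].to_numpy()
    aj = par.loc[resp["item_id"], "a"].to_numpy()
    bj = par.loc[resp["item_id"], "b"].to_numpy()
    P = irf(th, aj, bj, model.c_fixed)
    clipped = (P < eps) | (P > 1 - eps)
    if clipped.any():
        logger.info("clipping %d response probabilities away from 0/1", int(clipped.sum()))
        P = np.clip(P, eps, 1 - eps)
    x = resp["correct"].to_numpy(dtype=float)
    res2 = (x - P) ** 2
    v = P * (1 - P)
    frame = pd.DataFrame({"item_id": resp["item_id"].to_numpy(),
                          "res2": res2, "z2": res2 / v, "v": v})
    g = frame.groupby("item_id", sort=False)
    out = pd.DataFrame({
        "outfit": g["z2"].mean(),
        "infit": g["res2"].sum() / g["v"].sum(),
        "n_responses_used": g.size(),
    }).reset_index()
    return out.set_index("item_id").loc[
        [i for i in model.item_ids if i in set(out["item_id"])]].reset_index()


def test_information(model: FittedModel, theta_grid, item_ids=None) -> pd.DataFrame:
    """Test information curve: pointwise sum of item informations."""
    theta_grid = np.asarray(theta_grid, dtype=float)
    if item_ids is None:
        a, b = model.a, model.b
    else:
        sub = model.subset(item_ids)
        a, b = sub.a, sub.b
    if len(a) == 0:
        info = np.zeros_like(theta_grid)
    else:
        info = item_information(a[:, None], b[:, None], model.c_fixed,
                                theta_grid[None, :]).sum(axis=0)
    return pd.DataFrame({"theta": theta_grid, "information": info})


def marginal_reliability(model: FittedModel, abilities: AbilityEstimates) -> float:
    """EAP marginal reliability: var(theta_hat) / (var(theta_hat) + mean(se^2)).

    The denominator estimates total latent variance (signal plus posterior
    uncertainty), so the value lies in [0, 1]; degenerate inputs clip with a
    warning.
    """
    t = abilities.table
    if len(t) < 2:
        raise ValueError("need at least 2 persons for reliability")
    v = float(np.var(t["theta_hat"], ddof=1))
    e = float(np.mean(t["se_theta"] ** 2))
    if v + e <= 0:
        logger.warning("zero ability variance; reliability undefined, returning 0")
        return 0.0
    rel = v / (v + e)
    if not 0.0 <= rel <= 1.0:
        logger.warning("reliability %.3f clipped into [0, 1]", rel)
        rel = min(max(rel, 0.0), 1.0)
    return rel
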