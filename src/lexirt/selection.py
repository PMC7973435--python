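"""Item-optimization pipeline and difficulty-equated form assembly.

The pipeline mirrors the four-stage construction of short, parallel
lexical-decision test forms from a large calibration bank:

1. **Correlation screen** — drop items whose correct/incorrect vector fails
   a lenient threshold (r <= 0.10) against overall test accuracy or the
   external criterion score.
2. **Rasch fit pruning** — iteratively fit the guess-floored Rasch model and
   drop items with infit or outfit outside [0.6, 1.4] until all survive.
3. **Discrimination pruning** — fit the guess-floored 2PL and drop items
   with slope a < 0.7.
4. **Assembly** — partition the survivors into class-balanced lists equated
   on Rasch difficulty (and length), spanning the full difficulty range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .irt import (FittedModel, estimate_abilities, fit_model, fit_statistics,
                  item_information, test_information)

logger = logging.getLogger("lexirt")

__all__ = [
    "SelectionReport",
    "StimulusLists",
    "PipelineResult",
    "ListEvaluation",
    "PipelineError",
    "step1_screen",
    "step2_rasch_prune",
    "step3_discrimination_prune",
    "run_selection_pipeline",
    "assemble_lists",
    "augment_lists",
    "evaluate_lists",
]


class PipelineError(RuntimeError):
    """A selection stage could not proceed (e.g. all items removed)."""


@dataclass
class SelectionReport:
    """Ledger of one selection step: who was removed, why, and with what statistic."""

    step_label: str
    removed: list  # (item_id, reason, statistic)
    retained: list  # item_id
    thresholds: dict
    n_iterations: int = 1
    model: FittedModel | None = field(default=None, repr=False)

    def __post_init__(self):
        overlap = set(self.removed_ids) & set(self.retained)
        if overlap:
            raise ValueError(f"items both removed and retained: {sorted(overlap)[:5]}")

    @property
    def removed_ids(self):
        return [r[0] for r in self.removed]

    def to_dict(self) -> dict:
        return {
            "step_label": self.step_label,
            "n_removed": len(self.removed),
            "n_retained": len(self.retained),
            "n_iterations": self.n_iterations,
            "thresholds": self.thresholds,
            "removed": [
                {"item_id": str(i), "reason": r,
                 "statistic": None if s is None or (isinstance(s, float) and np.isnan(s))
                 else float(s)}
                for i, r, s in self.removed
            ],
            "retained": [str(i) for i in self.retained],
        }


def _masked_pearson(x, y):
    """Pearson r over pairwise-complete entries; nan when degenerate."""
    m = ~(np.isnan(x) | np.isnan(y))
    if m.sum() < 3:
        return np.nan
    xs, ys = x[m], y[m]
    if xs.std() == 0 or ys.std() == 0:
        return np.nan
    return float(np.corrcoef(xs, ys)[0, 1])


def step1_screen(responses: pd.DataFrame, criterion: pd.Series,
                 r_threshold: float = 0.10, rule: str = "either",
                 corrected_total: bool = False) -> SelectionReport:
    """Correlation screen against total accuracy and the criterion score.

    ``rule='either'`` (default) removes an item when *either* correlation
    fails to exceed ``r_threshold`` — i.e. an item must be predictive of
    both overall performance and the criterion to survive.  ``rule='both'``
    removes only items failing both.  The total score is the proportion
    correct on the full input item set (``corrected_total=True`` subtracts
    the item itself).  Zero-variance items are removed as ``degenerate``.
    """
    if rule not in ("either", "both"):
        raise ValueError("rule must be 'either' or 'both'")
    pivot = responses.pivot(index="person_id", columns="item_id", values="correct")
    X = pivot.to_numpy(dtype=float)
    total = np.nanmean(X, axis=1)
    crit = criterion.reindex(pivot.index).to_numpy(dtype=float)
    if np.isfinite(crit).sum() < 3:
        raise PipelineError("need >= 3 persons with criterion scores for the screen")

    removed, retained = [], []
    n_items = X.shape[1]
    for j, item in enumerate(pivot.columns):
        x = X[:, j]
        obs = x[~np.isnan(x)]
        if obs.size == 0 or obs.std() == 0:
            removed.append((item, "degenerate", np.nan))
            continue
        tot = total
        if corrected_total:
            tot = (total * n_items - np.nan_to_num(x)) / (n_items - 1)
        r_tot = _masked_pearson(x, tot)
        r_cri = _masked_pearson(x, crit)
        fail_tot = not (r_tot > r_threshold)
        fail_cri = not (r_cri > r_threshold)
        fails = (fail_tot or fail_cri) if rule == "either" else (fail_tot and fail_cri)
        if fails:
            stat = r_tot if fail_tot else r_cri
            reason = "low_r_total" if fail_tot else "low_r_criterion"
            removed.append((item, reason, stat))
        else:
            retained.append(item)
    if not retained:
        raise PipelineError("all items removed by the correlation screen")
    logger.info("step 1: removed %d / %d items", len(removed), n_items)
    return SelectionReport("step1_correlation", removed, retained,
                           {"r_threshold": r_threshold, "rule": rule})


def step2_rasch_prune(responses: pd.DataFrame, fit_range=(0.6, 1.4),
                      max_rounds: int = 50, **fit_kwargs) -> SelectionReport:
    """Iterative Rasch-fit pruning on infit/outfit.

    Fits the guess-floored Rasch model, removes every item whose infit or
    outfit falls outside ``fit_range``, refits, and repeats until no item is
    removed.  On the returned report, ``model`` is the final fit (every
    retained item within range) and ``n_iterations`` counts the fits.
    """
    lo, hi = fit_range
    current = responses
    removed = []
    model = None
    for rounds in range(1, max_rounds + 1):
        model = fit_model(current, model_kind="rasch_g", **fit_kwargs)
        abilities = estimate_abilities(model, current)
        stats = fit_statistics(model, current, abilities)
        bad = stats[(stats["infit"] < lo) | (stats["infit"] > hi)
                    | (stats["outfit"] < lo) | (stats["outfit"] > hi)]
        if bad.empty:
            break
        for _, row in bad.iterrows():
            out_of = row["outfit"] if (row["outfit"] < lo or row["outfit"] > hi) \
                else row["infit"]
            which = "outfit" if (row["outfit"] < lo or row["outfit"] > hi) else "infit"
            removed.append((row["item_id"], f"{which}_out_of_range", float(out_of)))
        current = current[~current["item_id"].isin(set(bad["item_id"]))]
        if current["item_id"].nunique() < 2:
            raise PipelineError("Rasch pruning removed (nearly) all items")
    else:
        raise PipelineError(f"Rasch pruning did not stabilize in {max_rounds} rounds")
    retained = list(pd.unique(current["item_id"]))
    logger.info("step 2: removed %d items in %d fit rounds", len(removed), rounds)
    return SelectionReport("step2_rasch_fit", removed, retained,
                           {"fit_range": list(fit_range)}, n_iterations=rounds,
                           model=model)


def step3_discrimination_prune(responses: pd.DataFrame, a_min: float = 0.7,
                               model: FittedModel | None = None,
                               **fit_kwargs) -> SelectionReport:
    """2PL slope pruning: drop items with estimated discrimination a < a_min.

    The inequality is strict: an item at exactly ``a_min`` survives.  A
    pre-fitted 2PL ``model`` may be supplied; otherwise one is fit to
    ``responses``.
    """
    if model is None:
        model = fit_model(responses, model_kind="twopl_g", **fit_kwargs)
    removed, retained = [], []
    for item, a in zip(model.item_ids, model.a):
        if a < a_min:
            removed.append((item, "low_slope", float(a)))
        else:
            retained.append(item)
    if not retained:
        raise PipelineError("all items removed by the discrimination prune")
    logger.info("step 3: removed %d items", len(removed))
    return SelectionReport("step3_discrimination", removed, retained,
                           {"a_min": a_min}, model=model)


@dataclass
class PipelineResult:
    retained_items: list
    reports: list
    rasch_model: FittedModel  # refit on the retained set; source of b_hat
    twopl_model: FittedModel

    def retained_table(self, items: pd.DataFrame) -> pd.DataFrame:
        """Retained items joined with covariates and the Rasch b_hat."""
        tab = self.rasch_model.item_table()[["item_id", "a_hat", "b_hat"]]
        tw = self.twopl_model.item_table()[["item_id", "a_hat"]].rename(
            columns={"a_hat": "a_hat_2pl"})
        out = items.merge(tab, on="item_id").merge(tw, on="item_id", how="left")
        return out[out["item_id"].isin(set(self.retained_items))].reset_index(drop=True)


def run_selection_pipeline(responses: pd.DataFrame, criterion: pd.Series,
                           r_threshold: float = 0.10, rule: str = "either",
                           fit_range=(0.6, 1.4), a_min: float = 0.7,
                           **fit_kwargs) -> PipelineResult:
    """Chain steps 1-3 with full provenance, then refit Rasch on survivors.

    The final Rasch refit supplies the difficulty estimates (``b_hat``) used
    for list assembly.
    """
    rep1 = step1_screen(responses, criterion, r_threshold=r_threshold, rule=rule)
    r1 = responses[responses["item_id"].isin(set(rep1.retained))]
    rep2 = step2_rasch_prune(r1, fit_range=fit_range, **fit_kwargs)
    r2 = r1[r1["item_id"].isin(set(rep2.retained))]
    rep3 = step3_discrimination_prune(r2, a_min=a_min, **fit_kwargs)
    r3 = r2[r2["item_id"].isin(set(rep3.retained))]
    rasch = fit_model(r3, model_kind="rasch_g", **fit_kwargs)
    for rep in (rep1, rep2, rep3):
        logger.info("%s: %d removed, %d retained", rep.step_label,
                    len(rep.removed), len(rep.retained))
    return PipelineResult(retained_items=list(rep3.retained),
                          reports=[rep1, rep2, rep3],
                          rasch_model=rasch, twopl_model=rep3.model)


@dataclass
class StimulusLists:
    """A partition of retained items into parallel forms."""

    lists: dict  # list_id -> DataFrame with item_id, lexicality, length, b_hat

    def __post_init__(self):
        ids = [set(df["item_id"]) for df in self.lists.values()]
        for i, s1 in enumerate(ids):
            for s2 in ids[i + 1:]:
                if s1 & s2:
                    raise ValueError("stimulus lists must be pairwise disjoint")

    @property
    def n_lists(self) -> int:
        return len(self.lists)

    @property
    def list_ids(self):
        return list(self.lists)

    def sizes(self) -> dict:
        return {k: len(v) for k, v in self.lists.items()}

    def class_counts(self) -> pd.DataFrame:
        rows = {k: v["lexicality"].value_counts().to_dict()
                for k, v in self.lists.items()}
        return pd.DataFrame(rows).T.fillna(0).astype(int)

    def difficulty_summary(self) -> pd.DataFrame:
        rows = {}
        for k, v in self.lists.items():
            b = v["b_hat"]
            rows[k] = {"mean": b.mean(), "sd": b.std(ddof=1),
                       "min": b.min(), "max": b.max(), "n": len(v)}
        return pd.DataFrame(rows).T

    def assignment(self) -> pd.DataFrame:
        frames = []
        for k, v in self.lists.items():
            f = v.copy()
            f.insert(0, "list_id", k)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def item_ids(self) -> set:
        return set().union(*(set(v["item_id"]) for v in self.lists.values()))


def _quantile_subsample(pool: pd.DataFrame, reference_b: np.ndarray, m: int,
                        rng) -> pd.DataFrame:
    """Pick m items from pool whose b_hat profile matches reference_b's quantiles.

    Greedy nearest-unused match to the reference distribution's evenly
    spaced quantiles; ties broken by higher 2PL information at the pool's
    ability quartiles when a slope column exists, then by seeded order.
    """
    targets = np.quantile(reference_b, (np.arange(m) + 0.5) / m)
    pool = pool.sample(frac=1.0, random_state=np.random.RandomState(
        rng.integers(2**31))).reset_index(drop=True)
    if "a_hat_2pl" in pool.columns and pool["a_hat_2pl"].notna().all():
        quartiles = np.quantile(reference_b, [0.25, 0.5, 0.75])
        info = item_information(pool["a_hat_2pl"].to_numpy()[:, None],
                                pool["b_hat"].to_numpy()[:, None], 0.5,
                                quartiles[None, :]).sum(axis=1)
        pool = pool.iloc[np.argsort(-info, kind="stable")].reset_index(drop=True)
    b = pool["b_hat"].to_numpy()
    used = np.zeros(len(pool), dtype=bool)
    chosen = []
    for t in targets:
        d = np.abs(b - t)
        d[used] = np.inf
        k = int(np.argmin(d))
        used[k] = True
        chosen.append(k)
    return pool.iloc[sorted(chosen)].reset_index(drop=True)


def _balance_objective(assign, b, length, length_weight):
    means_b = np.array([b[assign == g].mean() for g in range(assign.max() + 1)])
    means_l = np.array([length[assign == g].mean() for g in range(assign.max() + 1)])
    return means_b.var() + length_weight * means_l.var()


def assemble_lists(retained: pd.DataFrame, n_lists: int = 3,
                   balance_classes: bool = True, b_tolerance: float = 0.1,
                   length_weight: float = 0.1, max_swaps: int = 1000,
                   seed: int = 0) -> StimulusLists:
    """Partition retained items into difficulty-equated, class-balanced lists.

    With ``balance_classes`` the per-list size is ``2 * floor(min(n_real,
    n_pseudo) / n_lists)``; the abundant class is subsampled to match the
    scarcer class's difficulty distribution.  Items are dealt in serpentine
    order of difficulty across lists, then pairwise same-class swaps
    hill-climb on ``var(list mean b) + length_weight * var(list mean
    length)``.  A warning is logged if list mean difficulties end up more
    than ``b_tolerance`` apart.
    """
    required = {"item_id", "lexicality", "length", "b_hat"}
    if not required <= set(retained.columns):
        raise ValueError(f"retained table needs columns {sorted(required)}")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(77,)))
    classes = ["real", "pseudo"] if balance_classes else ["all"]
    parts = []
    if balance_classes:
        by = {cls: retained[retained["lexicality"] == cls] for cls in classes}
        counts = {cls: len(df) for cls, df in by.items()}
        per_list = min(counts.values()) // n_lists
        if per_list < 1:
            raise PipelineError(
                f"fewer than {n_lists} items in a class: {counts}")
        m = per_list * n_lists
        scarce = min(by, key=lambda c: counts[c])
        ref = by[scarce].sort_values("b_hat")
        # evenly spaced order statistics keep the scarce class's own spread
        keep_idx = np.round(np.linspace(0, counts[scarce] - 1, m)).astype(int)
        scarce_used = ref.iloc[keep_idx]
        for cls in classes:
            if cls == scarce:
                parts.append(scarce_used)
            else:
                parts.append(_quantile_subsample(
                    by[cls], scarce_used["b_hat"].to_numpy(), m, rng))
    else:
        m = (len(retained) // n_lists) * n_lists
        parts.append(retained.sort_values("b_hat").iloc[:m])

    # serpentine deal within each class, by difficulty
    assignments = []
    frames = []
    for part in parts:
        part = part.sort_values("b_hat").reset_index(drop=True)
        pattern = np.concatenate([np.arange(n_lists), np.arange(n_lists)[::-1]])
        assign = np.resize(pattern, len(part))
        assignments.append(assign)
        frames.append(part)
    serpentine = np.concatenate(assignments)
    pool = pd.concat(frames, ignore_index=True)
    class_of = pool["lexicality"].to_numpy()
    b = pool["b_hat"].to_numpy()
    length = pool["length"].to_numpy(dtype=float)

    def local_search(assign, budget):
        """Sweep all same-class cross-list swaps until no improvement."""
        obj = _balance_objective(assign, b, length, length_weight)
        swappable = [(i, j) for i in range(len(pool))
                     for j in range(i + 1, len(pool))
                     if class_of[i] == class_of[j]]
        improved = True
        while improved and budget > 0:
            improved = False
            for i, j in swappable:
                if assign[i] == assign[j]:
                    continue
                budget -= 1
                assign[i], assign[j] = assign[j], assign[i]
                new = _balance_objective(assign, b, length, length_weight)
                if new < obj - 1e-15:
                    obj = new
                    improved = True
                else:
                    assign[i], assign[j] = assign[j], assign[i]
                if budget <= 0:
                    break
        return assign, obj

    # serpentine start plus seeded random restarts; keep the best local optimum
    best_assign, best_obj = local_search(serpentine.copy(), max_swaps)
    for _ in range(4):
        shuffled = serpentine.copy()
        for cls in np.unique(class_of):
            sel = np.flatnonzero(class_of == cls)
            shuffled[sel] = shuffled[sel][rng.permutation(len(sel))]
        cand, obj = local_search(shuffled, max_swaps)
        if obj < best_obj:
            best_assign, best_obj = cand, obj
    assign = best_assign

    labels = [chr(ord("A") + g) for g in range(n_lists)]
    lists = {}
    for g, lab in enumerate(labels):
        lists[lab] = pool[assign == g].sort_values("b_hat").reset_index(drop=True)
    out = StimulusLists(lists=lists)
    means = out.difficulty_summary()["mean"]
    spread = float(means.max() - means.min())
    if spread > b_tolerance:
        logger.warning("list mean difficulties differ by %.3f > tolerance %.3f",
                       spread, b_tolerance)
    return out


def augment_lists(lists: StimulusLists, easy_items: pd.DataFrame) -> StimulusLists:
    """Add easy anchor items (e.g. 4 real + 4 pseudo per list) to each form.

    ``easy_items`` may carry a ``list_id`` column; otherwise items are dealt
    round-robin within lexicality class in difficulty order.  Added items
    must be disjoint from the current lists and from each other.
    """
    if easy_items.empty:
        return lists
    if easy_items["item_id"].duplicated().any():
        raise ValueError("duplicate item_id in augmentation set")
    clash = set(easy_items["item_id"]) & lists.item_ids()
    if clash:
        raise ValueError(f"augmentation items already assigned: {sorted(clash)[:5]}")
    new = {k: [v] for k, v in lists.lists.items()}
    labels = lists.list_ids
    if "list_id" in easy_items.columns:
        for lab, grp in easy_items.groupby("list_id"):
            if lab not in new:
                raise ValueError(f"unknown list id {lab!r} in augmentation set")
            new[lab].append(grp.drop(columns="list_id"))
    else:
        if len(easy_items) % len(labels):
            raise ValueError("augmentation set size must divide evenly across lists")
        for _, grp in easy_items.groupby("lexicality"):
            grp = grp.sort_values("b_hat") if "b_hat" in grp else grp
            for k, (_, row) in enumerate(grp.iterrows()):
                new[labels[k % len(labels)]].append(row.to_frame().T)
    merged = {k: pd.concat(v, ignore_index=True) for k, v in new.items()}
    return StimulusLists(lists=merged)


@dataclass
class ListEvaluation:
    info_curves: pd.DataFrame      # theta x one column per list
    info_ratio_range: tuple        # (min, max) pairwise pointwise ratio
    scores: pd.DataFrame           # person x list proportion correct
    mean_differences: pd.DataFrame
    icc_single: float
    icc_average: float


def evaluate_lists(lists: StimulusLists, model: FittedModel,
                   responses: pd.DataFrame | None = None,
                   theta_grid=None) -> ListEvaluation:
    """Parallel-form diagnostics: information curves and score equivalence.

    Computes each list's test information on ``theta_grid``, the extreme
    pairwise pointwise information ratios, and — when responses are given —
    per-person per-list proportion-correct scores, their between-list mean
    differences, and the consistency ICC across forms.
    """
    from .psych import icc_consistency

    theta_grid = np.asarray(theta_grid if theta_grid is not None
                            else np.linspace(-3, 3, 61), dtype=float)
    curves = {"theta": theta_grid}
    for lab, df in lists.lists.items():
        curves[lab] = test_information(model, theta_grid,
                                       item_ids=df["item_id"]).to_numpy()[:, 1]
    info_curves = pd.DataFrame(curves)
    labs = lists.list_ids
    ratios = []
    for i, l1 in enumerate(labs):
        for l2 in labs[i + 1:]:
            r = info_curves[l1].to_numpy() / info_curves[l2].to_numpy()
            ratios.extend([r.min(), r.max()])
    ratio_range = (float(min(ratios)), float(max(ratios))) if ratios else (1.0, 1.0)

    scores = pd.DataFrame()
    mean_diffs = pd.DataFrame()
    icc_s = icc_a = np.nan
    if responses is not None:
        assign = lists.assignment()[["list_id", "item_id"]]
        merged = responses.merge(assign, on="item_id")
        scores = (merged.groupby(["person_id", "list_id"])["correct"].mean()
                  .unstack("list_id"))
        rows = []
        for i, l1 in enumerate(labs):
            for l2 in labs[i + 1:]:
                d = scores[l1] - scores[l2]
                rows.append({"pair": f"{l1}-{l2}", "mean_diff": d.mean(),
                             "se": d.std(ddof=1) / np.sqrt(d.notna().sum())})
        mean_diffs = pd.DataFrame(rows)
        icc = icc_consistency(scores)
        icc_s, icc_a = icc.icc_single, icc.icc_average
    return ListEvaluation(info_curves=info_curves, info_ratio_range=ratio_range,
                          scores=scores, mean_differences=mean_diffs,
                          icc_single=icc_s, icc_average=icc_a)
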