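"""Scoring and validation statistics for parallel test forms.

Covers the classical-test-theory side of test validation: accuracy scoring,
criterion correlations with disattenuation, Williams' test for comparing two
dependent correlations, intraclass correlation across parallel forms,
Spearman-Brown composite reliability, the linear ability-to-criterion
mapping, rank-based comparisons of retained vs. rejected item properties,
and list/block/trial-order effect checks.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("lexirt")

__all__ = [
    "accuracy_scores",
    "criterion_correlation",
    "disattenuate",
    "williams_test",
    "icc_consistency",
    "ICCResult",
    "spearman_brown",
    "map_ability_to_criterion",
    "compare_item_properties",
    "order_effect_checks",
]


def accuracy_scores(responses: pd.DataFrame, items: pd.DataFrame | None = None,
                    list_assignment: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-person proportion-correct scores, overall and by grouping.

    Adds per-lexicality columns when an item table is supplied and per-list
    columns when a (list_id, item_id) assignment is supplied; per-block
    columns come from the response table itself.  Groups a person never saw
    are left absent (NaN), not zero.
    """
    if responses.empty:
        raise ValueError("responses are empty")
    out = responses.groupby("person_id")["correct"].mean().to_frame("overall")
    blocks = responses.pivot_table(index="person_id", columns="block_index",
                                   values="correct", aggfunc="mean")
    blocks.columns = [f"block_{int(b)}" for b in blocks.columns]
    out = out.join(blocks)
    if items is not None:
        merged = responses.merge(items[["item_id", "lexicality"]], on="item_id")
        lex = merged.pivot_table(index="person_id", columns="lexicality",
                                 values="correct", aggfunc="mean")
        out = out.join(lex.add_prefix("lex_"))
    if list_assignment is not None:
        merged = responses.merge(list_assignment[["list_id", "item_id"]],
                                 on="item_id")
        ls = merged.pivot_table(index="person_id", columns="list_id",
                                values="correct", aggfunc="mean")
        out = out.join(ls.add_prefix("list_"))
    return out


def criterion_correlation(scores: pd.Series, criterion: pd.Series):
    """Pearson r between scores and criterion, pairwise-complete.

    Returns ``(r, n_used)``.
    """
    df = pd.DataFrame({"s": scores, "c": criterion}).dropna()
    if len(df) < 3:
        raise ValueError("need >= 3 complete pairs")
    if df["s"].std() == 0 or df["c"].std() == 0:
        raise ValueError("correlation undefined: zero variance input")
    return float(np.corrcoef(df["s"], df["c"])[0, 1]), len(df)


def disattenuate(r_observed: float, reliability_x: float,
                 reliability_y: float | None = None) -> float:
    """Classical correction for attenuation: r / sqrt(rel_x * rel_y).

    Pass ``reliability_y=None`` to correct for one instrument only
    (r / sqrt(rel_x)).  Corrected values above 1 are clipped with a warning.
    """
    rels = [reliability_x] + ([] if reliability_y is None else [reliability_y])
    for rel in rels:
        if not 0 < rel <= 1:
            raise ValueError("reliabilities must lie in (0, 1]")
    denom = np.sqrt(np.prod(rels))
    r = r_observed / denom
    if abs(r) > 1:
        logger.warning("disattenuated r = %.3f clipped to +/-1", r)
        r = float(np.clip(r, -1, 1))
    return float(r)


def williams_test(r12: float, r13: float, r23: float, n: int):
    """Williams' t for two dependent correlations sharing variable 1.

    Tests r12 = r13 given their mutual correlation r23; t has n - 3 degrees
    of freedom and carries the sign of (r12 - r13).  Returns ``(t, p)`` with
    a two-sided p-value.
    """
    if n <= 3:
        raise ValueError("n must exceed 3")
    for r in (r12, r13, r23):
        if not -1 < r < 1:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    detR = 1 - r12**2 - r13**2 - r23**2 + 2 * r12 * r13 * r23
    if detR <= 0:
        raise ValueError("inconsistent correlation matrix (determinant <= 0)")
    rbar = (r12 + r13) / 2
    denom = 2 * ((n - 1) / (n - 3)) * detR + rbar**2 * (1 - r23) ** 3
    t = (r12 - r13) * np.sqrt((n - 1) * (1 + r23) / denom)
    p = 2 * stats.t.sf(abs(t), df=n - 3)
    return float(t), float(p)


@dataclass
class ICCResult:
    icc_single: float
    icc_average: float
    variant: str
    n_persons: int
    n_forms: int


def icc_consistency(score_matrix: pd.DataFrame, agreement: bool = False) -> ICCResult:
    """Intraclass correlation across parallel forms (two-way, single measure).

    Default is the consistency variant (invariant to adding a constant to
    one form — appropriate for interchangeable forms); ``agreement=True``
    additionally penalizes form mean differences.  Rows with missing entries
    are dropped (logged).  Also reports the average-measure ICC of the
    k-form composite.
    """
    m = score_matrix.dropna()
    dropped = len(score_matrix) - len(m)
    if dropped:
        logger.info("ICC drops %d incomplete person rows", dropped)
    n, k = m.shape
    if k < 2 or n < 3:
        raise ValueError("need >= 2 forms and >= 3 complete persons")
    x = m.to_numpy(dtype=float)
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if msr <= 0:
        logger.warning("zero between-person variance; ICC set to 0")
        return ICCResult(0.0, 0.0, "consistency", n, k)
    if agreement:
        single = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        average = (msr - mse) / (msr + (msc - mse) / n)
        variant = "agreement"
    else:
        single = (msr - mse) / (msr + (k - 1) * mse)
        average = (msr - mse) / msr
        variant = "consistency"
    return ICCResult(float(single), float(average), variant, n, k)


def spearman_brown(reliability: float, k_forms: float) -> float:
    """Spearman-Brown prophecy: reliability of a k-times-longer composite."""
    if not 0 <= reliability <= 1:
        raise ValueError("reliability must lie in [0, 1]")
    if k_forms < 1:
        raise ValueError("k_forms must be >= 1")
    if reliability == 0:
        return 0.0
    return k_forms * reliability / (1 + (k_forms - 1) * reliability)


@dataclass
class AbilityCriterionMap:
    slope: float
    intercept: float
    r: float
    n: int
    criterion_range: tuple

    def predict(self, theta, clip: bool = True):
        theta = np.asarray(theta, dtype=float)
        y = self.intercept + self.slope * theta
        lo, hi = self.criterion_range
        if clip:
            extrap = (y < lo) | (y > hi)
            if extrap.any():
                logger.info("clipping %d prediction(s) outside the criterion range",
                            int(np.sum(extrap)))
            y = np.clip(y, lo, hi)
        return y


def map_ability_to_criterion(theta_hats: pd.Series,
                             criterion: pd.Series) -> AbilityCriterionMap:
    """Least-squares line mapping ability estimates to the criterion scale.

    Supports reporting model-based scores in the criterion's raw-score units
    (e.g. a standardized reading test).  Predictions clip to the observed
    criterion range (flagged when extrapolating).
    """
    df = pd.DataFrame({"t": theta_hats, "c": criterion}).dropna()
    if len(df) < 3:
        raise ValueError("need >= 3 complete pairs")
    if df["t"].std() == 0:
        raise ValueError("zero variance in ability estimates")
    slope, intercept = np.polyfit(df["t"], df["c"], 1)
    if df["c"].std() == 0:
        logger.warning("constant criterion: slope is 0")
        r = 0.0
    else:
        r = float(np.corrcoef(df["t"], df["c"])[0, 1])
    return AbilityCriterionMap(
        slope=float(slope), intercept=float(intercept), r=r, n=len(df),
        criterion_range=(float(df["c"].min()), float(df["c"].max())))


@dataclass
class PropertyComparison:
    H: float
    df: int
    p: float
    group_medians: dict
    pairwise: pd.DataFrame


def compare_item_properties(items: pd.DataFrame, retained_ids,
                            prop: str, p_mode: str = "asymptotic",
                            max_exact_n: int = 9) -> PropertyComparison:
    """Kruskal-Wallis comparison of an item property across selection groups.

    Groups are the retained/rejected by real/pseudo cells (empty groups
    dropped).  ``p_mode='exact'`` replaces the chi-square p-value by full
    permutation enumeration (small samples only).  Pairwise follow-ups use
    two-sided rank-sum tests with Bonferroni correction.
    """
    retained_ids = set(retained_ids)
    d = items.dropna(subset=[prop]).copy()
    d["group"] = np.where(d["item_id"].isin(retained_ids), "retained", "rejected") \
        + "_" + d["lexicality"].astype(str)
    groups = {g: grp[prop].to_numpy() for g, grp in d.groupby("group") if len(grp)}
    if len(groups) < 2:
        raise ValueError("need >= 2 non-empty groups")
    H, p = stats.kruskal(*groups.values())
    if p_mode == "exact":
        values = np.concatenate(list(groups.values()))
        if len(values) > max_exact_n:
            raise ValueError(f"exact enumeration limited to n <= {max_exact_n}")
        sizes = [len(v) for v in groups.values()]
        count = total = 0
        for perm in itertools.permutations(values):
            perm = np.asarray(perm)
            chunks, start = [], 0
            for s in sizes:
                chunks.append(perm[start:start + s])
                start += s
            h_perm, _ = stats.kruskal(*chunks)
            count += h_perm >= H - 1e-12
            total += 1
        p = count / total
    elif p_mode != "asymptotic":
        raise ValueError("p_mode must be 'asymptotic' or 'exact'")
    medians = {g: float(np.median(v)) for g, v in groups.items()}
    rows = []
    pairs = list(itertools.combinations(sorted(groups), 2))
    for g1, g2 in pairs:
        u, pu = stats.mannwhitneyu(groups[g1], groups[g2], alternative="two-sided")
        rows.append({"group1": g1, "group2": g2, "u": float(u),
                     "p_raw": float(pu),
                     "p_bonferroni": float(min(1.0, pu * len(pairs)))})
    return PropertyComparison(H=float(H), df=len(groups) - 1, p=float(p),
                              group_medians=medians, pairwise=pd.DataFrame(rows))


def _paired_contrasts(wide: pd.DataFrame, label: str) -> pd.DataFrame:
    """Within-person paired contrasts of each column against the first."""
    cols = list(wide.columns)
    rows = []
    for col in cols[1:]:
        d = (wide[col] - wide[cols[0]]).dropna()
        se = d.std(ddof=1) / np.sqrt(len(d))
        t = d.mean() / se if se > 0 else np.nan
        p = 2 * stats.t.sf(abs(t), df=len(d) - 1) if np.isfinite(t) else np.nan
        rows.append({"contrast": f"{label}:{col} - {cols[0]}",
                     "estimate": d.mean(), "se": se, "t": t, "p": p,
                     "n_persons": len(d)})
    return pd.DataFrame(rows)


def _person_logistic_slope(y, x, max_iter=50):
    """Newton-fit logistic regression slope of y on standardized x."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    for _ in range(max_iter):
        eta = X @ beta
        p = 1 / (1 + np.exp(-eta))
        W = p * (1 - p)
        g = X.T @ (y - p)
        Hmat = (X * W[:, None]).T @ X + 1e-8 * np.eye(2)
        step = np.linalg.solve(Hmat, g)
        beta = beta + step
        if np.abs(step).max() < 1e-8 or np.abs(beta).max() > 20:
            break
    return beta[1]


@dataclass
class OrderEffects:
    list_contrasts: pd.DataFrame
    block_contrasts: pd.DataFrame
    trial_slope: dict  # estimate, se, t, n_persons


def order_effect_checks(responses: pd.DataFrame,
                        list_assignment: pd.DataFrame | None = None) -> OrderEffects:
    """List, block and trial-order effect checks.

    List and block contrasts are within-person paired comparisons of
    proportion correct against the first list/block.  The trial-order effect
    is a per-person logistic regression of correctness on the standardized
    trial index, with the slopes aggregated across persons (mean, se, t).
    """
    scores = accuracy_scores(responses, list_assignment=list_assignment)
    block_cols = [c for c in scores.columns if c.startswith("block_")]
    block_contrasts = (_paired_contrasts(scores[block_cols], "block")
                       if len(block_cols) > 1 else pd.DataFrame())
    list_cols = [c for c in scores.columns if c.startswith("list_")]
    list_contrasts = (_paired_contrasts(scores[list_cols], "list")
                      if len(list_cols) > 1 else pd.DataFrame())

    slopes = []
    for _, grp in responses.groupby("person_id"):
        y = grp["correct"].to_numpy(dtype=float)
        if y.std() == 0 or len(y) < 10:
            continue
        x = grp["trial_index"].to_numpy(dtype=float)
        x = (x - x.mean()) / x.std()
        slopes.append(_person_logistic_slope(y, x))
    if slopes:
        slopes = np.asarray(slopes)
        se = slopes.std(ddof=1) / np.sqrt(len(slopes))
        trial = {"estimate": float(slopes.mean()), "se": float(se),
                 "t": float(slopes.mean() / se) if se > 0 else np.nan,
                 "n_persons": int(len(slopes))}
    else:
        trial = {"estimate": np.nan, "se": np.nan, "t": np.nan, "n_persons": 0}
    return OrderEffects(list_contrasts=list_contrasts,
                        block_contrasts=block_contrasts, trial_slope=trial)
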