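"""Response-time preprocessing and effect estimation.

Order of operations (fixed): participant exclusion on median RT, absolute
window trimming, per-participant IQR trimming, log transform, modelling on
correct trials only.

Effect estimation is a two-stage approximation to a mixed-effects model:
stage 1 fits an ordinary least-squares regression of log RT on the
configured terms within each person; stage 2 summarizes the per-person
coefficients across persons (mean, sd, t), or — for the length-by-ability
interaction, which is collinear with length within a person — regresses the
per-person length slopes on ability.  For balanced designs this recovers the
fixed effects of the random-intercept-and-slope model without variance-
component machinery.

Because lexicality, frequency and length are *item-level* covariates, their
sampling uncertainty is dominated by the finite draw of items, which the
cross-person spread of coefficients cannot see (item intercepts shift every
person's coefficient identically — the language-as-a-fixed-effect problem).
The reported standard error for item-level terms therefore combines the
cross-person component with the between-item regression's coefficient
standard error, mirroring what a crossed random-effects model would report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("lexirt")

__all__ = [
    "ExclusionLedger",
    "exclude_outlier_participants",
    "filter_rt_trials",
    "estimate_rt_effects",
    "rt_criterion_correlation",
    "RT_TERMS",
]

RT_TERMS = ("lexicality", "log_frequency", "bigram_pseudo", "length",
            "length_x_ability")


@dataclass
class ExclusionLedger:
    """Bookkeeping for participant and trial exclusions."""

    n_input_trials: int
    n_retained_trials: int
    excluded_persons: list = field(default_factory=list)  # (person_id, median_rt, rule)
    excluded_trials: dict = field(default_factory=dict)   # rule -> count

    @property
    def fraction_excluded(self) -> float:
        if self.n_input_trials == 0:
            return 0.0
        return 1.0 - self.n_retained_trials / self.n_input_trials

    def to_dict(self) -> dict:
        return {
            "n_input_trials": self.n_input_trials,
            "n_retained_trials": self.n_retained_trials,
            "fraction_excluded": self.fraction_excluded,
            "excluded_persons": [
                {"person_id": str(p), "median_rt": float(m), "rule": r}
                for p, m, r in self.excluded_persons],
            "excluded_trials": {k: int(v) for k, v in self.excluded_trials.items()},
        }


def exclude_outlier_participants(responses: pd.DataFrame, n_sd: float = 3.0,
                                 on_log: bool = False):
    """Drop participants whose median RT is > n_sd below the sample mean.

    One-sided (only implausibly *fast* medians are excluded — the signature
    of random key-mashing).  Medians are over all of a person's trials, on
    raw seconds by default (``on_log=True`` screens log medians instead).
    """
    med = responses.groupby("person_id")["rt_seconds"].median()
    vals = np.log(med) if on_log else med
    if len(med) < 2:
        logger.warning("single participant: outlier screen is a no-op")
        return responses, ExclusionLedger(len(responses), len(responses))
    cutoff = vals.mean() - n_sd * vals.std(ddof=1)
    bad = vals.index[vals < cutoff]
    ledger = ExclusionLedger(
        n_input_trials=len(responses),
        n_retained_trials=0,
        excluded_persons=[(p, float(med.loc[p]), f"median_rt_below_mean_minus_{n_sd:g}sd")
                          for p in bad],
    )
    out = responses[~responses["person_id"].isin(set(bad))]
    ledger.n_retained_trials = len(out)
    ledger.excluded_trials = {"outlier_participant": len(responses) - len(out)}
    if len(bad):
        logger.info("excluded %d participant(s) by the %g-sd median-RT rule",
                    len(bad), n_sd)
    return out, ledger


def filter_rt_trials(responses: pd.DataFrame, min_s: float = 0.2,
                     max_s: float = 5.0, iqr_multiplier: float = 3.0):
    """Absolute RT window, then per-participant IQR trimming.

    Trials strictly outside [min_s, max_s] are removed first; then, per
    participant, quartiles of the surviving RTs define a fence of
    ``iqr_multiplier`` times the IQR beyond Q1/Q3.  A person with zero IQR
    loses no further trials.
    """
    rt = responses["rt_seconds"]
    too_fast = rt < min_s
    too_slow = rt > max_s
    windowed = responses[~(too_fast | too_slow)]
    q = windowed.groupby("person_id")["rt_seconds"].quantile([0.25, 0.75]).unstack()
    lo = (q[0.25] - iqr_multiplier * (q[0.75] - q[0.25])).reindex(
        windowed["person_id"]).to_numpy()
    hi = (q[0.75] + iqr_multiplier * (q[0.75] - q[0.25])).reindex(
        windowed["person_id"]).to_numpy()
    v = windowed["rt_seconds"].to_numpy()
    iqr_low = v < lo
    iqr_high = v > hi
    out = windowed[~(iqr_low | iqr_high)]
    ledger = ExclusionLedger(
        n_input_trials=len(responses), n_retained_trials=len(out),
        excluded_trials={
            "too_fast": int(too_fast.sum()), "too_slow": int(too_slow.sum()),
            "iqr_low": int(iqr_low.sum()), "iqr_high": int(iqr_high.sum()),
        })
    return out, ledger


def _per_person_ols(y, X):
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        return None
    return coef


def _stage2(coefs, term):
    coefs = np.asarray(coefs, dtype=float)
    n = len(coefs)
    est = coefs.mean()
    se = coefs.std(ddof=1) / np.sqrt(n)
    return {"term": term, "estimate": est, "se": se,
            "t": est / se if se > 0 else np.nan, "n_persons": n}


def estimate_rt_effects(filtered: pd.DataFrame, items: pd.DataFrame,
                        persons: pd.DataFrame, model_terms=("lexicality",),
                        ability: pd.Series | None = None) -> pd.DataFrame:
    """Two-stage estimation of log-RT effects on correct trials.

    ``model_terms`` selects which effects to estimate; each within-person
    term yields one row (cross-person mean, se, t).  Term semantics:

    * ``lexicality`` — pseudoword minus real-word log RT;
    * ``log_frequency`` — slope on log lexical frequency (real trials only);
    * ``bigram_pseudo`` — slope on log bigram frequency (pseudoword trials);
    * ``length`` — slope on stimulus length in letters;
    * ``length_x_ability`` — stage-2 regression of per-person length slopes
      on an externally supplied ability score (defaults to the cohort's
      ``theta_true``; pass ``ability`` to use e.g. a criterion score).

    Persons with fewer usable trials than parameters + 2 are dropped from
    stage 2 (logged).
    """
    terms = list(model_terms)
    unknown = set(terms) - set(RT_TERMS)
    if unknown:
        raise ValueError(f"unknown terms: {sorted(unknown)}")
    d = filtered[filtered["correct"] == 1].merge(
        items[["item_id", "lexicality", "length", "log_lexical_frequency",
               "log_bigram_frequency"]], on="item_id")
    d["log_rt"] = np.log(d["rt_seconds"])
    if ability is None:
        ability = persons.set_index("person_id")["theta_true"]

    # Stage-1 design.  Class-specific slopes are estimated within their class
    # when requested alone (the classic single-effect models); otherwise all
    # requested terms enter one per-person regression so each coefficient is
    # adjusted for the others.
    if terms == ["log_frequency"]:
        d = d[d["lexicality"] == "real"]
        columns = ["log_frequency"]
    elif terms == ["bigram_pseudo"]:
        d = d[d["lexicality"] == "pseudo"]
        columns = ["bigram_pseudo"]
    else:
        columns = []
        need_lex = {"lexicality", "log_frequency", "bigram_pseudo"} & set(terms)
        if need_lex:
            columns.append("lexicality")
        if "log_frequency" in terms:
            columns.append("log_frequency")
        if "bigram_pseudo" in terms:
            columns.append("bigram_pseudo")
        if "length" in terms or "length_x_ability" in terms:
            columns.append("length")

    pseudo = (d["lexicality"] == "pseudo").to_numpy(dtype=float)
    design = {
        "lexicality": pseudo,
        "log_frequency": np.nan_to_num(
            d["log_lexical_frequency"].to_numpy(), nan=0.0) * (1 - pseudo),
        "bigram_pseudo": d["log_bigram_frequency"].to_numpy() * pseudo,
        "length": d["length"].to_numpy(dtype=float),
    }
    d = d.assign(**{f"x_{c}": design[c] for c in columns})

    n_params = len(columns) + 1
    per_person = {c: {} for c in columns}
    n_dropped = 0
    for pid, grp in d.groupby("person_id"):
        X = np.column_stack([np.ones(len(grp))]
                            + [grp[f"x_{c}"].to_numpy() for c in columns])
        if len(grp) < n_params + 2 or any(
                np.std(grp[f"x_{c}"]) == 0 for c in columns):
            n_dropped += 1
            continue
        coef = _per_person_ols(grp["log_rt"].to_numpy(), X)
        if coef is None:
            n_dropped += 1
            continue
        for k, c in enumerate(columns):
            per_person[c][pid] = coef[k + 1]
    if n_dropped:
        logger.info("dropped %d person(s) with too few usable trials", n_dropped)

    # Item-side uncertainty of the item-level covariate effects: OLS of
    # per-item mean log RT on the same design across items.
    se_item = {c: 0.0 for c in columns}
    item_means = d.groupby("item_id").agg(
        y=("log_rt", "mean"), **{c: (f"x_{c}", "first") for c in columns})
    if len(item_means) >= len(columns) + 3:
        Z = np.column_stack([np.ones(len(item_means))]
                            + [item_means[c].to_numpy() for c in columns])
        yi = item_means["y"].to_numpy()
        coef_i, _, rank, _ = np.linalg.lstsq(Z, yi, rcond=None)
        if rank == Z.shape[1]:
            resid = yi - Z @ coef_i
            sigma2 = (resid**2).sum() / (len(yi) - Z.shape[1])
            cov = sigma2 * np.linalg.inv(Z.T @ Z)
            for k, c in enumerate(columns):
                se_item[c] = float(np.sqrt(cov[k + 1, k + 1]))
    else:
        logger.warning("too few items to estimate item-side uncertainty")

    rows = []
    for term in terms:
        if term == "length_x_ability":
            # stage 2: per-person length slopes regressed on ability
            s = pd.Series(per_person["length"])
            ab = ability.reindex(s.index)
            keep = ab.notna()
            s, ab = s[keep], ab[keep]
            if len(s) < 4:
                raise ValueError("too few persons with ability for the interaction")
            X = np.column_stack([np.ones(len(s)), ab.to_numpy()])
            coef, _, _, _ = np.linalg.lstsq(X, s.to_numpy(), rcond=None)
            resid = s.to_numpy() - X @ coef
            sigma2 = (resid**2).sum() / (len(s) - 2)
            se = float(np.sqrt((sigma2 * np.linalg.inv(X.T @ X))[1, 1]))
            rows.append({"term": term, "estimate": float(coef[1]), "se": se,
                         "t": float(coef[1] / se), "n_persons": len(s)})
        else:
            vals = list(per_person[term].values())
            if not vals:
                raise ValueError(f"no person had enough trials for term {term!r}")
            row = _stage2(vals, term)
            row["se"] = float(np.sqrt(row["se"] ** 2 + se_item[term] ** 2))
            row["t"] = row["estimate"] / row["se"] if row["se"] > 0 else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RTCriterionResult:
    r_all: float
    n_all: int
    r_high_accuracy: float | None
    n_high_accuracy: int
    accuracy_floor: float


def rt_criterion_correlation(responses: pd.DataFrame, criterion: pd.Series,
                             accuracy_floor: float = 0.7) -> RTCriterionResult:
    """Correlation of per-person median correct-trial RT with the criterion.

    Computed over all persons with a criterion score, and again restricted
    to persons above ``accuracy_floor`` proportion correct — the subset in
    which response speed is expected to carry ability information.
    """
    per = responses.groupby("person_id").agg(
        accuracy=("correct", "mean"))
    med = responses[responses["correct"] == 1].groupby("person_id")[
        "rt_seconds"].median()
    per["median_rt"] = med
    per["criterion"] = criterion.reindex(per.index)
    full = per.dropna(subset=["median_rt", "criterion"])
    if len(full) < 3:
        raise ValueError("need >= 3 persons with criterion and correct trials")
    if full["criterion"].std() == 0 or full["median_rt"].std() == 0:
        raise ValueError("correlation undefined: zero variance input")
    r_all = float(np.corrcoef(full["median_rt"], full["criterion"])[0, 1])
    sub = full[full["accuracy"] > accuracy_floor]
    if len(sub) < 3:
        logger.warning("high-accuracy subset has %d persons; correlation omitted",
                       len(sub))
        r_high = None
    else:
        r_high = float(np.corrcoef(sub["median_rt"], sub["criterion"])[0, 1])
    return RTCriterionResult(r_all=r_all, n_all=len(full), r_high_accuracy=r_high,
                             n_high_accuracy=len(sub), accuracy_floor=accuracy_floor)
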