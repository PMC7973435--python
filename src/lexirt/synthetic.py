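"""Synthetic lexical-decision data with the structure the analyses assume.

Generates item banks (words and pseudowords with lexical covariates and true
IRT parameters), person cohorts (latent ability linearly linked to an
external criterion score), and full sessions of 2AFC accuracy plus lognormal
response times carrying lexicality, frequency and length effects.

Pathologies can be planted for recall testing of the selection pipeline:

* ``null_discrimination`` — the item's slope is zero, so every person
  succeeds with the same flat probability ``irf(theta, 0, b, c)`` (0.75 at
  the 2AFC floor); the 2PL slope prune catches these.
* ``misfit_lapse`` — an easy, well-discriminating item on which persons in
  the top ability quartile respond at chance (high performers stop
  attending to trivially easy items); they then err exactly where the model
  is most confident, which inflates outfit, so the Rasch fit-statistic
  prune catches these.  Milder lapse structures (uniform lapses, inverted
  segments) are absorbed or boundary-censored by the floor and stay inside
  the lenient fit window.
* ``misfit_inverted`` — persons in the upper half of the ability
  distribution get the *complement* of the item response function.  Note:
  the resulting below-chance accuracy is boundary-censored by a
  guess-floored fit (all residuals land at 1), so this pathology is
  invisible to infit/outfit and to the slope prune; it dies at the
  correlation screen instead.  It is kept for studying exactly that
  censoring.

Non-compliant persons answer at chance with fast response times, emulating
participants who mash keys without reading.

All randomness flows from one integer seed through ``numpy.random.
SeedSequence`` spawn keys, with per-person substreams so regenerating a
subset of persons is stable.
"""

from __future__ import annotations

import logging
import math
import string as _string
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .irt import irf

logger = logging.getLogger("lexirt")

__all__ = [
    "RTGenParams",
    "SessionDesign",
    "generate_item_bank",
    "generate_cohort",
    "simulate_session",
    "ITEM_COLUMNS",
    "COHORT_COLUMNS",
    "RESPONSE_COLUMNS",
]

ITEM_COLUMNS = [
    "item_id", "string", "lexicality", "length", "log_lexical_frequency",
    "log_bigram_frequency", "log_trigram_frequency", "log_neighbor_frequency",
    "a_true", "b_true", "c_true", "pathology",
]
COHORT_COLUMNS = [
    "person_id", "theta_true", "age_years", "criterion_true",
    "criterion_observed", "compliant",
]
RESPONSE_COLUMNS = [
    "person_id", "item_id", "block_index", "trial_index", "correct", "rt_seconds",
]

# Substream tags (spawn keys) for the counter-based seed splitting.
_S_BANK, _S_COHORT, _S_SESSION, _S_PERSON = 11, 22, 33, 44

# misfit_lapse: persons above this ability quantile respond at chance.
LAPSE_ABILITY_QUANTILE = 0.75
PATHOLOGY_KINDS = ("none", "null_discrimination", "misfit_lapse", "misfit_inverted")


def _rng(seed, *key):
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


@dataclass(frozen=True)
class RTGenParams:
    """Fixed effects of the lognormal response-time generator (log-seconds).

    Defaults are the study conditions: a lexicality slowdown of 0.11 for
    pseudowords, a -0.021 speedup per unit log lexical frequency (real words
    only), a 0.035 slowdown per unit log bigram frequency (pseudowords
    only), 0.031 per letter of length, and a -0.010 length-by-ability
    interaction.  Variance components (person/item intercepts, residual) are
    package defaults chosen so the effects are recoverable at cohorts of
    about 100-150 persons.

    ``contam_rate`` of trials are contaminated: one third anticipations
    (median ``anticip_median_s``), two thirds attentional lapses (median
    ``lapse_median_s``).  These are what the absolute RT window and the
    per-person IQR fence exist to remove.
    """

    mu0: float = -0.30
    beta_lexicality: float = 0.11
    beta_log_frequency: float = -0.021
    beta_bigram_pseudo: float = 0.035
    beta_length: float = 0.031
    beta_length_x_ability: float = -0.010
    sd_person: float = 0.15
    sd_item: float = 0.10
    sd_resid: float = 0.25
    fast_median_s: float = 0.25
    fast_sd_log: float = 0.20
    contam_rate: float = 0.03
    anticip_median_s: float = 0.10
    lapse_median_s: float = 4.0
    contam_sd_log: float = 0.5


@dataclass(frozen=True)
class SessionDesign:
    """Block structure of one test session (defaults: 5 blocks of 50+50)."""

    n_blocks: int = 5
    real_per_block: int = 50
    pseudo_per_block: int = 50
    shuffle_within_block: bool = True
    seed: int = 0

    @property
    def n_trials(self) -> int:
        return self.n_blocks * (self.real_per_block + self.pseudo_per_block)


def _stratified_uniform(rng, lo, hi, n):
    """One uniform draw per equal-width bin, shuffled: covers [lo, hi] evenly."""
    edges = np.linspace(lo, hi, n + 1)
    vals = rng.uniform(edges[:-1], edges[1:])
    return rng.permutation(vals)


def _draw_discrimination(rng, spec, n):
    kind = spec.get("kind", "lognormal")
    if kind == "constant":
        return np.full(n, float(spec["value"]))
    if kind == "lognormal":
        return np.exp(rng.normal(math.log(spec.get("median", 1.2)),
                                 spec.get("sigma", 0.3), n))
    if kind == "uniform":
        return rng.uniform(spec["low"], spec["high"], n)
    raise ValueError(f"unknown discrimination distribution: {kind!r}")


def _random_string(rng, length):
    return "".join(rng.choice(list(_string.ascii_lowercase), size=length))


def generate_item_bank(n_real: int, n_pseudo: int,
                       difficulty_spread=(-3.0, 3.0),
                       discrimination_dist=None,
                       planted_bad_fraction: float = 0.0,
                       pathology_kinds=("null_discrimination", "misfit_lapse"),
                       length_range=(3, 10),
                       c_guess: float = 0.5,
                       id_prefix=("w", "p"),
                       seed: int = 0) -> pd.DataFrame:
    """Generate an item bank of real words and pseudowords.

    Difficulties are stratified across ``difficulty_spread`` within each
    lexicality class so both classes cover the full range.  Letter strings
    are arbitrary labels of the stated length; lexical frequency exists for
    real words only.  ``planted_bad_fraction`` of items (rounded) receive a
    pathology tag, cycling through ``pathology_kinds``.  Null-discrimination
    items have ``a_true = 0``; lapse items are forced easy (lower end of the
    difficulty spread) with a slope of at least 1.2, since only there can a
    guess-floored fit statistic see the lapses.
    """
    if n_real < 0 or n_pseudo < 0:
        raise ValueError("item counts must be nonnegative")
    n = n_real + n_pseudo
    if n == 0:
        raise ValueError("cannot generate an empty item bank")
    if not 0 <= planted_bad_fraction < 1:
        raise ValueError("planted_bad_fraction must be in [0, 1)")
    if discrimination_dist is None:
        discrimination_dist = {"kind": "lognormal", "median": 1.2, "sigma": 0.3}
    rng = _rng(seed, _S_BANK)

    lex = np.array(["real"] * n_real + ["pseudo"] * n_pseudo)
    b = np.concatenate([
        _stratified_uniform(rng, *difficulty_spread, n_real) if n_real else [],
        _stratified_uniform(rng, *difficulty_spread, n_pseudo) if n_pseudo else [],
    ]).astype(float)
    a = _draw_discrimination(rng, discrimination_dist, n)
    lengths = rng.integers(length_range[0], length_range[1] + 1, n)
    strings = [_random_string(rng, int(L)) for L in lengths]
    log_lex_freq = np.where(lex == "real", rng.normal(1.5, 1.2, n), np.nan)
    log_bigram = rng.normal(2.5, 0.8, n)
    log_trigram = rng.normal(2.0, 0.8, n)
    log_neighbor = rng.normal(1.0, 0.8, n)

    pathology = np.array(["none"] * n, dtype=object)
    n_bad = round(planted_bad_fraction * n)
    if n_bad:
        unknown = set(pathology_kinds) - set(PATHOLOGY_KINDS)
        if unknown:
            raise ValueError(f"unknown pathology kinds: {sorted(unknown)}")
        bad_idx = rng.choice(n, size=n_bad, replace=False)
        for j, idx in enumerate(np.sort(bad_idx)):
            pathology[idx] = pathology_kinds[j % len(pathology_kinds)]
        a[pathology == "null_discrimination"] = 0.0
        lapse = pathology == "misfit_lapse"
        if lapse.any():
            # lapses are only visible to outfit where the model is confident,
            # so lapse items sit at the very easy end with a steep slope
            lo, hi = difficulty_spread
            b[lapse] = lo + (0.02 + 0.06 * rng.random(int(lapse.sum()))) * (hi - lo)
            a[lapse] = np.maximum(a[lapse], 1.5)

    width = max(3, len(str(n)))
    item_id = [f"{id_prefix[0] if l == 'real' else id_prefix[1]}{i + 1:0{width}d}"
               for i, l in enumerate(lex)]
    bank = pd.DataFrame({
        "item_id": item_id, "string": strings, "lexicality": lex,
        "length": lengths.astype(int),
        "log_lexical_frequency": log_lex_freq,
        "log_bigram_frequency": log_bigram,
        "log_trigram_frequency": log_trigram,
        "log_neighbor_frequency": log_neighbor,
        "a_true": a, "b_true": b, "c_true": float(c_guess),
        "pathology": pathology,
    })
    return bank


def generate_cohort(n_persons: int,
                    ability_dist=None,
                    criterion_slope: float = 80.0 / 6.0,
                    criterion_intercept: float = 40.0,
                    criterion_noise_sd: float = 4.4,
                    missing_criterion_fraction: float = 0.0,
                    noncompliant_fraction: float = 0.0,
                    age_range=(6.0, 30.0),
                    seed: int = 0) -> pd.DataFrame:
    """Generate a person cohort with a criterion score linked to ability.

    ``criterion_true = intercept + slope * theta_true``;
    ``criterion_observed`` adds Gaussian measurement noise and may be
    missing for a configured fraction of persons.  Default slope/intercept
    map theta in [-3, 3] onto a 0-80 raw-score-like range; the default noise
    puts the latent validity near 0.95.  ``noncompliant_fraction`` of
    persons are flagged as fast random guessers.
    """
    if n_persons <= 0:
        raise ValueError("n_persons must be positive")
    for frac in (missing_criterion_fraction, noncompliant_fraction):
        if not 0 <= frac < 1:
            raise ValueError("fractions must be in [0, 1)")
    if criterion_slope == 0:
        logger.warning("criterion_slope = 0: criterion carries no ability signal")
    if ability_dist is None:
        ability_dist = {"kind": "normal", "mean": 0.0, "sd": 1.0}
    rng = _rng(seed, _S_COHORT)
    if ability_dist.get("kind", "normal") == "normal":
        theta = rng.normal(ability_dist.get("mean", 0.0),
                           ability_dist.get("sd", 1.0), n_persons)
    elif ability_dist["kind"] == "uniform":
        theta = rng.uniform(ability_dist["low"], ability_dist["high"], n_persons)
    else:
        raise ValueError(f"unknown ability distribution: {ability_dist['kind']!r}")
    ages = rng.uniform(age_range[0], age_range[1], n_persons)
    crit_true = criterion_intercept + criterion_slope * theta
    crit_obs = crit_true + rng.normal(0.0, criterion_noise_sd, n_persons) \
        if criterion_noise_sd > 0 else crit_true.copy()

    n_missing = round(missing_criterion_fraction * n_persons)
    if n_missing:
        crit_obs[rng.choice(n_persons, n_missing, replace=False)] = np.nan
    compliant = np.ones(n_persons, dtype=bool)
    n_bad = round(noncompliant_fraction * n_persons)
    if n_bad:
        compliant[rng.choice(n_persons, n_bad, replace=False)] = False

    width = max(3, len(str(n_persons)))
    return pd.DataFrame({
        "person_id": [f"s{i + 1:0{width}d}" for i in range(n_persons)],
        "theta_true": theta, "age_years": ages,
        "criterion_true": crit_true, "criterion_observed": crit_obs,
        "compliant": compliant,
    })


def _block_assignment(items: pd.DataFrame, design: SessionDesign, rng):
    """Assign bank items to blocks: shuffled within class, sliced per block."""
    real = items.index[items["lexicality"] == "real"].to_numpy()
    pseudo = items.index[items["lexicality"] == "pseudo"].to_numpy()
    need_r = design.n_blocks * design.real_per_block
    need_p = design.n_blocks * design.pseudo_per_block
    if len(real) < need_r or len(pseudo) < need_p:
        raise ValueError(
            f"design needs {need_r} real / {need_p} pseudo items; "
            f"bank has {len(real)} / {len(pseudo)}")
    real = rng.permutation(real)[:need_r]
    pseudo = rng.permutation(pseudo)[:need_p]
    blocks = []
    for blk in range(design.n_blocks):
        r = real[blk * design.real_per_block:(blk + 1) * design.real_per_block]
        p = pseudo[blk * design.pseudo_per_block:(blk + 1) * design.pseudo_per_block]
        blocks.append(np.concatenate([r, p]))
    return blocks


def simulate_session(items: pd.DataFrame, persons: pd.DataFrame,
                     design: SessionDesign | None = None,
                     rt_params: RTGenParams | None = None,
                     seed: int = 0) -> pd.DataFrame:
    """Simulate a full lexical-decision session (accuracy + response times).

    Accuracy: ``correct ~ Bernoulli(irf(theta, a, b, c))`` with the planted
    pathologies and non-compliance rules described in the module docstring.
    Response times: lognormal with the fixed effects in ``rt_params`` plus
    person and item random intercepts.

    Returns a long table, one row per (person, item) trial, with 1-based
    block and trial indices.
    """
    if items.empty or persons.empty:
        raise ValueError("item bank and cohort must be non-empty")
    design = design or SessionDesign(
        n_blocks=1,
        real_per_block=int((items["lexicality"] == "real").sum()),
        pseudo_per_block=int((items["lexicality"] == "pseudo").sum()),
    )
    rt_params = rt_params or RTGenParams()
    items = items.reset_index(drop=True)
    rng_sess = _rng(seed, _S_SESSION)
    blocks = _block_assignment(items, design, rng_sess)
    item_intercept = rng_sess.normal(0.0, rt_params.sd_item, len(items))

    theta = persons["theta_true"].to_numpy()
    theta_median = float(np.median(theta))
    theta_q_lapse = float(np.quantile(theta, LAPSE_ABILITY_QUANTILE))

    used = np.concatenate(blocks)
    it = items.loc[used]
    a = it["a_true"].to_numpy()
    b = it["b_true"].to_numpy()
    c = it["c_true"].to_numpy()
    pseudo = (it["lexicality"] == "pseudo").to_numpy().astype(float)
    length = it["length"].to_numpy(dtype=float)
    logfreq = np.nan_to_num(it["log_lexical_frequency"].to_numpy(), nan=0.0)
    logbigram = it["log_bigram_frequency"].to_numpy()
    inverted = (it["pathology"] == "misfit_inverted").to_numpy()
    lapsing = (it["pathology"] == "misfit_lapse").to_numpy()
    item_ids = it["item_id"].to_numpy()
    item_int = item_intercept[used]
    block_of_trial = np.concatenate(
        [np.full(len(blk), i + 1) for i, blk in enumerate(blocks)])

    fixed_logrt = (rt_params.mu0
                   + rt_params.beta_lexicality * pseudo
                   + rt_params.beta_log_frequency * logfreq * (1 - pseudo)
                   + rt_params.beta_bigram_pseudo * logbigram * pseudo
                   + rt_params.beta_length * length
                   + item_int)

    rows = []
    n_items = len(used)
    for i, person in persons.reset_index(drop=True).iterrows():
        prng = _rng(seed, _S_PERSON, i)
        th = person["theta_true"]
        if person["compliant"]:
            P = irf(th, a, b, c)
            if th > theta_median:
                P = np.where(inverted, 1.0 - P, P)
            if th > theta_q_lapse:
                P = np.where(lapsing, 0.5, P)
            logrt = (fixed_logrt
                     + rt_params.beta_length_x_ability * length * th
                     + prng.normal(0.0, rt_params.sd_person)
                     + prng.normal(0.0, rt_params.sd_resid, n_items))
            if rt_params.contam_rate > 0:
                contam = prng.random(n_items) < rt_params.contam_rate
                slow = prng.random(n_items) < 2.0 / 3.0
                med = np.where(slow, rt_params.lapse_median_s,
                               rt_params.anticip_median_s)
                contam_logrt = (np.log(med)
                                + prng.normal(0.0, rt_params.contam_sd_log, n_items))
                logrt = np.where(contam, contam_logrt, logrt)
        else:
            P = np.full(n_items, 0.5)
            logrt = (math.log(rt_params.fast_median_s)
                     + prng.normal(0.0, rt_params.fast_sd_log, n_items))
        correct = (prng.random(n_items) < P).astype(int)
        rt = np.exp(logrt)
        # per-person presentation order within each block
        order = np.arange(n_items)
        if design.shuffle_within_block:
            order = np.concatenate([
                prng.permutation(np.flatnonzero(block_of_trial == blk + 1))
                for blk in range(design.n_blocks)])
        rows.append(pd.DataFrame({
            "person_id": person["person_id"],
            "item_id": item_ids[order],
            "block_index": block_of_trial[order],
            "trial_index": np.arange(1, n_items + 1),
            "correct": correct[order],
            "rt_seconds": rt[order],
        }))
    out = pd.concat(rows, ignore_index=True)
    return out[RESPONSE_COLUMNS]


def rt_params_to_dict(params: RTGenParams) -> dict:
    return asdict(params)
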