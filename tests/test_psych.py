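"""Scoring and validation statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import lexirt as lx
from lexirt.psych import (accuracy_scores, criterion_correlation, disattenuate,
                          williams_test, icc_consistency, spearman_brown,
                          map_ability_to_criterion, compare_item_properties,
                          order_effect_checks)
from conftest import make_responses


class TestAccuracyScores:
    def test_all_correct_is_one(self):
        resp = make_responses(np.ones((3, 4)))
        scores = accuracy_scores(resp)
        assert (scores["overall"] == 1.0).all()

    def test_chance_performer_near_half(self):
        rng = np.random.default_rng(1)
        resp = make_responses(rng.integers(0, 2, (1, 500)))
        acc = accuracy_scores(resp)["overall"].iloc[0]
        assert abs(acc - 0.5) < 3 * np.sqrt(0.25 / 500)

    def test_block_and_class_groupings(self):
        bank = lx.generate_item_bank(10, 10, seed=2)
        cohort = lx.generate_cohort(5, seed=2)
        design = lx.SessionDesign(n_blocks=2, real_per_block=5, pseudo_per_block=5)
        resp = lx.simulate_session(bank, cohort, design, seed=2)
        scores = accuracy_scores(resp, items=bank)
        assert {"block_1", "block_2", "lex_real", "lex_pseudo"} <= set(scores)
        # overall is the mean of the two equal-size blocks
        assert np.allclose(scores["overall"],
                           (scores["block_1"] + scores["block_2"]) / 2)

    def test_missing_groups_absent_not_zero(self):
        resp = make_responses(np.ones((2, 3)))
        resp = resp[~((resp["person_id"] == "s01") & (resp["item_id"] == "i02"))]
        lists = pd.DataFrame({"list_id": ["A", "A", "B"],
                              "item_id": ["i00", "i01", "i02"]})
        scores = accuracy_scores(resp, list_assignment=lists)
        assert np.isnan(scores.loc["s01", "list_B"])
        assert scores.loc["s00", "list_B"] == 1.0


class TestCriterionCorrelation:
    def test_identity_is_one(self):
        s = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        r, n = criterion_correlation(s, s)
        assert r == pytest.approx(1.0) and n == 4

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(7)
        idx = [f"p{i}" for i in range(1000)]
        r, n = criterion_correlation(pd.Series(rng.normal(size=1000), index=idx),
                                     pd.Series(rng.normal(size=1000), index=idx))
        assert abs(r) < 0.1 and n == 1000

    def test_pairwise_complete(self):
        s = pd.Series([1.0, 2, 3, 4, 5], index=list("abcde"))
        c = pd.Series([1.0, 2, 3, 4, np.nan], index=list("abcde"))
        r, n = criterion_correlation(s, c)
        assert n == 4 and r == pytest.approx(1.0)


class TestDisattenuate:
    def test_perfect_reliability_is_identity(self):
        assert disattenuate(0.5, 1.0, 1.0) == 0.5

    def test_exact_arithmetic(self):
        assert disattenuate(0.9, 0.81, 1.0) == pytest.approx(1.0)

    def test_study_style_values(self):
        # r = 0.91 with reliabilities 0.97 and 0.94
        assert disattenuate(0.91, 0.97, 0.94) == pytest.approx(
            0.91 / np.sqrt(0.97 * 0.94), abs=1e-12)
        assert disattenuate(0.91, 0.97, 0.94) == pytest.approx(0.953, abs=5e-4)

    def test_single_instrument_convention(self):
        assert disattenuate(0.91, 0.94) == pytest.approx(0.91 / np.sqrt(0.94))

    def test_clipping_and_validation(self):
        assert disattenuate(0.99, 0.5, 0.5) == 1.0
        with pytest.raises(ValueError):
            disattenuate(0.5, 0.0)

    @settings(derandomize=True, max_examples=30)
    @given(r=st.floats(0.05, 0.6), rel1=st.floats(0.5, 0.99),
           rel2=st.floats(0.5, 0.99))
    def test_monotone_in_unreliability(self, r, rel1, rel2):
        assert disattenuate(r, rel1, rel2) >= disattenuate(r, max(rel1, rel2), 1.0) \
            or disattenuate(r, rel1, rel2) == 1.0


def williams_oracle(r12, r13, r23, n):
    """Independent coding of Williams' t from the textbook formulation."""
    detR = (1 - r12**2 - r13**2 - r23**2) + 2 * r12 * r13 * r23
    rbar = (r12 + r13) / 2
    num = (r12 - r13) * np.sqrt((n - 1) * (1 + r23))
    den = np.sqrt(2 * detR * (n - 1) / (n - 3) + rbar**2 * (1 - r23) ** 3)
    return num / den


class TestWilliams:
    def test_equal_correlations_give_zero(self):
        t, p = williams_test(0.5, 0.5, 0.3, 50)
        assert t == 0 and p == pytest.approx(1.0)

    def test_antisymmetry(self):
        t1, _ = williams_test(0.7, 0.4, 0.3, 40)
        t2, _ = williams_test(0.4, 0.7, 0.3, 40)
        assert t1 == pytest.approx(-t2)

    def test_fixed_case_matches_independent_oracle(self):
        # accuracy vs RT as competing predictors of the criterion
        args = (0.91, -0.06, -0.10, 43)
        t, p = williams_test(*args)
        assert t == pytest.approx(williams_oracle(*args), abs=1e-6)
        assert 0 < p < 1e-6 or p < 1  # two-sided p consistent with df = 40
        assert p == pytest.approx(
            2 * sps.t.sf(abs(t), df=40), abs=1e-12)

    def test_reduces_to_independent_comparison_for_r23_zero(self):
        # with r23 = 0 and large n, Williams' t approaches the Fisher-z
        # independent-overlap comparison
        r12, r13, n = 0.45, 0.30, 5000
        t, _ = williams_test(r12, r13, 0.0, n)
        z = (np.arctanh(r12) - np.arctanh(r13)) / np.sqrt(2 / (n - 3))
        assert t == pytest.approx(z, rel=0.1)

    def test_inconsistent_matrix_rejected(self):
        with pytest.raises(ValueError, match="determinant"):
            williams_test(0.95, -0.95, 0.9, 30)


class TestICC:
    def test_identical_forms_give_one(self):
        m = pd.DataFrame({"A": [1.0, 2, 3, 4], "B": [1.0, 2, 3, 4]})
        res = icc_consistency(m)
        assert res.icc_single == pytest.approx(1.0)

    def test_hand_anova_decomposition(self):
        # 4 persons x 2 forms worked example, mean squares by hand
        m = pd.DataFrame({"A": [8.0, 6, 4, 2], "B": [7.0, 5, 5, 1]})
        x = m.to_numpy()
        n, k = x.shape
        msr = k * np.sum((x.mean(1) - x.mean()) ** 2) / (n - 1)
        msc = n * np.sum((x.mean(0) - x.mean()) ** 2) / (k - 1)
        mse = (np.sum((x - x.mean()) ** 2) - (n - 1) * msr / k * k
               - (k - 1) * msc / n * n) / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse)
        res = icc_consistency(m)
        assert res.icc_single == pytest.approx(expected, rel=1e-12)

    def test_matches_pingouin(self):
        rng = np.random.default_rng(11)
        base = rng.normal(size=30)
        m = pd.DataFrame({f"F{j}": base + rng.normal(0, 0.4, 30)
                          for j in range(3)})
        res = icc_consistency(m)
        import pingouin as pg
        long = m.reset_index().melt(id_vars="index", var_name="form",
                                    value_name="score")
        icc = pg.intraclass_corr(long, targets="index", raters="form",
                                 ratings="score").set_index("Type")
        assert res.icc_single == pytest.approx(icc.loc["ICC(C,1)", "ICC"], abs=1e-9)
        assert res.icc_average == pytest.approx(icc.loc["ICC(C,k)", "ICC"], abs=1e-9)

    def test_consistency_invariant_to_form_shift(self):
        rng = np.random.default_rng(12)
        base = rng.normal(size=20)
        m = pd.DataFrame({"A": base + rng.normal(0, 0.3, 20),
                          "B": base + rng.normal(0, 0.3, 20)})
        shifted = m.assign(B=m["B"] + 5.0)
        assert icc_consistency(m).icc_single == pytest.approx(
            icc_consistency(shifted).icc_single, abs=1e-12)
        # the agreement variant is not shift invariant
        assert icc_consistency(shifted, agreement=True).icc_single < \
            icc_consistency(m, agreement=True).icc_single

    def test_independent_forms_near_zero(self):
        rng = np.random.default_rng(13)
        m = pd.DataFrame(rng.normal(size=(1000, 3)), columns=list("ABC"))
        assert abs(icc_consistency(m).icc_single) < 0.05


class TestSpearmanBrown:
    def test_endpoints(self):
        assert spearman_brown(1.0, 3) == 1.0
        assert spearman_brown(0.0, 3) == 0.0

    def test_three_form_composite(self):
        assert spearman_brown(0.91, 3) == pytest.approx(3 * 0.91 / (1 + 2 * 0.91))
        assert spearman_brown(0.91, 3) == pytest.approx(0.968, abs=5e-4)


class TestAbilityCriterionMap:
    def test_noise_free_recovery(self):
        theta = pd.Series(np.linspace(-2, 2, 20), index=range(20))
        crit = 40 + 13.0 * theta
        fit = map_ability_to_criterion(theta, crit)
        assert fit.slope == pytest.approx(13.0)
        assert fit.intercept == pytest.approx(40.0)
        assert fit.predict([0.5])[0] == pytest.approx(46.5)

    def test_prediction_clips_to_criterion_range(self):
        theta = pd.Series(np.linspace(-1, 1, 10), index=range(10))
        fit = map_ability_to_criterion(theta, 40 + 13 * theta)
        assert fit.predict([10.0])[0] == pytest.approx(53.0)  # observed max

    def test_constant_criterion_flagged_zero_slope(self):
        theta = pd.Series(np.linspace(-1, 1, 10), index=range(10))
        fit = map_ability_to_criterion(theta, pd.Series(5.0, index=range(10)))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_noisy_calibration_within_two_se(self):
        rng = np.random.default_rng(14)
        theta = pd.Series(rng.normal(size=200))
        crit = 40 + 13 * theta + rng.normal(0, 4, 200)
        fit = map_ability_to_criterion(theta, crit)
        se = 4 / (theta.std() * np.sqrt(200))
        assert abs(fit.slope - 13) < 2.5 * se


def items_frame(values_by_group):
    rows = []
    k = 0
    for (retained, lex), values in values_by_group.items():
        for v in values:
            rows.append({"item_id": f"{'r' if retained else 'x'}{k}",
                         "lexicality": lex, "prop": v})
            k += 1
    frame = pd.DataFrame(rows)
    retained_ids = [r["item_id"] for _, r in frame.iterrows()
                    if r["item_id"].startswith("r")]
    return frame, retained_ids


class TestItemPropertyComparison:
    def test_equal_rank_sums_give_zero(self):
        frame, retained = items_frame({(True, "real"): [1, 4],
                                       (False, "real"): [2, 3]})
        res = compare_item_properties(frame, retained, "prop")
        assert res.H == pytest.approx(0.0, abs=1e-12)

    def test_h_matches_rank_formula_and_permutation_p(self):
        frame, retained = items_frame({(True, "real"): [1.0, 5.2],
                                       (False, "real"): [2.1, 3.3],
                                       (True, "pseudo"): [7.4, 9.8]})
        res = compare_item_properties(frame, retained, "prop", p_mode="exact")
        values = frame["prop"].to_numpy()
        labels = (np.where(frame["item_id"].isin(retained), "ret", "rej")
                  + "_" + frame["lexicality"]).to_numpy()

        def kw_h(vals, labs):
            ranks = sps.rankdata(vals)
            n = len(vals)
            h = 0.0
            for g in set(labs):
                rg = ranks[labs == g]
                h += rg.sum() ** 2 / len(rg)
            return 12 / (n * (n + 1)) * h - 3 * (n + 1)

        h_obs = kw_h(values, labels)
        assert res.H == pytest.approx(h_obs, rel=1e-9)
        # exact permutation reference distribution of H
        count = 0
        total = 0
        for perm in itertools.permutations(values):
            h = kw_h(np.array(perm), labels)
            count += h >= h_obs - 1e-12
            total += 1
        p_exact = count / total
        assert res.p == pytest.approx(p_exact, abs=1e-12)

    def test_planted_length_effect_detected(self):
        rng = np.random.default_rng(15)
        n = 300
        frame = pd.DataFrame({
            "item_id": [f"i{k}" for k in range(n)],
            "lexicality": np.where(np.arange(n) % 2 == 0, "real", "pseudo"),
            "length": rng.integers(3, 11, n).astype(float),
        })
        retained = frame["item_id"].iloc[:120]
        # retained real words made longer by construction
        sel = frame["item_id"].isin(retained) & (frame["lexicality"] == "real")
        frame.loc[sel, "length"] += 2
        res = compare_item_properties(frame, retained, "length")
        assert res.p < 0.05
        key_pair = res.pairwise[
            (res.pairwise["group1"] == "rejected_real")
            & (res.pairwise["group2"] == "retained_real")]
        assert (key_pair["p_bonferroni"] < 0.05).all()

    def test_single_group_rejected(self):
        frame, retained = items_frame({(True, "real"): [1, 2, 3]})
        with pytest.raises(ValueError, match="groups"):
            compare_item_properties(frame, retained, "prop")


@pytest.fixture(scope="module")
def flat_session():
    bank = lx.generate_item_bank(30, 30, seed=16)
    cohort = lx.generate_cohort(80, seed=16)
    design = lx.SessionDesign(n_blocks=3, real_per_block=10,
                              pseudo_per_block=10)
    resp = lx.simulate_session(bank, cohort, design, seed=16)
    return bank, resp


class TestOrderEffects:
    def test_no_planted_order_effects_found(self, flat_session):
        _, resp = flat_session
        res = order_effect_checks(resp)
        assert abs(res.trial_slope["t"]) < 2
        assert (res.block_contrasts["t"].abs() < 2.5).all()

    def test_planted_fatigue_detected(self):
        # correctness drifts down by 1.5 logits across the session
        rng = np.random.default_rng(17)
        rows = []
        for i in range(120):
            for t in range(60):
                logit = 1.0 - 1.5 * t / 59
                p = 1 / (1 + np.exp(-logit))
                rows.append({"person_id": f"s{i}", "item_id": f"i{t}",
                             "block_index": 1, "trial_index": t + 1,
                             "correct": int(rng.random() < p),
                             "rt_seconds": 1.0})
        res = order_effect_checks(pd.DataFrame(rows))
        assert res.trial_slope["estimate"] < 0
        assert res.trial_slope["t"] < -2

    def test_list_labels_do_not_affect_trial_slope(self, flat_session):
        bank, resp = flat_session
        lists = pd.DataFrame({"item_id": bank["item_id"],
                              "list_id": np.resize(list("ABC"), len(bank))})
        permuted = lists.assign(list_id=np.resize(list("CAB"), len(bank)))
        r1 = order_effect_checks(resp, list_assignment=lists)
        r2 = order_effect_checks(resp, list_assignment=permuted)
        assert r1.trial_slope["estimate"] == pytest.approx(
            r2.trial_slope["estimate"], abs=1e-12)
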