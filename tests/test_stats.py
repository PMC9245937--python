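"""Rank correlations, adjusted models, stratified analyses, contrasts."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from synapcover.cohort import CohortConfig, records_to_frame, simulate_cohort
from synapcover.errors import (
    CollinearityError,
    InvalidInputError,
    MissingOutcomeError,
    UndefinedCorrelationError,
)
from synapcover.stats import (
    fit_adjusted_model,
    group_contrast,
    spearman,
    stratified_correlations,
)


class TestSpearman:
    def test_hand_oracle(self):
        # ranks (1,2,3,4) vs (2,1,4,3): Σd² = 4 → r = 1 − 24/60 = 0.6
        assert spearman([1, 2, 3, 4], [2, 1, 4, 3]).estimate == pytest.approx(0.6)

    def test_perfect_monotone_transform(self):
        assert spearman([1, 2, 3, 4], [3, 5, 7, 9]).estimate == pytest.approx(1.0)
        assert spearman([1, 2, 3], [-1, -8, -27]).estimate == pytest.approx(-1.0)

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_exact_p_matches_brute_force_enumeration(self, n):
        rng = np.random.default_rng(n)
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        result = spearman(x, y)
        ranks_x = sps.rankdata(x)
        hits = total = 0
        for perm in itertools.permutations(range(1, n + 1)):
            r_perm = np.corrcoef(ranks_x, perm)[0, 1]
            total += 1
            if abs(r_perm) >= abs(result.estimate) - 1e-12:
                hits += 1
        assert result.p_value == pytest.approx(hits / total)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal(30), rng.standard_normal(30)
        assert spearman(x, y).estimate == pytest.approx(spearman(y, x).estimate)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_under_increasing_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(20)
        y = rng.standard_normal(20)
        base = spearman(x, y).estimate
        assert spearman(np.exp(x), y).estimate == pytest.approx(base)
        assert spearman(x, 5 * y + 2).estimate == pytest.approx(base)

    def test_pairwise_complete_nan_handling(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 4.0, 6.0, np.nan, 10.0]
        result = spearman(x, y)
        assert result.n == 3
        assert result.estimate == pytest.approx(1.0)

    def test_constant_vector_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_few_pairs_raises(self):
        with pytest.raises(InvalidInputError):
            spearman([1, 2], [3, 4])

    def test_copula_cohort_recovery_at_study_n(self):
        from synapcover.cohort import _default_marginals, simulate_stratum

        marginals = _default_marginals()["DRB15_neg"]
        rng = np.random.default_rng(99)
        estimates = []
        for _ in range(300):
            block = simulate_stratum(47, {"iba1": 0.548}, marginals, rng)
            estimates.append(
                spearman(block["iba1"], block["neuron_density"]).estimate)
        assert np.mean(estimates) == pytest.approx(0.548, abs=0.03)


class TestFitAdjustedModel:
    def _frame(self, n, rng, slope=0.0):
        x = rng.standard_normal(n)
        covs = dict(age=rng.normal(60, 10, n),
                    sex=rng.choice(["M", "F"], n),
                    pmi=rng.normal(18, 5, n))
        y = slope * x + np.sqrt(max(1 - slope**2, 0.05)) * rng.standard_normal(n)
        return pd.DataFrame(dict(y=y, x=x, **covs))

    def test_planted_standardized_effect_recovered(self):
        rng = np.random.default_rng(0)
        betas = [fit_adjusted_model("y", "x", ["age", "sex", "pmi"],
                                    self._frame(26, rng, slope=0.5),
                                    transform="none").estimate
                 for _ in range(400)]
        assert np.mean(betas) == pytest.approx(0.5, abs=0.05)

    def test_null_slope_gives_uniform_p(self):
        rng = np.random.default_rng(1)
        ps = [fit_adjusted_model("y", "x", ["age", "sex", "pmi"],
                                 self._frame(30, rng), transform="none").p_value
              for _ in range(400)]
        assert 0.03 <= np.mean(np.array(ps) < 0.05) <= 0.07

    def test_confounder_shifts_estimate_in_planted_direction(self):
        rng = np.random.default_rng(2)
        n = 200
        confounder = rng.standard_normal(n)
        x = confounder + 0.5 * rng.standard_normal(n)
        y = confounder + 0.5 * rng.standard_normal(n)  # x–y link only via confounder
        frame = pd.DataFrame(dict(y=y, x=x, c=confounder))
        naive = fit_adjusted_model("y", "x", [], frame, transform="none").estimate
        adjusted = fit_adjusted_model("y", "x", ["c"], frame,
                                      transform="none").estimate
        assert naive > adjusted + 0.2

    def test_rank_deficient_design_names_aliased_terms(self):
        rng = np.random.default_rng(3)
        frame = self._frame(30, rng)
        frame["age_copy"] = frame["age"]
        with pytest.raises(CollinearityError) as exc:
            fit_adjusted_model("y", "x", ["age", "age_copy"], frame,
                               transform="none")
        assert any("age" in name for name in exc.value.aliased)

    def test_log_transform_triggered_by_skewed_outcome(self):
        rng = np.random.default_rng(4)
        n = 60
        frame = pd.DataFrame(dict(
            y=np.exp(rng.normal(0, 1.2, n)),  # log-normal: W_raw low, W_log high
            x=rng.standard_normal(n),
        ))
        result = fit_adjusted_model("y", "x", [], frame)
        assert result.transform == "log"

    def test_residuals_orthogonal_to_design(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        frame = self._frame(50, rng, slope=0.3)
        X = pd.DataFrame(dict(const=1.0, x=frame.x, age=frame.age))
        fit = sm.OLS(frame.y, X).fit()
        assert np.abs(X.to_numpy().T @ fit.resid.to_numpy()).max() < 1e-8

    def test_insufficient_n_raises(self):
        rng = np.random.default_rng(6)
        with pytest.raises(InvalidInputError):
            fit_adjusted_model("y", "x", ["age", "sex", "pmi"],
                               self._frame(6, rng), transform="none")


class TestStratifiedCorrelations:
    def test_single_stratum_equals_unstratified(self):
        frame = records_to_frame(simulate_cohort(CohortConfig(seed=2)))
        ms = frame[frame.genotype == "DRB15_neg"]
        strat = stratified_correlations(ms, ["iba1"], "neuron_density",
                                        "genotype")
        assert len(strat) == 1
        direct = spearman(ms["iba1"], ms["neuron_density"])
        assert strat[0].estimate == pytest.approx(direct.estimate)
        assert strat[0].stratum == "DRB15_neg"

    def test_empty_marker_list_gives_empty_results(self):
        frame = records_to_frame(simulate_cohort(CohortConfig(seed=2)))
        assert stratified_correlations(frame, [], "neuron_density") == []

    def test_planted_genotype_difference_is_recovered(self):
        # strong link in non-carriers, none in carriers: estimates separate
        gaps = []
        for seed in range(60):
            frame = records_to_frame(simulate_cohort(CohortConfig(seed=seed)))
            ms = frame[frame.group == "MS"]
            res = {r.stratum: r.estimate
                   for r in stratified_correlations(ms, ["iba1"],
                                                    "neuron_density")}
            gaps.append(res["DRB15_neg"] - res["DRB15_pos"])
        assert np.mean(gaps) > 0.4

    def test_small_stratum_skipped(self):
        frame = pd.DataFrame(dict(
            genotype=["a"] * 10 + ["b"] * 2,
            m=np.random.default_rng(0).random(12),
            y=np.random.default_rng(1).random(12),
        ))
        results = stratified_correlations(frame, ["m"], "y")
        assert {r.stratum for r in results} == {"a"}


class TestGroupContrast:
    def test_printed_group_means_arithmetic(self):
        frame = pd.DataFrame(dict(group=["control"] * 7 + ["MS"] * 20,
                                  v=[0.348] * 7 + [0.299] * 20))
        gc = group_contrast(frame, "v", "control", "MS")
        assert gc.percent_difference == pytest.approx(14.08, abs=0.05)
        frame2 = pd.DataFrame(dict(group=["control"] * 7 + ["MS"] * 20,
                                   v=[531.0] * 7 + [403.0] * 20))
        gc2 = group_contrast(frame2, "v", "control", "MS")
        assert gc2.percent_difference == pytest.approx(24.1, abs=0.05)

    def test_identical_groups_null_contrast(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(10, 1, 15)
        frame = pd.DataFrame(dict(group=["a"] * 15 + ["b"] * 15,
                                  v=np.concatenate([vals, vals])))
        gc = group_contrast(frame, "v", "a", "b")
        assert gc.percent_difference == pytest.approx(0.0, abs=1e-12)
        assert gc.adjusted_p > 0.99

    def test_missing_outcome_for_group_raises(self):
        frame = pd.DataFrame(dict(group=["a", "a", "b", "b"],
                                  v=[1.0, 2.0, np.nan, np.nan]))
        with pytest.raises(MissingOutcomeError):
            group_contrast(frame, "v", "a", "b")

    def test_sems_accompany_means(self):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame(dict(group=["a"] * 20 + ["b"] * 20,
                                  v=np.r_[rng.normal(10, 2, 20),
                                          rng.normal(8, 2, 20)]))
        gc = group_contrast(frame, "v", "a", "b")
        assert gc.sem_a == pytest.approx(
            frame[frame.group == "a"].v.std(ddof=1) / np.sqrt(20))
        assert gc.n_a == gc.n_b == 20
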