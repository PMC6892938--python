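"""Polygenic transmission disequilibrium test and liability-model power."""

import math

import numpy as np
import pytest
from scipy import stats

from sibcnv.ptdt import (
    LiabilityModelParams,
    PrsWeights,
    PtdtError,
    TrioPrs,
    _ascertained_trios,
    compute_prs,
    estimate_power,
    estimate_type1_error,
    ptdt_deviations,
    ptdt_test,
    simulate_liability_cohort,
)


def trio(child, mother, father, i=0, group="proband"):
    return TrioPrs(f"F{i}", f"C{i}", group, child, mother, father)


class TestComputePrs:
    weights = PrsWeights({"v1": 0.5, "v2": -0.2}, {"v1": 0.01, "v2": 0.05})

    def test_zero_dosages(self):
        assert compute_prs({"v1": 0.0, "v2": 0.0}, self.weights).score == 0.0

    def test_weighted_sum(self):
        res = compute_prs({"v1": 1.0, "v2": 2.0}, self.weights)
        assert res.score == pytest.approx(0.5 * 1 - 0.2 * 2)
        assert res.n_variants == 2

    def test_single_variant(self):
        w = PrsWeights({"v1": 0.5})
        assert compute_prs({"v1": 2.0}, w).score == pytest.approx(1.0)

    def test_gwas_p_threshold_excludes_variants(self):
        w = PrsWeights({"v1": 0.5, "v2": 10.0}, {"v1": 0.01, "v2": 0.5}, p_threshold=0.1)
        res = compute_prs({"v1": 2.0, "v2": 2.0}, w)
        assert res.score == pytest.approx(1.0)  # v2 fails the p cut

    def test_missing_dosage_skipped_and_counted(self):
        res = compute_prs({"v1": 1.0}, self.weights)
        assert res.n_skipped == 1

    def test_no_overlap_is_error(self):
        with pytest.raises(PtdtError, match="no overlap"):
            compute_prs({"other": 1.0}, self.weights)


class TestDeviations:
    def test_children_at_midparent_give_zero(self):
        trios = [trio(0.5, 0.0, 1.0, 0), trio(1.0, 1.0, 1.0, 1), trio(-1.0, 0.0, -2.0, 2)]
        assert ptdt_deviations(trios) == pytest.approx([0.0, 0.0, 0.0])

    def test_hand_computed_two_trios(self):
        # midparents {0, 1}: SD = 0.7071; children both 0.5
        trios = [trio(0.5, 0.0, 0.0, 0), trio(0.5, 1.0, 1.0, 1)]
        dev = ptdt_deviations(trios)
        assert dev == pytest.approx([math.sqrt(2) / 2, -math.sqrt(2) / 2])

    def test_equal_midparents_is_error(self):
        with pytest.raises(PtdtError, match="degenerate"):
            ptdt_deviations([trio(0.1, 0.5, 0.5, 0), trio(0.2, 0.0, 1.0, 1)])

    def test_needs_two_trios(self):
        with pytest.raises(PtdtError):
            ptdt_deviations([trio(0.1, 0.0, 0.0)])


class TestPtdtTest:
    def test_symmetric_deviations_give_t_zero(self):
        res = ptdt_test([-0.4, 0.4, -0.7, 0.7])
        assert res.t_stat == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.mean_deviation == pytest.approx(0.0)

    def test_zero_variance_is_error(self):
        with pytest.raises(PtdtError, match="variance"):
            ptdt_test([0.3, 0.3, 0.3])

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(0)
        dev = rng.normal(0.2, 1.0, 50)
        res = ptdt_test(dev)
        ref = stats.ttest_1samp(dev, 0.0)
        assert res.t_stat == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)


class TestLiabilityModel:
    def test_parameter_validation(self):
        with pytest.raises(PtdtError):
            LiabilityModelParams(prevalence_K=0.0)
        with pytest.raises(PtdtError, match="exceed"):
            LiabilityModelParams(h2g=0.1, r2_prs=0.2)

    def test_seed_is_required(self):
        with pytest.raises(PtdtError, match="seed"):
            simulate_liability_cohort(LiabilityModelParams(), 10, None)

    def test_prevalence_matches_k(self):
        params = LiabilityModelParams()
        _, affected = simulate_liability_cohort(params, 400_000, seed=3)
        rate = np.mean(affected)
        se = math.sqrt(params.prevalence_K * (1 - params.prevalence_K) / 400_000)
        assert abs(rate - params.prevalence_K) < 4 * se

    def test_child_variance_decomposition(self):
        trios, _ = simulate_liability_cohort(LiabilityModelParams(), 200_000, seed=4)
        child = np.array([t.prs_child for t in trios])
        mid = np.array([(t.prs_mother + t.prs_father) / 2 for t in trios])
        assert child.var() == pytest.approx(1.0, abs=0.02)
        assert mid.var() == pytest.approx(0.5, abs=0.02)
        assert (child - mid).var() == pytest.approx(0.5, abs=0.02)

    def test_null_r2_decouples_affection_from_prs(self):
        params = LiabilityModelParams(r2_prs=1e-9)
        rng = np.random.default_rng(5)
        mid, child = _ascertained_trios(rng, params, 30_000)
        dev = child - mid
        assert abs(dev.mean()) < 4 * dev.std() / math.sqrt(dev.size)

    def test_ascertained_mean_matches_truncated_normal_expectation(self):
        """E[child - midparent | affected] = cov(dev, L) * phi(z)/K."""
        params = LiabilityModelParams()
        rng = np.random.default_rng(6)
        mid, child = _ascertained_trios(rng, params, 60_000)
        dev = child - mid
        z = params.liability_threshold
        expected = (math.sqrt(params.r2_prs) / 2) * (
            stats.norm.pdf(z) / params.prevalence_K
        )
        assert abs(dev.mean() - expected) < 3 * dev.std() / math.sqrt(dev.size)


class TestPower:
    def test_size_under_null(self):
        est = estimate_type1_error(LiabilityModelParams(), 100, 2000, seed=8)
        assert 0.035 <= est.power <= 0.065

    def test_power_increases_with_n(self):
        params = LiabilityModelParams()
        small = estimate_power(params, 30, 400, seed=9)
        large = estimate_power(params, 189, 400, seed=10)
        assert large.power > small.power + 0.2

    def test_power_agrees_with_noncentral_t(self):
        """MC power matches a noncentral-t computation fed by an independent
        draw of ascertained trios."""
        params = LiabilityModelParams()
        n = 189
        rng = np.random.default_rng(11)
        mid, child = _ascertained_trios(rng, params, 100_000)
        sdev = (child - mid) / mid.std(ddof=1)
        ncp = math.sqrt(n) * sdev.mean() / sdev.std(ddof=1)
        tc = stats.t.ppf(0.975, n - 1)
        analytic = stats.nct.sf(tc, n - 1, ncp) + stats.nct.cdf(-tc, n - 1, ncp)
        mc = estimate_power(params, n, 1000, seed=12)
        assert mc.power == pytest.approx(analytic, abs=3 * mc.mc_se + 0.01)

    def test_rep_count_guard(self):
        with pytest.raises(PtdtError):
            estimate_power(LiabilityModelParams(), 189, 10, seed=1)
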