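"""Unit tests for the combination statistics against independent oracles."""

import mpmath
import numpy as np
import pytest
from scipy.stats import cauchy, combine_pvalues

from pvcomb.combine import (
    PValueVector,
    cauchy_transform,
    cct_pvalue,
    cmc_pvalue,
    fisher_pvalue,
    mcm_pvalue,
    minp_pvalue,
    stouffer_pvalue,
)


def mp_cct(values, dps=50):
    """High-precision oracle for the equal-weight Cauchy combination."""
    with mpmath.workdps(dps):
        ts = [mpmath.tan((mpmath.mpf("0.5") - mpmath.mpf(str(v))) * mpmath.pi) for v in values]
        t = mpmath.fsum(ts) / len(ts)
        return float(mpmath.mpf("0.5") - mpmath.atan(t) / mpmath.pi)


class TestCauchyTransform:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.5, 0.0), (0.25, 1.0), (0.75, -1.0)],
    )
    def test_quartile_values(self, p, expected):
        assert cauchy_transform(p) == pytest.approx(expected, abs=1e-12)

    def test_antisymmetry_is_exact_for_representable_complements(self):
        # dyadic p: 1 - p is exact, so the reflection branches agree bitwise
        for p in (0.25, 0.375, 0.015625, 0.46875):
            assert cauchy_transform(p) == -cauchy_transform(1.0 - p)

    def test_antisymmetry_holds_to_rounding(self):
        for p in (0.1, 0.3, 0.49, 0.007):
            t = cauchy_transform(p)
            assert t == pytest.approx(-cauchy_transform(1.0 - p), rel=1e-12)

    def test_strictly_decreasing(self):
        ps = np.linspace(0.001, 0.999, 200)
        assert (np.diff(cauchy_transform(ps)) < 0).all()

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5, np.nan])
    def test_domain_error_names_value(self, bad):
        with pytest.raises(ValueError, match="cauchy_transform"):
            cauchy_transform(bad)

    @pytest.mark.parametrize("p", [1e-5, 1e-12, 1e-14, 1e-16, 1e-100, 1e-300])
    def test_small_p_matches_high_precision(self, p):
        with mpmath.workdps(400):
            expected = float(mpmath.tan((mpmath.mpf("0.5") - mpmath.mpf(str(p))) * mpmath.pi))
        assert cauchy_transform(p) == pytest.approx(expected, rel=1e-12)


class TestCCT:
    def test_complementary_pair_is_exactly_half(self):
        # 0.75 and its complement are both exactly representable
        assert cct_pvalue([0.25, 0.75]).pvalue == 0.5
        assert cct_pvalue([0.3, 0.7]).pvalue == pytest.approx(0.5, abs=1e-12)

    def test_identical_pvalues_invert_to_input(self):
        res = cct_pvalue([0.1, 0.1, 0.1])
        assert res.pvalue == pytest.approx(0.1, rel=1e-12)

    def test_rehab_dependent_pair_oracle(self):
        # the dependent (left, right) MinP pair from the 12-study table
        values = [0.996635, 0.0064627]
        assert cct_pvalue(values).pvalue == pytest.approx(mp_cct(values), rel=1e-12)
        assert round(cct_pvalue(values).pvalue, 2) == 0.99

    def test_pvalue_is_cauchy_tail_of_statistic(self):
        res = cct_pvalue([0.02, 0.4, 0.9])
        assert res.pvalue == pytest.approx(cauchy.sf(res.statistic), abs=1e-12)

    def test_theorem1_bound_random_vectors(self, rng):
        for _ in range(200):
            k = rng.integers(1, 12)
            p = rng.uniform(1e-6, 1.0, size=k)
            w = rng.uniform(0.0, 1.0, size=k) + 1e-3
            res = cct_pvalue(p, weights=w)
            assert p.min() - 1e-12 <= res.pvalue <= p.max() + 1e-12

    def test_weights_shift_toward_heavy_coordinate(self):
        p = [0.01, 0.8]
        heavy_small = cct_pvalue(p, weights=[0.9, 0.1]).pvalue
        heavy_large = cct_pvalue(p, weights=[0.1, 0.9]).pvalue
        assert heavy_small < cct_pvalue(p).pvalue < heavy_large

    @pytest.mark.parametrize("p", [1e-5, 1e-15, 1e-100, 1e-300])
    def test_single_small_p_roundtrip(self, p):
        assert cct_pvalue([p]).pvalue == pytest.approx(p, rel=1e-6)

    def test_p_equal_one_clipped_not_nan(self):
        res = cct_pvalue([1.0, 0.5])
        assert np.isfinite(res.pvalue) and res.pvalue > 1.0 - 1e-12


class TestMinP:
    @pytest.mark.parametrize("mode", ["sidak", "bonferroni"])
    def test_single_study_identity(self, mode):
        assert minp_pvalue([0.037], mode=mode).pvalue == pytest.approx(0.037, rel=1e-12)

    def test_sidak_rehab_left_sided(self, rehab_studies_filled):
        p = [r.p_left for r in rehab_studies_filled]
        assert round(minp_pvalue(p, mode="sidak").pvalue, 3) == 0.997

    def test_bonferroni_dependent_pair(self):
        res = minp_pvalue([0.99984, 0.000157], mode="bonferroni")
        assert res.pvalue == pytest.approx(0.000314, abs=1e-9)

    def test_result_at_least_min_p(self, rng):
        p = rng.uniform(0.001, 1.0, size=8)
        for mode in ("sidak", "bonferroni"):
            assert minp_pvalue(p, mode=mode).pvalue >= p.min()

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            minp_pvalue([0.1, 0.2], mode="holm")


class TestMCM:
    def test_dependent_pair_bonferroni(self):
        res = mcm_pvalue([0.99984, 0.000157], minp_mode="bonferroni")
        assert res.pvalue == pytest.approx(0.000628, abs=1e-9)
        assert res.statistic is None

    def test_capped_at_one_via_half_term(self):
        assert mcm_pvalue([0.5, 0.5]).pvalue == 1.0

    def test_equals_bonferroni_of_subtests(self, rng):
        for _ in range(50):
            p = rng.uniform(1e-4, 1.0, size=5)
            got = mcm_pvalue(p, minp_mode="sidak").pvalue
            expected = min(1.0, 2.0 * min(cct_pvalue(p).pvalue,
                                          minp_pvalue(p, mode="sidak").pvalue))
            assert got == pytest.approx(expected, rel=1e-14)

    def test_rehab_two_sided_regression(self, rehab_studies_filled):
        p = [r.p_two for r in rehab_studies_filled]
        got = mcm_pvalue(p, minp_mode="bonferroni").pvalue
        expected = 2.0 * min(cct_pvalue(p).pvalue,
                             minp_pvalue(p, mode="bonferroni").pvalue, 0.5)
        assert got == pytest.approx(expected, rel=1e-14)


class TestCMC:
    def test_dependent_pair(self):
        got = cmc_pvalue([0.99984, 0.000157], minp_mode="bonferroni").pvalue
        # second-stage CCT over {p_CCT, p_MinP}; regression-pinned full precision
        assert got == pytest.approx(0.00063, abs=2e-5)
        assert got == pytest.approx(0.0006164411424830871, rel=1e-10)

    def test_degenerate_pair_hits_clipping_limit(self):
        # p_CCT = 0.5, Bonferroni p_MinP = 1: second stage CCT{0.5, 1} -> 1
        assert cmc_pvalue([0.5, 0.5]).pvalue > 1.0 - 1e-12

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(50):
            p = rng.uniform(1e-5, 1.0, size=6)
            assert 0.0 < cmc_pvalue(p).pvalue <= 1.0


class TestFisher:
    def test_single_study_identity(self):
        assert fisher_pvalue([0.2]).pvalue == pytest.approx(0.2, rel=1e-12)

    def test_half_half_chi_square_oracle(self):
        res = fisher_pvalue([0.5, 0.5])
        assert res.statistic == pytest.approx(2.7726, abs=1e-4)
        assert res.pvalue == pytest.approx(0.5966, abs=1e-4)

    def test_rehab_right_sided(self, rehab_studies_filled):
        p = [r.p_right for r in rehab_studies_filled]
        assert fisher_pvalue(p).pvalue == pytest.approx(0.000083, abs=5e-7)

    def test_matches_scipy(self, rng):
        p = rng.uniform(0.001, 1.0, size=7)
        stat, pval = combine_pvalues(p, method="fisher")
        res = fisher_pvalue(p)
        assert res.statistic == pytest.approx(stat, rel=1e-12)
        assert res.pvalue == pytest.approx(pval, rel=1e-10)


class TestStouffer:
    def test_single_study_identity(self):
        assert stouffer_pvalue([0.31]).pvalue == pytest.approx(0.31, rel=1e-12)

    def test_rehab_right_sided(self, rehab_studies_filled):
        p = [r.p_right for r in rehab_studies_filled]
        assert stouffer_pvalue(p).pvalue == pytest.approx(0.00016, abs=5e-6)

    def test_complement_symmetry(self, rng):
        p = rng.uniform(0.01, 0.99, size=9)
        total = stouffer_pvalue(p).pvalue + stouffer_pvalue(1.0 - p).pvalue
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_matches_scipy(self, rng):
        p = rng.uniform(0.001, 1.0, size=7)
        stat, pval = combine_pvalues(p, method="stouffer")
        res = stouffer_pvalue(p)
        assert res.statistic == pytest.approx(stat, rel=1e-10)
        assert res.pvalue == pytest.approx(pval, rel=1e-10)

    def test_rejects_p_of_one(self):
        with pytest.raises(ValueError, match="stouffer"):
            stouffer_pvalue([0.2, 1.0])


class TestPValueVector:
    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.2], [-0.1], [np.nan]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError, match=r"p-value out of \(0,1\]"):
            PValueVector(bad)

    def test_weight_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            PValueVector([0.1, 0.2], weights=[1.0])

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="all zero"):
            PValueVector([0.1, 0.2], weights=[0.0, 0.0])

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            PValueVector([0.1, 0.2], weights=[1.0, -0.5])

    def test_normalized_weights_sum_to_one(self):
        pv = PValueVector([0.1, 0.2, 0.3], weights=[2.0, 1.0, 1.0])
        assert pv.normalized_weights().sum() == pytest.approx(1.0, abs=1e-12)
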