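"""The four effect-size estimators on a pair of samples."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

import ovlsim as ov


def cles_brute_force(y1, y2):
    """Double-loop ordered-pairs count; oracle for the sort-based estimator."""
    n1 = sum(1 for a in y1 for b in y2 if a > b)
    n0 = sum(1 for a in y1 for b in y2 if a < b)
    return n1 / (n1 + n0)


class TestCohenD:
    @pytest.mark.parametrize(
        "y1, y2, expected",
        [
            ([0, 1, 2], [0, 1, 2], 0.0),
            ([0, 1, 2], [1, 2, 3], -1.0),  # means 1 and 2, both variances 1
            ([1, 2, 3], [0, 1, 2], 1.0),
        ],
    )
    def test_hand_examples(self, y1, y2, expected):
        assert ov.cohen_d(y1, y2) == pytest.approx(expected, abs=1e-12)

    def test_zero_pooled_sd_is_degenerate(self):
        with pytest.raises(ov.DegenerateSampleError):
            ov.cohen_d([1, 1], [2, 2])

    def test_too_small_groups_rejected(self):
        with pytest.raises(ov.InvalidArgumentError):
            ov.cohen_d([1], [1, 2])


class TestClesEmpirical:
    @pytest.mark.parametrize(
        "y1, y2, expected",
        [
            ([3, 4], [1, 2], 1.0),      # complete separation
            ([1, 2], [1, 2], 0.5),      # one pair each way, two ties excluded
            ([1], [2], 0.0),
        ],
    )
    def test_enumerated_examples(self, y1, y2, expected):
        assert ov.cles_empirical(y1, y2) == pytest.approx(expected)

    def test_all_ties_undefined(self):
        with pytest.raises(ov.UndefinedStatisticError):
            ov.cles_empirical([2, 2], [2, 2])

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2**32 - 1), st.integers(1, 50), st.integers(1, 50))
    def test_matches_brute_force_pair_count(self, seed, n1, n2):
        rng = np.random.default_rng(seed)
        # integer support forces ties so the tie-exclusion rule is exercised
        y1 = rng.integers(0, 8, n1).astype(float)
        y2 = rng.integers(0, 8, n2).astype(float)
        try:
            expected = cles_brute_force(y1, y2)
        except ZeroDivisionError:
            with pytest.raises(ov.UndefinedStatisticError):
                ov.cles_empirical(y1, y2)
            return
        assert ov.cles_empirical(y1, y2) == pytest.approx(expected, abs=1e-15)


class TestDTransforms:
    def test_cles_values(self):
        assert ov.cles_from_d(0.0) == 0.5
        assert ov.cles_from_d(2.0) == pytest.approx(norm.cdf(np.sqrt(2)), abs=1e-12)
        assert ov.cles_from_d(-2.0) == ov.cles_from_d(2.0)

    def test_overlap_parametric_values(self):
        assert ov.overlap_parametric(0.0) == pytest.approx(1.0, abs=1e-12)
        assert ov.overlap_parametric(2.0) == pytest.approx(2 * norm.cdf(-1), abs=1e-12)
        assert ov.overlap_parametric(-2.0) == ov.overlap_parametric(2.0)
        assert ov.overlap_parametric(10.0) < 1e-5

    def test_monotone_in_magnitude(self):
        d = np.linspace(0, 6, 200)
        cles = np.array([ov.cles_from_d(x) for x in d])
        etap = np.array([ov.overlap_parametric(x) for x in d])
        assert np.all(np.diff(cles) > 0)
        assert np.all(np.diff(etap) < 0)
        assert np.all((cles >= 0.5) & (cles <= 1.0))
        assert np.all((etap > 0.0) & (etap <= 1.0))

    @pytest.mark.parametrize("bad", [np.nan, np.inf])
    def test_nonfinite_rejected(self, bad):
        with pytest.raises(ov.InvalidArgumentError):
            ov.cles_from_d(bad)
        with pytest.raises(ov.InvalidArgumentError):
            ov.overlap_parametric(bad)


class TestOverlapNonparametric:
    def test_identical_samples_near_one(self):
        y = np.random.default_rng(0).normal(size=200)
        assert ov.overlap_nonparametric(y, y) >= 0.999

    def test_disjoint_supports_near_zero(self):
        rng = np.random.default_rng(1)
        y1 = rng.normal(0, 1, 200)
        y2 = rng.normal(100, 1, 200)
        assert ov.overlap_nonparametric(y1, y2) <= 0.001

    def test_symmetric_in_samples(self):
        rng = np.random.default_rng(2)
        y1 = rng.normal(0, 1, 150)
        y2 = rng.normal(1, 2, 80)
        assert ov.overlap_nonparametric(y1, y2) == pytest.approx(
            ov.overlap_nonparametric(y2, y1), abs=1e-12
        )

    @pytest.mark.parametrize("n", [10, 300, 5000])
    def test_binned_evaluation_matches_direct_summation(self, n):
        """The FFT-binned KDE agrees with exact kernel summation far below
        any tolerance the overlap integral is used at."""
        from ovlsim.effect_sizes import _bw_nrd0, _kde_on_grid, _kde_on_grid_direct

        y = np.random.default_rng(n).normal(0, 1, n)
        bw = _bw_nrd0(y)
        grid = np.linspace(y.min() - 3 * bw, y.max() + 3 * bw, 1024)
        binned = _kde_on_grid(y, bw, grid)
        direct = _kde_on_grid_direct(y, bw, grid)
        direct /= np.trapezoid(direct, grid)
        assert np.abs(binned - direct).max() < 1e-4

    def test_zero_spread_is_degenerate(self):
        with pytest.raises(ov.DegenerateSampleError):
            ov.overlap_nonparametric([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])

    def test_config_validation(self):
        with pytest.raises(ov.InvalidParameterError):
            ov.KdeConfig(grid_points=32)
        with pytest.raises(ov.InvalidParameterError):
            ov.KdeConfig(kernel="epanechnikov")
        with pytest.raises(ov.InvalidParameterError):
            ov.KdeConfig(grid_cut=-1)


class TestEstimateAll:
    def test_internal_consistency(self):
        rng = np.random.default_rng(5)
        y1 = rng.normal(0, 1, 60)
        y2 = rng.normal(1, 1, 60)
        est = ov.estimate_all(y1, y2)
        assert est.eta_p == pytest.approx(ov.overlap_parametric(est.d), abs=1e-15)
        assert est.cles == pytest.approx(ov.cles_from_d(est.d), abs=1e-15)
        assert 0 <= est.cles <= 1 and 0 <= est.eta_p <= 1 and 0 <= est.eta <= 1

    def test_empirical_switch(self):
        rng = np.random.default_rng(6)
        y1 = rng.normal(0, 1, 40)
        y2 = rng.normal(2, 1, 40)
        est = ov.estimate_all(y1, y2, cles_estimator="empirical")
        assert est.cles == pytest.approx(ov.cles_empirical(y1, y2), abs=1e-15)
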