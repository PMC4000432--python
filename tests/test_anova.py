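"""ANOVA decomposition and ICC computing formulas, checked against
brute-force oracles and textbook identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clusticc import (
    ClusterDataset,
    DegenerateDataError,
    DegenerateVarianceError,
    fit_oneway_anova,
    icc_confidence_interval,
    icc_from_f,
    icc_kish,
)
from clusticc.anova import smith_variance

from conftest import make_dataset


def brute_force_anova(values_by_cluster):
    """Double-loop computation of the one-way ANOVA sums of squares."""
    all_values = [v for cluster in values_by_cluster for v in cluster]
    grand = sum(all_values) / len(all_values)
    ssb = ssw = 0.0
    for cluster in values_by_cluster:
        mean = sum(cluster) / len(cluster)
        ssb += len(cluster) * (mean - grand) ** 2
        for v in cluster:
            ssw += (v - mean) ** 2
    a = len(values_by_cluster)
    n = len(all_values)
    msb = ssb / (a - 1)
    msw = ssw / (n - a)
    return msb, msw, (msb / msw if msw > 0 else math.inf)


class TestOnewayAnova:
    def test_toy_dataset_hand_sums(self, toy_dataset):
        vc = fit_oneway_anova(toy_dataset)
        assert vc.ssb == pytest.approx(54.0)
        assert vc.msb == pytest.approx(27.0)
        assert vc.ssw == pytest.approx(6.0)
        assert vc.msw == pytest.approx(1.0)
        assert vc.f == pytest.approx(27.0)
        assert vc.n0 == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_small_unbalanced_data(self, seed):
        rng = np.random.default_rng(seed)
        sizes = rng.integers(2, 8, rng.integers(2, 6))
        groups = [list(rng.normal(rng.normal(), 1.0, s)) for s in sizes]
        vc = fit_oneway_anova(make_dataset(groups))
        msb, msw, f = brute_force_anova(groups)
        assert vc.msb == pytest.approx(msb, rel=1e-12)
        assert vc.msw == pytest.approx(msw, rel=1e-12)
        assert vc.f == pytest.approx(f, rel=1e-12)

    def test_adjusted_size_equals_common_size_when_balanced(self):
        rng = np.random.default_rng(0)
        vc = fit_oneway_anova(make_dataset([list(rng.normal(i, 1, 7)) for i in range(5)]))
        assert vc.n0 == pytest.approx(7.0)

    def test_adjusted_size_bounded_by_largest_cluster(self):
        vc = fit_oneway_anova(make_dataset([[1.0, 2.0], [3.0, 4.0, 5.0, 9.0], [0.5]]))
        assert 1.0 <= vc.n0 <= 4.0

    def test_constant_data_raises_degenerate_variance(self):
        with pytest.raises(DegenerateVarianceError):
            fit_oneway_anova(make_dataset([[2.0, 2.0], [2.0, 2.0]]))

    def test_all_singletons_raises(self):
        with pytest.raises(DegenerateDataError, match="singleton"):
            fit_oneway_anova(make_dataset([[1.0], [2.0], [3.0]]))


class TestICCFormulas:
    def test_toy_icc_is_26_over_29(self, toy_dataset):
        vc = fit_oneway_anova(toy_dataset)
        assert icc_kish(vc).rho == pytest.approx(26 / 29)
        assert icc_from_f(vc).rho == pytest.approx(26 / 29)
        # also equals the F-form (F-1)/(F-1+n0) by hand
        assert icc_from_f(vc).rho == pytest.approx((27 - 1) / (27 - 1 + 3))

    def test_zero_within_cluster_variance_gives_icc_one(self):
        vc = fit_oneway_anova(make_dataset([[0.0, 0.0], [1.0, 1.0]]))
        assert vc.msw == 0.0 and math.isinf(vc.f)
        assert icc_kish(vc).rho == 1.0
        assert icc_from_f(vc).rho == 1.0

    def test_equal_cluster_means_truncate_to_zero(self):
        vc = fit_oneway_anova(make_dataset([[0.0, 2.0], [1.0, 1.0]]))
        est = icc_kish(vc)
        assert est.rho_raw < 0
        assert est.rho == 0.0

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        seed=st.integers(0, 2**31 - 1),
        a=st.integers(2, 8),
        m=st.integers(2, 9),
    )
    def test_three_formula_equivalence_on_balanced_designs(self, seed, a, m):
        """Kish form, F form and the textbook (MSB-MSW)/(MSB+(n0-1)MSW)
        agree to 1e-12 on balanced data."""
        rng = np.random.default_rng(seed)
        groups = [list(rng.normal(rng.normal(0, 1), 1.0, m)) for _ in range(a)]
        try:
            vc = fit_oneway_anova(make_dataset(groups))
        except DegenerateDataError:
            return
        kish = icc_kish(vc).rho_raw
        f_form = icc_from_f(vc).rho_raw if not math.isinf(vc.f) else 1.0
        textbook = (vc.msb - vc.msw) / (vc.msb + (vc.n0 - 1) * vc.msw)
        assert kish == pytest.approx(textbook, abs=1e-12)
        assert f_form == pytest.approx(textbook, abs=1e-12)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), scale=st.floats(1.0, 20.0))
    def test_rho_raw_monotone_in_between_cluster_spread(self, seed, scale):
        """Scaling cluster means away from the grand mean (fixed within-cluster
        residuals) never decreases the raw ICC."""
        rng = np.random.default_rng(seed)
        a, m = 6, 5
        means = rng.normal(0, 1, a)
        resid = rng.normal(0, 1, (a, m))
        resid -= resid.mean(axis=1, keepdims=True)
        if np.allclose(resid, 0):
            return
        base = [list(means[i] + resid[i]) for i in range(a)]
        wide = [list(scale * means[i] + resid[i]) for i in range(a)]
        rho_base = icc_kish(fit_oneway_anova(make_dataset(base))).rho_raw
        rho_wide = icc_kish(fit_oneway_anova(make_dataset(wide))).rho_raw
        assert rho_wide >= rho_base - 1e-12


class TestConfidenceInterval:
    def test_alpha_one_collapses_to_point(self, toy_dataset):
        vc = fit_oneway_anova(toy_dataset)
        est = icc_confidence_interval(vc, icc_kish(vc), alpha=1.0)
        assert est.ci_low == est.ci_high == est.rho

    def test_truncated_estimate_has_zero_lower_bound(self):
        vc = fit_oneway_anova(make_dataset([[0.0, 2.0], [1.0, 1.0]]))
        est = icc_confidence_interval(vc, icc_kish(vc), alpha=0.05)
        assert est.rho == 0.0
        assert est.ci_low == 0.0
        assert est.ci_high >= 0.0

    def test_interval_brackets_estimate_and_stays_in_unit_range(self, toy_dataset):
        vc = fit_oneway_anova(toy_dataset)
        est = icc_confidence_interval(vc, icc_kish(vc), alpha=0.05)
        assert 0.0 <= est.ci_low <= est.rho <= est.ci_high <= 1.0
        assert est.se > 0

    def test_smith_variance_balanced_reduction(self):
        """For equal cluster sizes the unequal-size formula collapses to the
        classical 2(1-rho)^2 (1+(m-1)rho)^2 (N-1) / (m^2 (N-a)(a-1))."""
        rng = np.random.default_rng(1)
        a, m = 10, 6
        vc = fit_oneway_anova(make_dataset([list(rng.normal(i, 1, m)) for i in range(a)]))
        rho = 0.3
        n = a * m
        classical = (
            2 * (1 - rho) ** 2 * (1 + (m - 1) * rho) ** 2 * (n - 1)
            / (m**2 * (n - a) * (a - 1))
        )
        assert smith_variance(vc, rho) == pytest.approx(classical, rel=1e-12)

    def test_narrower_interval_with_more_clusters(self):
        rng = np.random.default_rng(5)
        def width(a):
            groups = [list(rng.normal(rng.normal(0, 0.5), 1, 30)) for _ in range(a)]
            vc = fit_oneway_anova(make_dataset(groups))
            est = icc_confidence_interval(vc, icc_kish(vc), alpha=0.05)
            return est.se
        assert width(80) < width(8)
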