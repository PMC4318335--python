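"""Asymmetry metric, cohort summaries, Kruskal-Wallis, and power analysis."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst
from scipy import stats as sps

from myeloarch import (CohortSpec, bilateral_asymmetry, compare_asymmetry,
                       detectable_difference, example_cohort, h_statistic,
                       kruskal_wallis, make_cohort, power_two_sample_t,
                       required_sample_size, round_half_up, summarize_group)
from myeloarch.stats import EXAMPLE_REPORTED_ASYM, cohort_table


class TestBilateralAsymmetry:
    def test_reference_values(self):
        assert round_half_up(bilateral_asymmetry(4.0, 3.1)) == 25
        assert bilateral_asymmetry(4.5, 4.5) == 0.0

    @settings(deadline=None, derandomize=True)
    @given(
        left=hst.floats(0.1, 10.0),
        right=hst.floats(0.1, 10.0),
        k=hst.floats(0.01, 100.0),
    )
    def test_symmetry_scale_invariance_and_bounds(self, left, right, k):
        a = bilateral_asymmetry(left, right)
        assert a == bilateral_asymmetry(right, left)
        assert np.isclose(a, bilateral_asymmetry(k * left, k * right), rtol=1e-9)
        assert 0 <= a < 200

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            bilateral_asymmetry(0.0, 1.0)
        with pytest.raises(ValueError):
            bilateral_asymmetry(2.0, -1.0)


def test_round_half_up_convention():
    assert round_half_up(16.5) == 17
    assert round_half_up(2.5) == 3
    assert round_half_up(3.45, 1) == 3.5
    assert np.array_equal(round_half_up(np.array([0.5, 1.49])), [1, 1])


class TestCohortTable:
    def test_asym_recomputed_exactly(self):
        tab = example_cohort()
        expected = bilateral_asymmetry(tab["left"].to_numpy(), tab["right"].to_numpy())
        assert np.max(np.abs(tab["asym_percent"].to_numpy() - expected)) < 1e-9

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            cohort_table([{"subject_id": "s1", "left": 1.0}])

    def test_reported_integer_cells_match_recomputation_within_rounding(self):
        # the published integer asym cells were derived from unrounded
        # hemisphere values; recomputing from the printed one-decimal values
        # reproduces most cells exactly and none is off by more than 3
        tab = example_cohort()
        exact = 0
        worst = 0
        for metric, groups in EXAMPLE_REPORTED_ASYM.items():
            for group, printed in groups.items():
                sel = tab[(tab["group"] == group) & (tab["metric"] == metric)]
                recomputed = round_half_up(sel["asym_percent"].to_numpy())
                diffs = np.abs(recomputed - np.array(printed))
                exact += int((diffs == 0).sum())
                worst = max(worst, int(diffs.max()))
        assert exact >= 9
        assert worst <= 3


class TestSummaries:
    def test_reference_group_summary(self):
        tab = example_cohort()
        mean, sd = summarize_group(tab, "amputee", "myelinated_thickness", "left")
        assert round_half_up(mean, 1) == 3.4
        assert round_half_up(sd, 1) == 0.3

    def test_identical_values_give_zero_sd(self):
        tab = cohort_table(
            [{"subject_id": f"s{i}", "group": "g", "metric": "m", "left": 3.0,
              "right": 3.0} for i in range(4)]
        )
        mean, sd = summarize_group(tab, "g", "m", "left")
        assert mean == 3.0 and sd == 0.0

    def test_matches_two_pass_reference(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(2, 5, size=4)
        tab = cohort_table(
            [{"subject_id": f"s{i}", "group": "g", "metric": "m", "left": v,
              "right": v} for i, v in enumerate(vals)]
        )
        mean, sd = summarize_group(tab, "g", "m", "left")
        ref_mean = sum(vals) / 4
        ref_sd = (sum((v - ref_mean) ** 2 for v in vals) / 3) ** 0.5
        assert np.isclose(mean, ref_mean) and np.isclose(sd, ref_sd)

    def test_single_row_rejected(self):
        tab = example_cohort()
        with pytest.raises(ValueError):
            summarize_group(tab[tab["subject_id"] == "control_1"], "control",
                            "myelinated_thickness", "left")


def exact_p_oracle(a, b):
    """Independent enumeration using scipy's H on every group assignment."""
    pooled = np.concatenate([a, b])
    n_total = len(pooled)
    h_obs = sps.kruskal(a, b).statistic
    count = total = 0
    for idx in itertools.combinations(range(n_total), len(a)):
        mask = np.zeros(n_total, bool)
        mask[list(idx)] = True
        h = sps.kruskal(pooled[mask], pooled[~mask]).statistic
        if h >= h_obs - 1e-12:
            count += 1
        total += 1
    return count / total


class TestKruskalWallis:
    def test_identical_groups(self):
        res = kruskal_wallis([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_fully_separated_groups(self):
        res = kruskal_wallis([1, 2, 3, 4], [5, 6, 7, 8])
        assert np.isclose(res.statistic, 16.0 / 3.0)
        assert np.isclose(res.p_value, 2.0 / 70.0)
        assert res.method == "exact_permutation"

    def test_h_matches_scipy_rank_formula(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.normal(size=5)
            b = rng.normal(size=4)
            if rng.random() < 0.5:  # inject ties
                b[0] = a[0]
            assert np.isclose(h_statistic(a, b), sps.kruskal(a, b).statistic)

    @pytest.mark.parametrize("na, nb", [(2, 3), (3, 3), (4, 4), (5, 5), (4, 6)])
    def test_exact_p_agrees_with_enumeration_oracle(self, na, nb):
        rng = np.random.default_rng(na * 10 + nb)
        a = rng.normal(0, 1, na)
        b = rng.normal(1, 1, nb)
        res = kruskal_wallis(a, b, method="exact_permutation")
        assert np.isclose(res.p_value, exact_p_oracle(a, b))

    def test_exact_p_invariant_to_monotone_transform(self):
        a = np.array([1.2, 3.4, 2.2, 5.5])
        b = np.array([2.1, 6.6, 7.7, 0.5])
        p0 = kruskal_wallis(a, b, method="exact_permutation").p_value
        for f in (np.exp, np.log, lambda x: x**3):
            x = f(a + 1), f(b + 1)
            assert kruskal_wallis(*x, method="exact_permutation").p_value == p0

    def test_chi2_approximation_quality_at_small_n(self):
        # at n=4+4 the chi-square approximation is rough (deviations above
        # 0.1 occur); the exact mode exists precisely for this regime
        rng = np.random.default_rng(0)
        diffs = []
        for _ in range(200):
            a = rng.normal(size=4)
            b = rng.normal(rng.uniform(0, 2), size=4)
            pe = kruskal_wallis(a, b, method="exact_permutation").p_value
            pc = kruskal_wallis(a, b, method="chi_square_approx").p_value
            diffs.append(abs(pe - pc))
        assert max(diffs) <= 0.15
        assert np.mean(diffs) <= 0.08

    def test_cohort_recovery_detects_large_group_difference(self):
        # 30-point asymmetry difference, n=50/group: significant in >=95/100
        hits = 0
        for rep in range(100):
            spec = CohortSpec(
                n_per_group=50, metric_names=("myelinated_thickness",),
                asym_mean={"control": 10.0, "amputee": 40.0},
                asym_sd=8.0, seed=1000 + rep,
            )
            tab = make_cohort(spec)
            res = compare_asymmetry(tab, "myelinated_thickness")
            hits += res.p_value < 0.05
        assert hits >= 95


class TestPower:
    def test_doubling_sd_doubles_detectable_difference(self):
        d1 = detectable_difference(10, 1.0)
        d2 = detectable_difference(10, 2.0)
        assert np.isclose(d2, 2 * d1, rtol=1e-6)

    def test_required_n_nonincreasing_in_delta(self):
        ns = [required_sample_size(d, 1.0) for d in (0.3, 0.5, 0.8, 1.2, 2.0)]
        assert all(a >= b for a, b in zip(ns, ns[1:]))

    def test_power_at_n17_delta_equal_sd(self):
        # frozen Monte-Carlo reference (1e5 two-sample t-tests): 0.8069
        assert abs(power_two_sample_t(1.0, 1.0, 17) - 0.8069) < 0.01

    def test_solver_roundtrip(self):
        delta = detectable_difference(12, 2.5, power=0.8)
        assert abs(power_two_sample_t(delta, 2.5, 12) - 0.8) < 1e-6

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            detectable_difference(1, 1.0)
        with pytest.raises(ValueError):
            detectable_difference(4, 0.0)
        with pytest.raises(ValueError):
            required_sample_size(0.0, 1.0)
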