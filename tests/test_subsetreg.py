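"""Constrained ML regression, LRT stepwise building, bootstrap CIs."""

import numpy as np
import pandas as pd
import pytest

from methaccord import subsetreg
from methaccord.subsetreg import (
    IdentifiabilityError,
    SubsetLinearFit,
    SubsetLinearSpec,
    build_final_model,
    bootstrap_ci,
    fit_model,
    lrt_step,
)
from conftest import make_sheet

SUBSETS = ("A", "B", "C")


def full_free_spec(subsets=SUBSETS):
    """Every subset gets its own intercept and slope."""
    groups = tuple((s,) for s in subsets)
    return SubsetLinearSpec(tuple(subsets), groups, groups)


class TestFitModel:
    def test_exact_line_recovered(self):
        df = make_sheet({"A": (10, 1.0), "B": (10, 1.0)}, slope=2.0, sigma=0.0)
        fit = fit_model(df, SubsetLinearSpec.reduced(("A", "B")))
        assert fit.effective_intercepts["A"] == pytest.approx(1.0, abs=1e-8)
        assert fit.effective_slopes["A"] == pytest.approx(2.0, abs=1e-8)
        assert fit.sigma2 < 1e-16

    def test_all_free_equals_per_subset_ols(self, rng):
        df = make_sheet({"A": (30, 5.0), "B": (25, -3.0), "C": (40, 12.0)},
                        sigma=2.0, seed=4)
        fit = fit_model(df, full_free_spec())
        for s in SUBSETS:
            sub = df[df["subset"] == s]
            slope, intercept = np.polyfit(sub["luma_pct"], sub["line1_pct"], 1)
            assert fit.effective_intercepts[s] == pytest.approx(intercept, abs=1e-8)
            assert fit.effective_slopes[s] == pytest.approx(slope, abs=1e-8)

    def test_minus2ll_identity(self, rng):
        df = make_sheet({"A": (30, 5.0), "B": (25, -3.0)}, sigma=2.0, seed=4)
        fit = fit_model(df, SubsetLinearSpec.reduced(("A", "B")))
        resid = df["line1_pct"] - fit.predict(df)
        sigma2 = float(np.mean(resid**2))
        n = len(df)
        assert fit.sigma2 == pytest.approx(sigma2, rel=1e-10)
        assert fit.minus2LL == pytest.approx(n * np.log(2 * np.pi * sigma2) + n)

    def test_zero_intercept_constraint(self):
        df = make_sheet({"A": (20, 0.0), "B": (20, 8.0)}, sigma=0.0, slope=0.9)
        spec = SubsetLinearSpec(("A", "B"), (("A",), ("B",)), (("A", "B"),),
                                zero_intercepts=(("A",),))
        fit = fit_model(df, spec)
        assert fit.effective_intercepts["A"] == 0.0
        assert fit.effective_intercepts["B"] == pytest.approx(8.0, abs=1e-8)

    def test_redundant_free_mask_raises(self):
        with pytest.raises(IdentifiabilityError, match="intercept"):
            SubsetLinearSpec.from_free_mask(SUBSETS, free_intercepts=SUBSETS)
        with pytest.raises(IdentifiabilityError, match="products"):
            SubsetLinearSpec.from_free_mask(SUBSETS, free_slopes=SUBSETS)
        # a tie resolves the slope redundancy
        spec = SubsetLinearSpec.from_free_mask(
            SUBSETS, free_slopes=SUBSETS, slope_ties=[("A", "B")])
        assert sorted(map(sorted, spec.slope_groups)) == [["A", "B"], ["C"]]

    def test_small_subset_rejected(self):
        df = make_sheet({"A": (2, 0.0), "B": (20, 1.0)}, sigma=1.0)
        with pytest.raises(ValueError, match="fewer than 3"):
            fit_model(df, full_free_spec(("A", "B")))


class TestLrtStep:
    def _fit_pair(self, m2ll_full, m2ll_reduced):
        subsets = ("A", "B")
        red = SubsetLinearSpec.reduced(subsets)
        full = SubsetLinearSpec(subsets, (("A",), ("B",)), (subsets,))
        mk = lambda spec, ll: SubsetLinearFit(
            spec=spec, effective_intercepts={}, effective_slopes={},
            sigma2=1.0, minus2LL=ll, n=50)
        return mk(full, m2ll_full), mk(red, m2ll_reduced)

    @pytest.mark.parametrize("delta, kept", [
        (-5.0, True),      # improvement beyond the criterion
        (-2.0, False),
        (-3.84, False),    # boundary: strictly below is required
    ])
    def test_retention_criterion(self, delta, kept):
        full, red = self._fit_pair(delta, 0.0)
        keep, d, p = lrt_step(full, red, df=1)
        assert keep is kept
        assert d == pytest.approx(delta)

    def test_p_value_from_chi2(self):
        full, red = self._fit_pair(95.0, 100.0)
        _, _, p = lrt_step(full, red, df=1)
        assert p == pytest.approx(0.0253, abs=1e-3)

    def test_non_nested_rejected(self):
        full, red = self._fit_pair(95.0, 100.0)
        with pytest.raises(ValueError, match="more free parameters"):
            lrt_step(red, full, df=1)


class TestBuildFinalModel:
    def test_distinct_structure_recovered_with_low_noise(self):
        df = make_sheet({"A": (40, 0.0), "B": (40, 9.0), "C": (60, 70.0)},
                        sigma=1.0, seed=2)
        df.loc[df.subset == "C", "line1_pct"] = (
            70.0 + 0.3 * df.loc[df.subset == "C", "luma_pct"]
            + np.random.default_rng(3).normal(0, 1.0, 60))
        fit, log = build_final_model(df, subset_order=list(SUBSETS))
        assert fit.spec.zero_intercepts == (("A",),)
        assert sorted(map(sorted, fit.spec.slope_groups)) == [["A", "B"], ["C"]]
        assert fit.effective_intercepts["C"] == pytest.approx(70.0, abs=2.5)
        assert fit.effective_slopes["C"] == pytest.approx(0.3, abs=0.06)

    def test_minus2ll_monotone_in_step_log(self, default_sheet):
        fit, log = build_final_model(default_sheet)
        for step in log:
            if step["action"].startswith("free"):
                # freeing a parameter can only improve the likelihood
                assert step["delta_m2ll"] <= 1e-6

    def test_null_data_keeps_reduced_structure(self):
        """On data from a single shared line, subset parameters are retained
        at roughly the per-test type-I rate."""
        reduced_kept = 0
        first_step_accepts = 0
        reps = 200
        for rep in range(reps):
            df = make_sheet({"A": (25, 5.0), "B": (25, 5.0), "C": (25, 5.0)},
                            sigma=2.0, seed=1000 + rep)
            fit, log = build_final_model(df, subset_order=list(SUBSETS))
            first_step_accepts += log[0]["accepted"]
            reduced_kept += (len(fit.spec.intercept_groups) == 1
                             and len(fit.spec.slope_groups) == 1)
        assert first_step_accepts / reps < 0.12  # ~ alpha = 0.05
        assert reduced_kept / reps > 0.6

    def test_theta_table_consistent_with_effective_values(self, default_sheet):
        fit, _ = build_final_model(default_sheet)
        th = fit.theta
        for i, s in enumerate(fit.spec.subsets, start=3):
            assert th["theta1"] + th[f"theta{i}_Int_{s}"] == pytest.approx(
                fit.effective_intercepts[s], abs=1e-9)


class TestBootstrapCI:
    def test_zero_noise_gives_degenerate_intervals(self):
        df = make_sheet({"A": (20, 1.0), "B": (20, 4.0)}, sigma=0.0, slope=1.5)
        spec = SubsetLinearSpec(("A", "B"), (("A",), ("B",)), (("A", "B"),))
        fit = bootstrap_ci(df, spec, n_boot=100, seed=0)
        for key, (lo, hi) in fit.boot_ci.items():
            if key.startswith(("intercept", "slope")):
                assert hi - lo < 1e-8

    def test_interval_order_and_point_coverage(self, default_sheet):
        fit0, _ = build_final_model(default_sheet)
        fit = bootstrap_ci(default_sheet, fit0.spec, n_boot=200, seed=5)
        for lo, hi in fit.boot_ci.values():
            assert lo <= hi
        lo, hi = fit.boot_ci["slope_blood"]
        assert lo < fit.effective_slopes["blood"] < hi

    def test_deterministic_under_seed(self):
        df = make_sheet({"A": (15, 1.0), "B": (15, 5.0)}, sigma=1.0)
        spec = SubsetLinearSpec.reduced(("A", "B"))
        a = bootstrap_ci(df, spec, n_boot=50, seed=3).boot_ci
        b = bootstrap_ci(df, spec, n_boot=50, seed=3).boot_ci
        assert a == b
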