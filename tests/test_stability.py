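"""Stability tables, ddG algebra, destabilization calls, predictor comparison."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import moltenfit as mf
from conftest import DDG_NU, DG_NU, P237H_LITERATURE_DDG


@pytest.fixture(scope="module")
def panel_fits(panel):
    """Noiseless fits of the whole mutant panel (the pipeline's input)."""
    return {name: mf.fit_curve(mf.generate_curve(p, noise_sd=0.0))
            for name, p in panel.variants.items()}


@pytest.fixture(scope="module")
def table(panel_fits):
    return mf.build_stability_table(
        panel_fits, reference="HCAII_pwt",
        literature={"HCAII_P237H": P237H_LITERATURE_DDG})


class TestTotalDg:
    @pytest.mark.parametrize("dg_ni, dg_iu, expected", [
        (5.7, 7.8, 13.5), (5.3, 5.3, 10.6), (0.0, 0.0, 0.0)])
    def test_sum_of_transitions(self, dg_ni, dg_iu, expected):
        fake_cov = np.zeros((7, 7))
        names = ("dg_ni", "m_ni", "dg_iu", "m_iu",
                 "baseline_n", "baseline_i", "baseline_u")
        params = mf.ThreeStateParams(
            ni=mf.TransitionThermo(dg_ni, 6.0),
            iu=mf.TransitionThermo(dg_iu, 4.0),
            baseline_n=336, baseline_i=341, baseline_u=355)
        fit = mf.FitResult(params=params, param_names=names,
                           stderr={n: 0.0 for n in names},
                           covariance=fake_cov, rss=0.0, n_points=31,
                           aic=-100.0, converged=True,
                           residuals=np.zeros(31))
        dg, se = mf.total_dg(fit)
        assert dg == pytest.approx(expected, abs=1e-12)
        assert se == 0.0

    def test_error_propagation_includes_covariance(self):
        names = ("dg_ni", "m_ni", "dg_iu", "m_iu",
                 "baseline_n", "baseline_i", "baseline_u")
        cov = np.zeros((7, 7))
        cov[0, 0], cov[2, 2] = 0.36, 0.36
        cov[0, 2] = cov[2, 0] = -0.10
        params = mf.ThreeStateParams(
            ni=mf.TransitionThermo(5.7, 6.3), iu=mf.TransitionThermo(7.8, 3.9),
            baseline_n=336, baseline_i=341, baseline_u=355)
        fit = mf.FitResult(params=params, param_names=names,
                           stderr={n: 0.0 for n in names}, covariance=cov,
                           rss=1.0, n_points=31, aic=0.0, converged=True,
                           residuals=np.zeros(31))
        _, se = mf.total_dg(fit)
        assert se == pytest.approx(math.sqrt(0.36 + 0.36 - 0.20))

    def test_requires_converged_three_state(self):
        params = mf.TwoStateParams(nu=mf.TransitionThermo(13.5, 10.0),
                                   baseline_n=336, baseline_u=355)
        fit = mf.FitResult(params=params, param_names=("dg_nu",),
                           stderr={"dg_nu": 0.1}, covariance=np.eye(1),
                           rss=0.1, n_points=31, aic=0.0, converged=True,
                           residuals=np.zeros(31))
        with pytest.raises(ValueError, match="three-state"):
            mf.total_dg(fit)


class TestDdg:
    def test_positive_means_destabilizing(self):
        ref = mf.StabilityRecord("wt", dg_nu=13.5, source="literature")
        mut = mf.StabilityRecord("m1", dg_nu=12.5, source="literature")
        assert mf.ddg_nu(ref, mut) == pytest.approx(1.0)
        mut2 = mf.StabilityRecord("m2", dg_nu=11.1, source="literature")
        assert mf.ddg_nu(ref, mut2) == pytest.approx(2.4)
        assert mf.ddg_nu(ref, ref) == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(a=st.floats(-5, 20), b=st.floats(-5, 20))
    def test_antisymmetry(self, a, b):
        ra = mf.StabilityRecord("a", dg_nu=a, source="literature")
        rb = mf.StabilityRecord("b", dg_nu=b, source="literature")
        assert mf.ddg_nu(ra, rb) == pytest.approx(-mf.ddg_nu(rb, ra))


class TestStabilityTable:
    def test_full_panel_reproduces_reported_columns(self, table):
        """Noiseless pipeline regenerates the published dG_NU and ddG_NU
        columns within 1% relative."""
        by_variant = {r.variant: r for r in table}
        for variant, dg_nu in DG_NU.items():
            assert by_variant[variant].dg_nu == pytest.approx(dg_nu, rel=0.01)
        for variant, ddg in DDG_NU.items():
            assert by_variant[variant].ddg_nu == pytest.approx(ddg, abs=0.05)
        lit = by_variant["HCAII_P237H"]
        assert lit.source == "literature"
        assert lit.ddg_nu == 7.3
        assert lit.dg_ni is None and lit.dg_iu is None

    def test_reference_first_with_zero_ddg(self, table):
        assert table[0].variant == "HCAII_pwt"
        assert table[0].ddg_nu == 0.0

    def test_single_variant_table(self, panel_fits):
        t = mf.build_stability_table(
            {"HCAII_pwt": panel_fits["HCAII_pwt"]}, reference="HCAII_pwt")
        assert len(t) == 1 and t[0].ddg_nu == 0.0

    def test_missing_reference_rejected(self, panel_fits):
        with pytest.raises(ValueError, match="reference"):
            mf.build_stability_table(panel_fits, reference="nope")

    def test_duplicate_labels_rejected(self, panel_fits):
        with pytest.raises(ValueError, match="duplicate"):
            mf.build_stability_table(panel_fits, reference="HCAII_pwt",
                                     literature={"HCAII_pwt": 1.0})


class TestClassifyDestabilizing:
    def test_default_threshold_flags_three_most_deleterious(self, table):
        flagged = mf.classify_destabilizing(table)
        assert flagged == ["HCAII_P237H", "HCAII_P237F", "HCAII_P237T"]

    def test_tighter_threshold(self, table):
        assert mf.classify_destabilizing(table, threshold=2.5) == [
            "HCAII_P237H", "HCAII_P237F"]

    def test_matches_brute_force_filter(self, table):
        for t in (0.0, 0.95, 2.0, 5.0, 10.0):
            expected = sorted(
                (r.variant for r in table
                 if r.ddg_nu is not None and r.ddg_nu > t),
                key=lambda v: -next(r.ddg_nu for r in table
                                    if r.variant == v))
            assert mf.classify_destabilizing(table, t) == expected

    def test_reference_only_is_empty(self):
        recs = [mf.StabilityRecord("wt", ddg_nu=0.0, source="literature")]
        assert mf.classify_destabilizing(recs, threshold=0.0) == []


class TestComparePredictions:
    def test_max_deviation_identifies_worst_predicted_variant(self):
        """The P237H prediction (1.03) vs literature (7.3): deviation 6.27."""
        records = [
            mf.StabilityRecord("HCAII_P237H", ddg_nu=7.3, source="literature"),
            mf.StabilityRecord("HCAII_P237I", ddg_nu=0.9, source="literature"),
        ]
        res = mf.compare_predictions(
            records, {"HCAII_P237H": 1.03, "HCAII_P237I": 1.22})
        assert res.max_deviation_variant == "HCAII_P237H"
        assert res.max_abs_deviation == pytest.approx(6.27)

    def test_identical_maps_perfect_agreement(self, table):
        predicted = {r.variant: r.ddg_nu for r in table
                     if r.ddg_nu is not None}
        res = mf.compare_predictions(table, predicted)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.rmse == pytest.approx(0.0, abs=1e-9)

    def test_constant_shift_keeps_r_one(self, table):
        predicted = {r.variant: r.ddg_nu + 0.7 for r in table
                     if r.ddg_nu is not None}
        res = mf.compare_predictions(table, predicted)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.rmse == pytest.approx(0.7)

    def test_fewer_than_two_common_variants_rejected(self, table):
        with pytest.raises(ValueError, match=">= 2"):
            mf.compare_predictions(table, {"HCAII_P237H": 1.03})

    def test_unmatched_variants_warned_and_listed(self, table):
        predicted = {r.variant: 1.0 for r in table}
        predicted["EXTRA"] = 2.0
        with pytest.warns(UserWarning, match="EXTRA"):
            res = mf.compare_predictions(table, predicted)
        assert "EXTRA" in res.unmatched
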