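"""Dose-size regression and BEIR VII excess relative risk."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import ctdosim as cd
from ctdosim.calibration import AbsoluteDoseMap
from ctdosim.phantom import OrganMask


def _dose_map(values, batches=None):
    values = np.asarray(values, dtype=float)
    if batches is None:
        batches = np.stack([values, values])
    return AbsoluteDoseMap(values_cgy=values, batch_values_cgy=batches,
                           spacing=np.ones(3), origin=np.zeros(3),
                           protocol_id="t")


class TestOrganMeanDose:
    def test_uniform_grid(self):
        amap = _dose_map(np.full((3, 3, 3), 5.0))
        mask = OrganMask("lungs", np.ones((3, 3, 3), dtype=bool))
        rec = cd.organ_mean_dose(amap, mask, patient_id="P0", protocol="4DCT")
        assert rec.dose_cgy == pytest.approx(5.0)
        assert rec.sigma_cgy == pytest.approx(0.0)

    def test_two_voxel_mean(self):
        v = np.zeros((2, 1, 1))
        v[0, 0, 0], v[1, 0, 0] = 1.0, 3.0
        mask = OrganMask("heart", np.ones((2, 1, 1), dtype=bool))
        assert cd.organ_mean_dose(_dose_map(v), mask).dose_cgy == pytest.approx(2.0)

    def test_empty_or_mismatched_mask_errors(self):
        amap = _dose_map(np.zeros((2, 2, 2)))
        with pytest.raises(ValueError):
            cd.organ_mean_dose(amap, OrganMask("x", np.ones((3, 3, 3), bool)))


class TestDoseDiameterFit:
    def test_exact_recovery_of_generating_line(self):
        d = np.linspace(185, 465, 30)
        y = 25.90 - 0.0491 * d
        fit = cd.fit_dose_vs_diameter(y, d, organ="lungs", protocol="4DCT")
        assert fit.intercept_cgy == pytest.approx(25.90, abs=1e-9)
        assert fit.slope_cgy_per_mm == pytest.approx(-0.0491, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_duplicating_points_leaves_fit_unchanged(self):
        rng = np.random.default_rng(0)
        d = np.linspace(200, 400, 20)
        y = 2.0 - 0.004 * d + rng.normal(0, 0.1, 20)
        f1 = cd.fit_dose_vs_diameter(y, d)
        f2 = cd.fit_dose_vs_diameter(np.tile(y, 2), np.tile(d, 2))
        assert f2.intercept_cgy == pytest.approx(f1.intercept_cgy)
        assert f2.slope_cgy_per_mm == pytest.approx(f1.slope_cgy_per_mm)

    def test_singular_designs_rejected(self):
        with pytest.raises(ValueError):
            cd.fit_dose_vs_diameter([1, 2, 3], [300, 300, 300])
        with pytest.raises(ValueError):
            cd.fit_dose_vs_diameter([1, 2], [300, 310])

    def test_noisy_recovery_within_three_standard_errors(self):
        rng = np.random.default_rng(42)
        d = rng.uniform(185, 465, 100)
        truth_b0, truth_b1 = 29.43, -0.0576  # heart, low-pitch helical arm
        mean = truth_b0 + truth_b1 * d
        y = mean + rng.normal(0, 0.1 * mean.mean(), 100)
        fit = cd.fit_dose_vs_diameter(y, d)
        assert abs(fit.slope_cgy_per_mm - truth_b1) < 3 * fit.slope_stderr
        assert abs(fit.intercept_cgy - truth_b0) < 3 * fit.intercept_stderr

    def test_null_slope_ci_coverage(self):
        """With zero true slope, the 95% slope CI covers 0 at ~95% rate."""
        rng = np.random.default_rng(7)
        n_rep, covered = 200, 0
        d = np.linspace(185, 465, 40)
        for _ in range(n_rep):
            y = 5.0 + rng.normal(0, 1.0, d.size)
            lo, hi = cd.fit_dose_vs_diameter(y, d).slope_ci()
            covered += lo <= 0.0 <= hi
        assert 0.90 <= covered / n_rep <= 0.99

    @pytest.mark.parametrize("coeffs,diameter,expected", [
        ((25.90, -0.0491), 300.0, 11.17),  # lungs, low-pitch helical arm
        ((1.63, -0.0030), 400.0, 0.43),    # skin, axial arm
        ((25.90, -0.0491), 0.0, 25.90),    # intercept at zero diameter
    ])
    def test_predictions(self, coeffs, diameter, expected):
        fit = cd.LinearFitResult(organ="", protocol="", intercept_cgy=coeffs[0],
                                 slope_cgy_per_mm=coeffs[1], r_squared=0.8,
                                 n_points=10)
        assert cd.predict_dose(fit, diameter) == pytest.approx(expected, abs=5e-3)

    def test_negative_prediction_clamps_with_warning(self):
        fit = cd.LinearFitResult(organ="", protocol="", intercept_cgy=1.63,
                                 slope_cgy_per_mm=-0.0030, r_squared=0.7,
                                 n_points=10)
        with pytest.warns(UserWarning, match="clamped"):
            assert cd.predict_dose(fit, 1000.0) == 0.0


class TestErrModel:
    def test_unit_dose_at_pivot_ages_returns_beta(self):
        # e >= 30 zeroes the exposure-age modifier; a = 60 zeroes the
        # attained-age modifier, so ERR = beta_s exactly
        m = cd.err(cd.LUNG_ERR_PARAMS, "male", 40, 60, 1.0)
        f = cd.err(cd.LUNG_ERR_PARAMS, "female", 40, 60, 1.0)
        assert m.err == 0.32 and m.ci == (0.15, 0.70)
        assert f.err == 1.40 and f.ci == (0.94, 2.1)

    def test_young_exposure_raises_risk(self):
        # e = 20 -> e* = -1 -> ERR = 0.32 * exp(0.30) = 0.4320
        r = cd.err(cd.LUNG_ERR_PARAMS, "male", 20, 60, 1.0)
        assert r.err == pytest.approx(0.32 * math.exp(0.30), abs=1e-6)
        assert r.err == pytest.approx(0.4320, abs=1e-4)

    def test_zero_dose_zero_risk(self):
        assert cd.err(cd.LUNG_ERR_PARAMS, "female", 50, 70, 0.0).err == 0.0

    def test_female_male_ratio_exact(self):
        f = cd.err(cd.LUNG_ERR_PARAMS, "female", 25, 55, 0.3).err
        m = cd.err(cd.LUNG_ERR_PARAMS, "male", 25, 55, 0.3).err
        assert f / m == pytest.approx(1.40 / 0.32, rel=1e-12)  # 4.375

    @settings(max_examples=40, deadline=None)
    @given(d1=st.floats(0.001, 5), d2=st.floats(0.001, 5),
           e=st.floats(1, 90), a=st.floats(30, 100))
    def test_monotone_and_linear_in_dose(self, d1, d2, e, a):
        lo, hi = sorted((d1, d2))
        r_lo = cd.err(cd.LUNG_ERR_PARAMS, "male", e, a, lo).err
        r_hi = cd.err(cd.LUNG_ERR_PARAMS, "male", e, a, hi).err
        assert r_lo <= r_hi
        assert r_hi * lo == pytest.approx(r_lo * hi, rel=1e-9)  # linearity

    def test_independent_of_exposure_age_above_30(self):
        r1 = cd.err(cd.LUNG_ERR_PARAMS, "female", 30, 60, 1.0).err
        r2 = cd.err(cd.LUNG_ERR_PARAMS, "female", 75, 60, 1.0).err
        assert r1 == r2

    def test_decreasing_in_attained_age(self):
        errs = [cd.err(cd.LUNG_ERR_PARAMS, "male", 40, a, 1.0).err
                for a in (40, 60, 80)]
        assert errs[0] > errs[1] > errs[2]

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            cd.err(cd.LUNG_ERR_PARAMS, "male", 40, 60, -0.1)
        with pytest.raises(ValueError):
            cd.err(cd.LUNG_ERR_PARAMS, "male", 40, 0, 1.0)
        with pytest.raises(ValueError):
            cd.err(cd.LUNG_ERR_PARAMS, "other", 40, 60, 1.0)


class TestCohortRisk:
    def _table(self, ratios, base=0.7, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i, r in enumerate(ratios):
            age = rng.uniform(20, 80)
            sex = "female" if i % 2 else "male"
            for protocol, dose in (("3DCT", base), ("4DCT", base * r)):
                rows.append({"patient_id": f"P{i}", "organ": "lungs",
                             "protocol": protocol, "dose_cGy": dose,
                             "age": age, "sex": sex})
        return pd.DataFrame(rows)

    def test_per_patient_ratio_equals_dose_ratio(self):
        per, summary = cd.cohort_risk(self._table([7.5]))
        assert per["err_ratio"].iloc[0] == pytest.approx(7.5, rel=1e-12)
        assert summary["mean_err_ratio"] == pytest.approx(7.5, rel=1e-12)

    def test_mean_ratio_tracks_generating_mean(self):
        rng = np.random.default_rng(3)
        ratios = rng.normal(13.3, 1.0, 120)
        _, summary = cd.cohort_risk(self._table(ratios))
        se = 1.0 / math.sqrt(120)
        assert abs(summary["mean_err_ratio"] - 13.3) < 4 * se

    def test_missing_arm_skipped_with_warning(self):
        t = self._table([5.0, 6.0])
        t = t.drop(t[(t.patient_id == "P1") & (t.protocol == "4DCT")].index)
        with pytest.warns(UserWarning, match="missing protocol arm"):
            per, summary = cd.cohort_risk(t)
        assert summary["n_patients"] == 1

    def test_ci_bounds_bracket_point_estimate(self):
        per, _ = cd.cohort_risk(self._table([9.0, 12.0, 15.0]))
        assert (per["err_4dct_lo"] <= per["err_4dct"]).all()
        assert (per["err_4dct"] <= per["err_4dct_hi"]).all()
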