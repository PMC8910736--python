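"""Kinetics classification, parameter recovery and correction factors."""

import numpy as np
import pytest

from carbonylome.io import CONTROL, QC, InjectionSchedule
from carbonylome.kinetics import (
    KineticsFit,
    apply_correction,
    classify_kinetics,
    correction_factors,
    fit_piecewise,
)
from carbonylome.io import FeatureRecord
from carbonylome.timeseries import rsd_percent

QC_TIMES = np.array([0.0, 255.0, 510.0, 765.0, 1020.0, 1275.0, 1423.75])


class TestClassify:
    def test_rising_line_is_type_I(self):
        y = 1e6 * (1 + 0.001 * QC_TIMES)
        assert classify_kinetics(QC_TIMES, y).kinetics_type == "I"

    def test_falling_line_is_type_II(self):
        y = 1e6 * (1 - 0.0005 * QC_TIMES)
        assert classify_kinetics(QC_TIMES, y).kinetics_type == "II"

    def test_flat_series_is_steady(self):
        y = np.full_like(QC_TIMES, 5e5)
        assert classify_kinetics(QC_TIMES, y).kinetics_type == "steady"

    def test_small_wobble_is_steady(self):
        rng = np.random.default_rng(0)
        y = 1e6 * rng.lognormal(0, 0.03, size=QC_TIMES.size)
        assert classify_kinetics(QC_TIMES, y).kinetics_type == "steady"

    def test_planted_breakpoint_recovered(self):
        """Flat to ~1000 min then a steep drop classifies as type III with
        the breakpoint within one QC interval of the truth."""
        tau = 1000.0
        y = np.where(
            QC_TIMES <= tau,
            1e6 * (1 - 0.05 * QC_TIMES / tau),
            1e6 * (0.95 - 0.8 * (QC_TIMES - tau) / 424.0),
        )
        fit = classify_kinetics(QC_TIMES, y)
        assert fit.kinetics_type == "III"
        assert abs(fit.model["breakpoint"] - tau) <= 255.0

    def test_scaled_centroid_flat_is_steady(self):
        rng = np.random.default_rng(1)
        y = rng.normal(0, 0.05, size=QC_TIMES.size)
        assert classify_kinetics(QC_TIMES, y).kinetics_type == "steady"

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            classify_kinetics([0.0, 1.0], [1.0, 2.0])


class TestPiecewiseFit:
    def test_exact_hinge_recovered(self):
        t = np.linspace(0, 10, 11)
        y = 5.0 + 1.0 * t - 3.0 * np.maximum(t - 6.0, 0)
        model, rss = fit_piecewise(t, y)
        assert rss == pytest.approx(0.0, abs=1e-18)
        assert model["breakpoint"] == 6.0
        assert model["slope1"] == pytest.approx(1.0)
        assert model["slope2"] == pytest.approx(-2.0)

    def test_continuity_at_breakpoint(self):
        t = np.linspace(0, 10, 9)
        y = np.exp(-t / 4)
        model, _ = fit_piecewise(t, y)
        fit = KineticsFit("x", "III", model)
        tau = model["breakpoint"]
        left = fit.predict([tau - 1e-9])[0]
        right = fit.predict([tau + 1e-9])[0]
        assert left == pytest.approx(right, abs=1e-6)


@pytest.fixture()
def qc_schedule():
    runs = [(f"QC{i:02d}", t, QC) for i, t in enumerate(QC_TIMES)]
    runs.insert(3, ("C01", 500.0, CONTROL))
    runs.sort(key=lambda r: r[1])
    return InjectionSchedule(tuple(runs))


class TestCorrectionFactors:
    def test_factor_one_at_reference(self, qc_schedule):
        fit = KineticsFit("f", "II", {"kind": "linear", "intercept": 1000.0,
                                      "slope": -0.5})
        fac = correction_factors(fit, qc_schedule, t_ref=0.0)
        assert fac.factors["QC00"] == pytest.approx(1.0, abs=1e-9)

    def test_zero_slope_all_ones(self, qc_schedule):
        fit = KineticsFit("f", "II", {"kind": "linear", "intercept": 7.0,
                                      "slope": 0.0})
        fac = correction_factors(fit, qc_schedule)
        assert all(v == pytest.approx(1.0) for v in fac.factors.values())

    def test_linear_decay_closed_form(self, qc_schedule):
        """f(t) = 1000 - t gives factor 2 at t = 500."""
        fit = KineticsFit("f", "II", {"kind": "linear", "intercept": 1000.0,
                                      "slope": -1.0})
        fac = correction_factors(fit, qc_schedule, t_ref=0.0)
        assert fac.factors["C01"] == pytest.approx(2.0)

    def test_steady_type_identity(self, qc_schedule):
        fit = KineticsFit("f", "steady", {"kind": "linear", "intercept": 5.0,
                                          "slope": -1.0})
        fac = correction_factors(fit, qc_schedule)
        assert set(fac.factors.values()) == {1.0}

    def test_clamping_flagged(self, qc_schedule):
        fit = KineticsFit("f", "II", {"kind": "linear", "intercept": 1000.0,
                                      "slope": -0.7})
        fac = correction_factors(fit, qc_schedule, t_ref=0.0)
        assert fac.clamped
        assert max(fac.factors.values()) == 5.0

    def test_nonpositive_curve_uncorrectable(self, qc_schedule):
        fit = KineticsFit("f", "II", {"kind": "linear", "intercept": 500.0,
                                      "slope": -1.0})
        fac = correction_factors(fit, qc_schedule, t_ref=0.0)
        assert fac.uncorrectable
        assert fac.factors["QC06"] == 1.0


class TestApplyCorrection:
    def _record(self):
        return FeatureRecord("f", 1.0, 300.0, intensities={
            "QC00": 1e5, "C01": 2e5, "QC01": float("nan"),
        })

    def test_identity_factors(self):
        from carbonylome.kinetics import CorrectionFactors

        rec = self._record()
        fac = {"f": CorrectionFactors("f", 0.0, {"QC00": 1.0, "C01": 1.0,
                                                 "QC01": 1.0})}
        (out,) = apply_correction([rec], fac)
        assert out.intensities["C01"] == rec.intensities["C01"]
        assert np.isnan(out.intensities["QC01"])

    def test_factor_two_doubles(self):
        from carbonylome.kinetics import CorrectionFactors

        rec = self._record()
        fac = {"f": CorrectionFactors("f", 0.0, {"QC00": 1.0, "C01": 2.0,
                                                 "QC01": 1.0})}
        (out,) = apply_correction([rec], fac)
        assert out.intensities["C01"] == 4e5

    def test_missing_factor_names_pair(self):
        from carbonylome.kinetics import CorrectionFactors

        rec = self._record()
        fac = {"f": CorrectionFactors("f", 0.0, {"QC00": 1.0})}
        with pytest.raises(KeyError, match="C01"):
            apply_correction([rec], fac)

    def test_self_correction_flattens_qc(self):
        """Correcting the QC series that generated the fit lowers its RSD."""
        times = QC_TIMES
        rng = np.random.default_rng(5)
        y = 1e6 * (1 - 0.0005 * times) * rng.lognormal(0, 0.03, times.size)
        fit = classify_kinetics(times, y)
        runs = tuple((f"QC{i:02d}", t, QC) for i, t in enumerate(times))
        sched = InjectionSchedule(runs)
        fit.feature_id = "f"
        fac = correction_factors(fit, sched, t_ref=0.0)
        corrected = y * np.array([fac.factors[r] for r, _, _ in runs])
        assert rsd_percent(corrected) < rsd_percent(y)
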