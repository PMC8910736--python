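"""Per-analyte degradation/drift kinetics and correction factors.

QC trajectories of CHH derivatives fall into a small number of kinetic
shapes: a continuous linear increase (type I, solvent evaporating faster
than the analyte degrades), a continuous linear decrease (type II,
derivative degradation), a gentle decline with a rapid drop after about
1000 min (type III, both effects in sequence), and steady behaviour
(types IV/V, treated jointly here: no correction applied).

A linear or continuous two-segment (hinge) model is fitted per analyte
on its raw QC peak areas; the fitted curve f(t) yields a multiplicative
correction factor f(t_ref)/f(t_run) per run, which removes the
degradation/drift contribution from sample intensities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import FeatureRecord, InjectionSchedule
from .timeseries import rsd_percent

__all__ = [
    "KineticsFit",
    "CorrectionFactors",
    "fit_linear",
    "fit_piecewise",
    "classify_kinetics",
    "correction_factors",
    "apply_correction",
    "STEADY_RSD_THRESHOLD",
    "CLAMP_BOUNDS",
]

log = logging.getLogger(__name__)

#: Series whose fitted values vary by less than this RSD are steady.
STEADY_RSD_THRESHOLD = 10.0

#: Correction factors are clamped to this interval to prevent blow-up
#: where a fitted decay approaches zero.
CLAMP_BOUNDS = (0.2, 5.0)

#: On min-max-scaled centroids (range 4, mean near 0) the RSD criterion
#: is undefined; a fitted excursion below this fraction of the full
#: scaled range marks the cluster as steady instead.
STEADY_SCALED_SPAN = 1.0


@dataclass
class KineticsFit:
    """Fitted intensity-vs-time model of one feature's QC series."""

    feature_id: str
    kinetics_type: str  # "I" | "II" | "III" | "steady"
    model: dict
    cluster_label: int = -1
    rsd_percent: float = float("nan")
    r_squared: float = float("nan")

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        m = self.model
        if m["kind"] == "linear":
            return m["intercept"] + m["slope"] * t
        if m["kind"] == "piecewise":
            hinge = np.maximum(t - m["breakpoint"], 0.0)
            return (
                m["intercept"]
                + m["slope1"] * t
                + (m["slope2"] - m["slope1"]) * hinge
            )
        raise ValueError(f"unknown model kind {m['kind']!r}")


@dataclass
class CorrectionFactors:
    """Per-run multiplicative factors referenced to t_ref."""

    feature_id: str
    t_ref: float
    factors: dict[str, float] = field(default_factory=dict)
    clamped: bool = False
    uncorrectable: bool = False


def fit_linear(times, values) -> tuple[dict, float]:
    """Least-squares line; returns (model dict, residual sum of squares)."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    b, a = np.polyfit(t, y, 1)
    rss = float(((y - (a + b * t)) ** 2).sum())
    return {"kind": "linear", "intercept": float(a), "slope": float(b)}, rss


def fit_piecewise(times, values, candidates=None) -> tuple[dict, float]:
    """Continuous two-segment line with the breakpoint searched over
    interior time points (or explicit ``candidates``)."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 4:
        raise ValueError("piecewise fit needs at least 4 points")
    if candidates is None:
        candidates = t[1:-1]
    best = None
    for tau in candidates:
        if not (t.min() < tau < t.max()):
            continue
        X = np.column_stack([np.ones_like(t), t, np.maximum(t - tau, 0.0)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(((y - X @ coef) ** 2).sum())
        if best is None or rss < best[1]:
            a, b, c = (float(v) for v in coef)
            best = (
                {
                    "kind": "piecewise",
                    "intercept": a,
                    "slope1": b,
                    "breakpoint": float(tau),
                    "slope2": b + c,
                },
                rss,
            )
    if best is None:
        raise ValueError("no admissible interior breakpoint")
    return best


def _bic(rss: float, n: int, n_params: int) -> float:
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + n_params * np.log(n)


def classify_kinetics(
    times,
    values,
    steady_rsd_threshold: float = STEADY_RSD_THRESHOLD,
    slope_ratio: float = 2.0,
) -> KineticsFit:
    """Assign a kinetics type (I/II/III/steady) to one series.

    Fits a line and (given >= 4 points) a continuous hinge; the hinge
    wins if it improves the BIC and its late slope is steeper than the
    early slope by ``slope_ratio`` or more (type III).  The series is
    steady when the fitted values vary by less than
    ``steady_rsd_threshold`` RSD (strictly positive series) or, for
    scaled/centred input where RSD is undefined, when the fitted
    excursion stays below a quarter of the [-2, 2] range.  Otherwise the
    sign of the fitted slope separates type I (up) from type II (down).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size != y.size or t.size < 3:
        raise ValueError("need >= 3 (time, value) pairs")

    lin_model, lin_rss = fit_linear(t, y)
    model, rss = lin_model, lin_rss
    piecewise = False
    if t.size >= 4:
        try:
            pw_model, pw_rss = fit_piecewise(t, y)
        except ValueError:
            pw_model = None
        if pw_model is not None:
            better = _bic(pw_rss, t.size, 4) < _bic(lin_rss, t.size, 2)
            steeper = abs(pw_model["slope2"]) >= slope_ratio * abs(
                pw_model["slope1"]
            )
            if better and steeper:
                model, rss, piecewise = pw_model, pw_rss, True

    fit = KineticsFit("", "?", model)
    fitted = fit.predict(t)
    tss = float(((y - y.mean()) ** 2).sum())
    fit.r_squared = 1.0 - rss / tss if tss > 0 else 1.0

    if y.min() > 0 and fitted.mean() > 0:
        fit.rsd_percent = rsd_percent(fitted)
        steady = fit.rsd_percent < steady_rsd_threshold
    else:  # scaled centroid: judge by fitted excursion on the 4-unit range
        steady = float(fitted.max() - fitted.min()) < STEADY_SCALED_SPAN

    if steady:
        fit.kinetics_type = "steady"
    elif piecewise:
        fit.kinetics_type = "III"
    else:
        fit.kinetics_type = "I" if model["slope"] > 0 else "II"
    return fit


def correction_factors(
    fit: KineticsFit,
    schedule: InjectionSchedule,
    t_ref: float | None = None,
    clamp: tuple[float, float] = CLAMP_BOUNDS,
) -> CorrectionFactors:
    """Per-run factors f(t_ref)/f(t_run) from a raw-scale kinetics fit.

    ``t_ref`` defaults to the first QC injection time (the earliest
    state is closest to the true abundance of a degrading derivative).
    Steady features get factors of 1.  Factors are clamped to ``clamp``
    with a logged warning; a non-positive fitted curve at a run time
    makes the feature uncorrectable there (factor 1).
    """
    if t_ref is None:
        qc_times = schedule.times(klass="QC")
        t_ref = float(qc_times[0]) if qc_times.size else float(
            schedule.times()[0]
        )
    result = CorrectionFactors(fit.feature_id, t_ref)
    if fit.kinetics_type == "steady":
        result.factors = {r: 1.0 for r in schedule.run_ids}
        return result
    f_ref = float(fit.predict(t_ref))
    if f_ref <= 0:
        log.warning("%s: fitted curve non-positive at t_ref; uncorrectable",
                    fit.feature_id)
        result.factors = {r: 1.0 for r in schedule.run_ids}
        result.uncorrectable = True
        return result
    lo, hi = clamp
    for run_id, t_run, _ in schedule.runs:
        f_run = float(fit.predict(t_run))
        if f_run <= 0:
            result.factors[run_id] = 1.0
            result.uncorrectable = True
            continue
        factor = f_ref / f_run
        clamped = min(max(factor, lo), hi)
        if clamped != factor:
            result.clamped = True
        result.factors[run_id] = clamped
    if result.clamped:
        log.warning("%s: correction factors clamped to [%g, %g]",
                    fit.feature_id, lo, hi)
    if result.uncorrectable:
        log.warning("%s: fitted curve non-positive at some runs; those "
                    "runs left uncorrected", fit.feature_id)
    return result


def apply_correction(
    features: list[FeatureRecord],
    factors: dict[str, CorrectionFactors],
) -> list[FeatureRecord]:
    """Multiply each raw intensity by its feature/run factor.

    Missing intensity values stay missing; a missing factor for any
    (feature, run) pair is an error naming the pair.
    """
    corrected = []
    for rec in features:
        if rec.feature_id not in factors:
            raise KeyError(f"no correction factors for feature {rec.feature_id}")
        fac = factors[rec.feature_id].factors
        new_int = {}
        for run, v in rec.intensities.items():
            if run not in fac:
                raise KeyError(
                    f"no correction factor for ({rec.feature_id}, {run})"
                )
            new_int[run] = v * fac[run] if np.isfinite(v) else v
        corrected.append(
            FeatureRecord(
                feature_id=rec.feature_id,
                rt=rec.rt,
                observed_mz=rec.observed_mz,
                composition=rec.composition,
                intensities=new_int,
            )
        )
    return corrected
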