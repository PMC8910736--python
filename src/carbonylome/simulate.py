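"""Synthetic LC-MS batches with planted kinetics, drift and group effects.

The generator emulates a single derivatization batch the way the
correction model assumes it: QC pools injected every ``runs_per_qc``
runs (255-min increments at the defaults) across a ~24 h sequence,
biological samples randomized over the remaining run slots, and per
feature a kinetic class governing how the derivative's signal moves
over clock time:

* class I   - linear increase (solvent evaporation outpaces degradation),
* class II  - linear decrease (derivative degradation),
* class III - gentle decline then a rapid drop after ~1000 min,
* steady    - no trend.

Drifting classes draw a target series RSD uniformly in [10, 55] %
(55 % is about the ceiling a linear ramp can produce); steady features
have no trend.  Noise is multiplicative lognormal with two components:
a shared per-injection (run-level) effect and independent measurement
noise - the shared component is what makes the scaled QC series of
stable analytes cohere into their own cluster, as observed in real
batches.  Drift is common to QCs and samples, so planted group fold
changes are biased without correction and recoverable with it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chh import Ms2Spectrum, NEUTRAL_LOSSES, derivative_from_rcc
from .formula import ElementalFormula, monoisotopic_mass
from .io import CONTROL, QC, TREATED, FeatureRecord, InjectionSchedule
from .registry import reference_rccs

__all__ = ["GroundTruth", "make_schedule", "generate_batch", "synth_ms2",
            "CLASS_COUNTS"]

#: Kinetic class sizes observed for the 194 pea-nodule RCC derivatives.
CLASS_COUNTS: dict[str, int] = {"I": 17, "II": 95, "III": 37, "steady": 45}

#: Fraction of the total noise CV assigned to the shared per-injection
#: effect and to independent measurement noise (3-4-5 split).
RUN_EFFECT_FRACTION = 0.8
MEASUREMENT_FRACTION = 0.6


@dataclass
class GroundTruth:
    """Planted truth for one synthetic feature."""

    feature_id: str
    rcc_formula: str
    kinetics_class: str  # "I" | "II" | "III" | "steady"
    params: dict
    fold_change: float  # >= 1
    direction: str  # "up" | "down" | "none"
    noise_cv: float

    def kinetic(self, t: np.ndarray, t_end: float) -> np.ndarray:
        """Noise-free drift multiplier g(t), g(0) = 1."""
        p = self.params
        if self.kinetics_class == "steady":
            return np.ones_like(t, dtype=float)
        if self.kinetics_class == "I":
            return 1.0 + p["total_change"] * t / t_end
        if self.kinetics_class == "II":
            return 1.0 - p["total_change"] * t / t_end
        tau, early, fend = p["breakpoint"], p["early_loss"], p["final_fraction"]
        late = (1 - early) + (fend - (1 - early)) * (t - tau) / (t_end - tau)
        return np.where(t <= tau, 1 - early * t / tau, late)


def truth_frame(truths: list[GroundTruth]) -> pd.DataFrame:
    rows = []
    for gt in truths:
        rows.append({
            "feature_id": gt.feature_id,
            "rcc_formula": gt.rcc_formula,
            "kinetics_class": gt.kinetics_class,
            "fold_change": gt.fold_change,
            "direction": gt.direction,
            "noise_cv": gt.noise_cv,
            **{f"param_{k}": v for k, v in gt.params.items()},
        })
    return pd.DataFrame(rows)


def make_schedule(
    n_samples: int = 14,
    runs_per_qc: int = 12,
    minutes_per_run: float = 21.25,
    total_minutes: float = 1440.0,
    seed: int | None = None,
) -> InjectionSchedule:
    """Batch schedule: QCs on a regular grid, samples randomized.

    Run slots sit every ``minutes_per_run``; every ``runs_per_qc``-th
    slot is a QC injection (255-min increments at the defaults) and the
    final slot is a closing QC.  ``n_samples`` biological runs (even
    control/treated split, order randomized under ``seed``) are placed
    on randomly chosen remaining slots; other slots are unmonitored
    filler acquisitions and are not listed.
    """
    if n_samples < 2 or n_samples % 2:
        raise ValueError("n_samples must be an even number >= 2")
    if runs_per_qc < 2:
        raise ValueError("runs_per_qc must be >= 2")
    rng = np.random.default_rng(seed)
    n_slots = int(math.floor(total_minutes / minutes_per_run)) + 1
    qc_slots = set(range(0, n_slots, runs_per_qc)) | {n_slots - 1}
    free = [s for s in range(n_slots) if s not in qc_slots]
    if n_samples > len(free):
        raise ValueError("too many samples for the batch length")
    sample_slots = sorted(rng.choice(len(free), size=n_samples, replace=False))
    sample_slots = [free[i] for i in sample_slots]
    classes = [CONTROL] * (n_samples // 2) + [TREATED] * (n_samples // 2)
    rng.shuffle(classes)

    runs = []
    qc_i = s_i = 0
    for slot in range(n_slots):
        t = slot * minutes_per_run
        if slot in qc_slots:
            qc_i += 1
            runs.append((f"QC{qc_i:02d}", t, QC))
        elif slot in sample_slots:
            klass = classes[s_i]
            s_i += 1
            prefix = "C" if klass == CONTROL else "T"
            runs.append((f"{prefix}{s_i:02d}", t, klass))
    return InjectionSchedule(tuple(runs))


def _scale_counts(counts: dict[str, int], n: int) -> dict[str, int]:
    """Rescale the reference class proportions to n features
    (largest-remainder rounding)."""
    total = sum(counts.values())
    exact = {k: v * n / total for k, v in counts.items()}
    out = {k: int(math.floor(v)) for k, v in exact.items()}
    rest = sorted(exact, key=lambda k: exact[k] - out[k], reverse=True)
    for k in rest[: n - sum(out.values())]:
        out[k] += 1
    return out


def _draw_rcc(rng: np.random.Generator) -> ElementalFormula:
    """A reference RCC or a random small carbonyl formula."""
    pool = reference_rccs()
    if rng.random() < 0.5:
        return pool[rng.integers(len(pool))]
    c = int(rng.integers(1, 12))
    o = int(rng.integers(1, 4))
    h = int(rng.integers(max(2, c - 2), 2 * c + 2))
    return ElementalFormula({"C": c, "H": h, "O": o})


def _draw_params(cls: str, rng: np.random.Generator) -> dict:
    if cls == "steady":
        return {}
    if cls == "III":
        return {
            "breakpoint": 1000.0,
            "early_loss": float(rng.uniform(0.02, 0.10)),
            "final_fraction": float(rng.uniform(0.05, 0.50)),
        }
    # linear classes: invert target RSD r of a uniform ramp to its
    # total relative change; r = (d/sqrt(12))/(1 -+ d/2).  Rising ramps
    # (evaporation) are capped lower: RSD 30% already means a ~2.2x
    # concentration gain over the batch.
    s = 1.0 / math.sqrt(12.0)
    if cls == "II":
        r = float(rng.uniform(0.10, 0.55))
        d = r / (s + r / 2.0)
    else:
        r = float(rng.uniform(0.10, 0.30))
        d = r / (s - r / 2.0)
    return {"total_change": d, "target_rsd": r}


def generate_batch(
    schedule: InjectionSchedule,
    n_features: int = 194,
    class_counts: dict[str, int] | None = None,
    fold_changes: dict[str, float] | None = None,
    noise_cv: float = 0.05,
    seed: int | None = None,
    missing_rate: float = 0.0,
    kinetics_overrides: dict[str, dict] | None = None,
) -> tuple[list[FeatureRecord], list[GroundTruth]]:
    """Synthesize a feature table with known ground truth.

    ``class_counts`` must sum to ``n_features`` (defaults to the
    17/95/37/45 proportions rescaled to ``n_features``).  ``fold_changes`` maps feature_id (``F001`` ...)
    to the treated/control intensity ratio; unlisted features are null.
    ``noise_cv`` is the total multiplicative noise CV, split into a
    shared per-injection component (0.8 x) and independent measurement
    noise (0.6 x).  ``kinetics_overrides`` plants exact kinetic
    parameters for selected feature_ids (merged over the random draw);
    the planted values are recorded in the ground truth.  Identical
    seeds give bit-identical tables.
    """
    if class_counts is None:
        counts = _scale_counts(CLASS_COUNTS, n_features)
    else:
        counts = dict(class_counts)
    if sum(counts.values()) != n_features:
        raise ValueError(
            f"class counts {counts} do not sum to n_features={n_features}"
        )
    fold_changes = fold_changes or {}
    kinetics_overrides = kinetics_overrides or {}
    rng = np.random.default_rng(seed)
    run_ids = schedule.run_ids
    times = schedule.times()
    t_end = float(times[-1])
    run_cv = RUN_EFFECT_FRACTION * noise_cv
    meas_cv = MEASUREMENT_FRACTION * noise_cv
    run_effect = (
        rng.lognormal(0.0, run_cv, size=len(run_ids))
        if run_cv > 0 else np.ones(len(run_ids))
    )

    order = [c for c, n in counts.items() for _ in range(n)]
    records: list[FeatureRecord] = []
    truths: list[GroundTruth] = []
    for i, cls in enumerate(order):
        fid = f"F{i + 1:03d}"
        rcc = _draw_rcc(rng)
        cation = derivative_from_rcc(rcc)
        mz = monoisotopic_mass(cation)
        observed = mz * (1 + rng.uniform(-2e-6, 2e-6))
        rt = float(rng.uniform(2.0, 14.0))
        baseline = 10.0 ** rng.uniform(5.0, 8.0)
        ratio = float(fold_changes.get(fid, 1.0))
        if ratio > 1:
            fc, direction = ratio, "up"
        elif ratio < 1:
            fc, direction = 1.0 / ratio, "down"
        else:
            fc, direction = 1.0, "none"
        params = _draw_params(cls, rng)
        if fid in kinetics_overrides:
            params = {**params, **kinetics_overrides[fid]}
            if "target_rsd" in kinetics_overrides[fid] and cls in ("I", "II"):
                r = params["target_rsd"]
                s = 1.0 / math.sqrt(12.0)
                params["total_change"] = (
                    r / (s + r / 2.0) if cls == "II" else r / (s - r / 2.0)
                )
        gt = GroundTruth(fid, rcc.hill(), cls, params, fc, direction, noise_cv)
        g = gt.kinetic(times, t_end)

        qc_base = baseline * (1.0 + ratio) / 2.0  # pool of both groups
        noise = (
            rng.lognormal(0.0, meas_cv, size=len(run_ids))
            if meas_cv > 0 else np.ones(len(run_ids))
        )
        intensities = {}
        for j, (run_id, _, klass) in enumerate(schedule.runs):
            if klass == QC:
                base = qc_base
            elif klass == TREATED:
                base = baseline * ratio
            else:
                base = baseline
            v = base * g[j] * run_effect[j] * noise[j]
            if missing_rate > 0 and rng.random() < missing_rate:
                v = float("nan")
            intensities[run_id] = float(v)
        records.append(FeatureRecord(fid, rt, float(observed), cation,
                                     intensities))
        truths.append(gt)
    return records, truths


def synth_ms2(
    rcc: ElementalFormula,
    losses: tuple[str, ...] = ("H2O",),
) -> Ms2Spectrum:
    """Template CID spectrum of a CHH derivative of ``rcc``.

    Peaks: both diagnostic ions (m/z 244.1, 262.1), the precursor, and
    the precursor minus each requested neutral loss.
    """
    precursor = monoisotopic_mass(derivative_from_rcc(rcc))
    peaks = [(244.1, 100.0), (262.1, 50.0), (round(precursor, 4), 20.0)]
    for name in losses:
        peaks.append((round(precursor - NEUTRAL_LOSSES[name], 4), 30.0))
    peaks = [(m, i) for m, i in peaks if m > 0]
    return Ms2Spectrum(precursor, tuple(sorted(peaks)))
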