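"""QC-based derivative-stability correction as a fitted model.

:class:`StabilityModel` is built from a feature table and an injection
schedule; :meth:`StabilityModel.fit` runs the full correction workflow:

1. extract each feature's QC trajectory and min-max scale it to [-2, 2];
2. k-means the scaled trajectories (euclidean / DTW / DBA metric) into
   ``k`` clusters of shared kinetic behaviour;
3. classify each cluster centroid as linear, two-segment or steady —
   the cluster fixes the model *family*;
4. fit the family's parameters per analyte on its raw QC peak areas;
5. derive per-run correction factors f(t_ref)/f(t_run) and apply them.

The returned :class:`StabilityResults` carries cluster labels,
centroids, per-feature kinetics fits, factors, before/after QC RSDs, a
``summary()`` table and ``correct()`` for new intensities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import QC, FeatureRecord, InjectionSchedule
from .kinetics import (
    CLAMP_BOUNDS,
    STEADY_RSD_THRESHOLD,
    CorrectionFactors,
    KineticsFit,
    apply_correction,
    classify_kinetics,
    correction_factors,
    fit_linear,
    fit_piecewise,
)
from .timeseries import cluster_qc_series, minmax_scale, rsd_percent

__all__ = ["StabilityModel", "StabilityResults"]

log = logging.getLogger(__name__)


class StabilityModel:
    """Correction model for derivative degradation / signal drift.

    Parameters
    ----------
    features : list of FeatureRecord
        Feature table (typically already intensity-filtered).
    schedule : InjectionSchedule
        Batch runs; at least two QC injections are required.
    k : int
        Number of kinetic clusters (five were observed in pea nodules;
        steady clusters merge at correction time).
    metric : {"dba", "dtw", "euclidean"}
        Distance used by the time-series k-means.
    seed, n_init : int
        Restart control of the k-means; deterministic for a fixed seed.
    steady_rsd_threshold : float
        Fitted-series RSD (%) below which an analyte is steady.
    clamp : (float, float)
        Bounds on the correction factors.
    t_ref : float, optional
        Reference time; defaults to the first QC injection.
    """

    def __init__(
        self,
        features: list[FeatureRecord],
        schedule: InjectionSchedule,
        k: int = 5,
        metric: str = "dba",
        seed: int = 0,
        n_init: int = 10,
        steady_rsd_threshold: float = STEADY_RSD_THRESHOLD,
        clamp: tuple[float, float] = CLAMP_BOUNDS,
        t_ref: float | None = None,
    ) -> None:
        if len(schedule.qc_ids) < 2:
            raise ValueError("stability correction needs >= 2 QC runs")
        if not features:
            raise ValueError("no features to fit")
        self.features = list(features)
        self.schedule = schedule
        self.k = k
        self.metric = metric
        self.seed = seed
        self.n_init = n_init
        self.steady_rsd_threshold = steady_rsd_threshold
        self.clamp = clamp
        qc_times = schedule.times(klass=QC)
        self.t_ref = float(qc_times[0]) if t_ref is None else float(t_ref)
        self.qc_times = qc_times

    # ------------------------------------------------------------------
    def qc_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Raw QC series per feature (rows) over QC injections (cols)."""
        qc_ids = self.schedule.qc_ids
        rows, ids = [], []
        for rec in self.features:
            rows.append([rec.intensities.get(r, np.nan) for r in qc_ids])
            ids.append(rec.feature_id)
        return np.asarray(rows, dtype=float), ids

    def fit(self) -> "StabilityResults":
        raw, ids = self.qc_matrix()
        finite = np.isfinite(raw).all(axis=1)
        if not finite.any():
            raise ValueError("no feature has a complete QC series")
        scaled = np.zeros_like(raw)
        scaled[finite] = np.array([minmax_scale(r) for r in raw[finite]])

        km = cluster_qc_series(
            scaled[finite],
            k=min(self.k, int(finite.sum())),
            metric=self.metric,
            seed=self.seed,
            n_init=self.n_init,
        )
        labels = np.full(len(ids), -1)
        labels[finite] = km.labels

        # cluster centroid fixes the model family
        cluster_types: dict[int, str] = {}
        for c in range(km.centroids.shape[0]):
            cfit = classify_kinetics(
                self.qc_times,
                km.centroids[c],
                steady_rsd_threshold=self.steady_rsd_threshold,
            )
            cluster_types[c] = cfit.kinetics_type

        fits: list[KineticsFit] = []
        factors: dict[str, CorrectionFactors] = {}
        for i, rec in enumerate(self.features):
            fid = rec.feature_id
            if not finite[i]:
                log.warning("%s: incomplete QC series; left uncorrected", fid)
                fit = KineticsFit(fid, "steady",
                                  {"kind": "linear", "intercept": 0.0,
                                   "slope": 0.0},
                                  cluster_label=-1)
                fac = CorrectionFactors(fid, self.t_ref,
                                        {r: 1.0 for r in self.schedule.run_ids},
                                        uncorrectable=True)
            else:
                fit = self._fit_feature(fid, raw[i], cluster_types[labels[i]])
                fit.cluster_label = int(labels[i])
                fac = correction_factors(fit, self.schedule, self.t_ref,
                                         self.clamp)
            fits.append(fit)
            factors[fid] = fac

        return StabilityResults(self, labels, km.centroids, cluster_types,
                                fits, factors, raw, ids)

    # ------------------------------------------------------------------
    def _fit_feature(self, fid: str, series: np.ndarray,
                     family: str) -> KineticsFit:
        """Per-analyte parameters under the cluster's model family."""
        t = self.qc_times
        if family == "III" and t.size >= 4:
            model, rss = fit_piecewise(t, series)
        else:
            model, rss = fit_linear(t, series)
        fit = KineticsFit(fid, family, model)
        fitted = fit.predict(t)
        tss = float(((series - series.mean()) ** 2).sum())
        fit.r_squared = 1.0 - rss / tss if tss > 0 else 1.0
        if fitted.mean() > 0:
            fit.rsd_percent = rsd_percent(fitted)
            # a flat member of a drifting cluster is still steady
            if fit.rsd_percent < self.steady_rsd_threshold:
                fit.kinetics_type = "steady"
        if family == "steady":
            fit.kinetics_type = "steady"
        elif fit.kinetics_type != "steady" and family in ("I", "II"):
            # the cluster shape carries the direction
            fit.kinetics_type = family
        return fit


@dataclass
class StabilityResults:
    """Fitted stability correction; see :class:`StabilityModel`."""

    model: StabilityModel
    labels_: np.ndarray
    centroids_: np.ndarray
    cluster_types_: dict[int, str]
    kinetics: list[KineticsFit]
    factors: dict[str, CorrectionFactors]
    qc_raw_: np.ndarray
    feature_ids: list[str]

    # -- application --------------------------------------------------
    def correct(self, features: list[FeatureRecord] | None = None
                ) -> list[FeatureRecord]:
        """Apply the fitted factors (default: to the training features)."""
        feats = self.model.features if features is None else features
        return apply_correction(feats, self.factors)

    # -- diagnostics --------------------------------------------------
    def qc_rsd(self) -> pd.DataFrame:
        """Per-feature QC RSD% before and after self-correction."""
        qc_ids = self.model.schedule.qc_ids
        rows = []
        for i, fid in enumerate(self.feature_ids):
            raw = self.qc_raw_[i]
            fac = np.array([self.factors[fid].factors[r] for r in qc_ids])
            ok = np.isfinite(raw).all()
            rows.append({
                "feature_id": fid,
                "rsd_before": rsd_percent(raw) if ok else np.nan,
                "rsd_after": rsd_percent(raw * fac) if ok else np.nan,
            })
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        """Correction report: cluster, type, model parameters, RSDs."""
        rsd = self.qc_rsd().set_index("feature_id")
        rows = []
        for fit in self.kinetics:
            m = fit.model
            rows.append({
                "feature_id": fit.feature_id,
                "cluster": fit.cluster_label,
                "kinetics_type": fit.kinetics_type,
                "model": m["kind"],
                "intercept": m.get("intercept", np.nan),
                "slope": m.get("slope", m.get("slope1", np.nan)),
                "breakpoint": m.get("breakpoint", np.nan),
                "late_slope": m.get("slope2", np.nan),
                "r_squared": fit.r_squared,
                "rsd_before": rsd.loc[fit.feature_id, "rsd_before"],
                "rsd_after": rsd.loc[fit.feature_id, "rsd_after"],
                "clamped": self.factors[fit.feature_id].clamped,
                "uncorrectable": self.factors[fit.feature_id].uncorrectable,
            })
        return pd.DataFrame(rows)

    def factors_frame(self) -> pd.DataFrame:
        """Features x runs matrix of correction factors."""
        run_ids = self.model.schedule.run_ids
        data = {
            fid: [self.factors[fid].factors[r] for r in run_ids]
            for fid in self.feature_ids
        }
        return pd.DataFrame(data, index=run_ids).T

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        df = self.to_frame()
        counts = df["kinetics_type"].value_counts()
        lines = [
            "Stability correction summary",
            "============================",
            f"features: {len(df)}   clusters (k): {self.centroids_.shape[0]}"
            f"   metric: {self.model.metric}   t_ref: {self.model.t_ref:g} min",
            "kinetics types: "
            + ", ".join(f"{t}: {counts.get(t, 0)}"
                        for t in ("I", "II", "III", "steady")),
            "median QC RSD% before -> after: "
            f"{df['rsd_before'].median():.1f} -> {df['rsd_after'].median():.1f}",
            f"clamped: {int(df['clamped'].sum())}   "
            f"uncorrectable: {int(df['uncorrectable'].sum())}",
        ]
        return "\n".join(lines)

    def plot_centroids(self, ax=None):
        """Cluster centroids over QC time (scaled units)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.model.qc_times
        for c, centroid in enumerate(self.centroids_):
            ax.plot(t, centroid, marker="o",
                    label=f"cluster {c} ({self.cluster_types_[c]})")
        ax.set_xlabel("QC injection time (min)")
        ax.set_ylabel("scaled peak area")
        ax.legend()
        return ax
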