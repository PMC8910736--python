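"""Feature tables and injection metadata.

The pipeline starts from integrated LC-MS peak areas: a table with one
row per feature (retention time, observed m/z, optional cation
composition) and one column per run, plus an injection schedule giving
each run's clock time and class (QC pool, control or treated sample).
Missing peak areas are carried explicitly as NaN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .formula import ElementalFormula

__all__ = [
    "QC",
    "CONTROL",
    "TREATED",
    "FeatureRecord",
    "InjectionSchedule",
    "read_feature_table",
    "write_feature_table",
    "records_to_frame",
    "frame_to_records",
    "filter_by_intensity",
    "INTENSITY_THRESHOLD",
]

log = logging.getLogger(__name__)

QC = "QC"
CONTROL = "control"
TREATED = "treated"

#: Inclusion threshold on QC peak areas (counts).
INTENSITY_THRESHOLD = 1.0e5

_META_COLUMNS = ["feature_id", "rt", "mz", "composition"]


@dataclass
class FeatureRecord:
    """One annotated LC-MS feature with per-run peak areas."""

    feature_id: str
    rt: float
    observed_mz: float
    composition: ElementalFormula | None = None
    intensities: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rt < 0:
            raise ValueError(f"{self.feature_id}: negative retention time")
        if self.observed_mz <= 0:
            raise ValueError(f"{self.feature_id}: non-positive m/z")
        for run, v in self.intensities.items():
            if np.isfinite(v) and v < 0:
                raise ValueError(f"{self.feature_id}: negative area in {run}")


@dataclass(frozen=True)
class InjectionSchedule:
    """Ordered batch runs: (run_id, clock time in minutes, class)."""

    runs: tuple[tuple[str, float, str], ...]

    def __post_init__(self) -> None:
        times = [t for _, t, _ in self.runs]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("clock times must be strictly increasing")
        for _, _, klass in self.runs:
            if klass not in (QC, CONTROL, TREATED):
                raise ValueError(f"unknown run class {klass!r}")
        ids = [r for r, _, _ in self.runs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate run_id in schedule")

    # -- accessors ---------------------------------------------------
    @property
    def run_ids(self) -> list[str]:
        return [r for r, _, _ in self.runs]

    def times(self, klass: str | None = None) -> np.ndarray:
        return np.array(
            [t for _, t, k in self.runs if klass is None or k == klass]
        )

    def ids_of(self, klass: str) -> list[str]:
        return [r for r, _, k in self.runs if k == klass]

    @property
    def qc_ids(self) -> list[str]:
        return self.ids_of(QC)

    def time_of(self, run_id: str) -> float:
        for r, t, _ in self.runs:
            if r == run_id:
                return t
        raise KeyError(run_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.runs, columns=["run_id", "time_min", "class"])

    # -- serialization -----------------------------------------------
    @classmethod
    def from_csv(cls, path) -> "InjectionSchedule":
        df = pd.read_csv(path, sep=_sep(path), comment="#")
        required = {"run_id", "time_min", "class"}
        if not required.issubset(df.columns):
            raise ValueError(f"schedule must have columns {sorted(required)}")
        return cls(
            tuple(
                (str(r.run_id), float(r.time_min), str(r["class"]))
                for _, r in df.iterrows()
            )
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, sep=_sep(path), index=False)


def _sep(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_feature_table(path, schedule: InjectionSchedule) -> list[FeatureRecord]:
    """Read a features x runs TSV/CSV into records.

    The header must name every scheduled run; unparseable intensity
    cells become NaN with a logged warning.
    """
    df = pd.read_csv(path, sep=_sep(path), dtype=str, comment="#")
    missing = [c for c in _META_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ValueError(f"feature table lacks columns: {missing}")
    orphans = [r for r in schedule.run_ids if r not in df.columns]
    if orphans:
        raise ValueError(f"scheduled runs absent from table header: {orphans}")
    records = []
    for _, row in df.iterrows():
        intensities = {}
        for run in schedule.run_ids:
            raw = row[run]
            try:
                intensities[run] = float(raw)
            except (TypeError, ValueError):
                log.warning(
                    "feature %s run %s: unparseable cell %r -> missing",
                    row["feature_id"], run, raw,
                )
                intensities[run] = float("nan")
        comp = None
        comp_text = row.get("composition")
        if isinstance(comp_text, str) and comp_text.strip():
            comp = ElementalFormula.parse(comp_text.strip(), charge=1)
        records.append(
            FeatureRecord(
                feature_id=str(row["feature_id"]),
                rt=float(row["rt"]),
                observed_mz=float(row["mz"]),
                composition=comp,
                intensities=intensities,
            )
        )
    return records


def records_to_frame(
    records: list[FeatureRecord], schedule: InjectionSchedule
) -> pd.DataFrame:
    """Features x runs DataFrame with leading metadata columns."""
    rows = []
    for rec in records:
        row = {
            "feature_id": rec.feature_id,
            "rt": rec.rt,
            "mz": rec.observed_mz,
            "composition": rec.composition.hill() if rec.composition else "",
        }
        for run in schedule.run_ids:
            row[run] = rec.intensities.get(run, np.nan)
        rows.append(row)
    return pd.DataFrame(rows, columns=_META_COLUMNS + schedule.run_ids)


def frame_to_records(
    df: pd.DataFrame, schedule: InjectionSchedule
) -> list[FeatureRecord]:
    records = []
    for _, row in df.iterrows():
        comp = None
        if isinstance(row.get("composition"), str) and row["composition"].strip():
            comp = ElementalFormula.parse(row["composition"].strip(), charge=1)
        records.append(
            FeatureRecord(
                feature_id=str(row["feature_id"]),
                rt=float(row["rt"]),
                observed_mz=float(row["mz"]),
                composition=comp,
                intensities={r: float(row[r]) for r in schedule.run_ids},
            )
        )
    return records


def write_feature_table(
    records: list[FeatureRecord], path, schedule: InjectionSchedule
) -> None:
    records_to_frame(records, schedule).to_csv(path, sep=_sep(path), index=False)


def filter_by_intensity(
    features: list[FeatureRecord],
    schedule: InjectionSchedule,
    threshold: float = INTENSITY_THRESHOLD,
) -> list[FeatureRecord]:
    """Keep features whose maximum QC peak area exceeds ``threshold``.

    QC pools combine all samples, so any real feature must appear there;
    the inclusion filter is therefore evaluated on QC maxima.  Order is
    preserved and the operation is idempotent.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if threshold == 0:
        return list(features)
    qc_ids = schedule.qc_ids
    kept = []
    for rec in features:
        finite = [
            v
            for r in qc_ids
            if np.isfinite(v := rec.intensities.get(r, float("nan")))
        ]
        if finite and max(finite) > threshold:
            kept.append(rec)
    return kept
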