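"""Group comparison of corrected intensities.

Control vs treated means are compared per feature with the two-sided
pooled-variance (Student) t-test; fold changes are reported as a ratio
>= 1 with an up/down direction, matching the convention of untargeted
metabolomics tables.  No multiple-testing correction is applied by
default (the significance gate is the raw p <= alpha); Benjamini-
Hochberg adjustment is available behind a flag.  Significant features
can be ordered by Ward hierarchical clustering on z-scored intensities
for heatmap display.  The leaf-relative-water-content helper used in
drought phenotyping lives here as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .io import CONTROL, TREATED, FeatureRecord, InjectionSchedule

__all__ = [
    "t_test_pooled",
    "fold_change",
    "differential_table",
    "hcluster_heatmap",
    "lrwc",
    "DifferentialAbundance",
    "DifferentialResults",
]

log = logging.getLogger(__name__)


def t_test_pooled(x, y) -> tuple[float, float]:
    """Two-sided pooled-variance t-test; df = n1 + n2 - 2.

    Returns (t statistic, p value) for treated (y) against control (x).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >= 2 values")
    res = stats.ttest_ind(y, x, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def fold_change(mean_control: float, mean_treated: float
                ) -> tuple[float, str]:
    """Ratio of group means reported >= 1, with an up/down direction."""
    if mean_control <= 0 or mean_treated <= 0:
        raise ValueError("group means must be positive")
    if mean_treated > mean_control:
        return mean_treated / mean_control, "up"
    if mean_treated < mean_control:
        return mean_control / mean_treated, "down"
    return 1.0, "none"


def lrwc(fresh_weight: float, dry_weight: float) -> float:
    """Leaf relative water content, (fresh - dry) x 100 / fresh, in %."""
    if fresh_weight <= 0:
        raise ValueError("fresh weight must be positive")
    if dry_weight > fresh_weight or dry_weight < 0:
        raise ValueError("dry weight must be in [0, fresh weight]")
    return (fresh_weight - dry_weight) * 100.0 / fresh_weight


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def differential_table(
    features: list[FeatureRecord],
    schedule: InjectionSchedule,
    alpha: float = 0.05,
    log2_transform: bool = False,
    bh: bool = False,
) -> pd.DataFrame:
    """One row per feature: means, fold change, t-test, significance.

    Features with fewer than two finite values in either group are
    skipped with a warning; Shapiro-Wilk p-values are reported for
    information only (nothing is excluded on normality grounds).
    """
    ctrl_ids = schedule.ids_of(CONTROL)
    trt_ids = schedule.ids_of(TREATED)
    rows = []
    for rec in features:
        x = np.array([rec.intensities.get(r, np.nan) for r in ctrl_ids])
        y = np.array([rec.intensities.get(r, np.nan) for r in trt_ids])
        x, y = x[np.isfinite(x)], y[np.isfinite(y)]
        if x.size < 2 or y.size < 2:
            log.warning("%s: fewer than 2 finite values in a group; skipped",
                        rec.feature_id)
            continue
        mean_c, mean_t = float(x.mean()), float(y.mean())
        if mean_c <= 0 or mean_t <= 0:
            log.warning("%s: non-positive group mean; flagged", rec.feature_id)
            fc, direction = np.nan, "undefined"
        else:
            fc, direction = fold_change(mean_c, mean_t)
        tx, ty = (np.log2(x), np.log2(y)) if log2_transform else (x, y)
        t_stat, p = t_test_pooled(tx, ty)
        shapiro_p = float(
            stats.shapiro(np.concatenate([tx - tx.mean(), ty - ty.mean()])).pvalue
        )
        rows.append({
            "feature_id": rec.feature_id,
            "rt": rec.rt,
            "mz": rec.observed_mz,
            "composition": rec.composition.hill() if rec.composition else "",
            "mean_control": mean_c,
            "mean_treated": mean_t,
            "fold_change": fc,
            "direction": direction,
            "t_stat": t_stat,
            "p_value": p,
            "shapiro_p": shapiro_p,
        })
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    if bh:
        df["p_adjusted"] = _bh_adjust(df["p_value"].to_numpy())
        df["significant"] = df["p_adjusted"] <= alpha
    else:
        df["significant"] = df["p_value"] <= alpha
    return df


def hcluster_heatmap(
    significant: pd.DataFrame,
    features: list[FeatureRecord],
    schedule: InjectionSchedule,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Ward linkage over z-scored intensities of significant features.

    Returns the scipy linkage matrix and the feature x sample matrix
    reordered by the deterministic leaf order.  Needs >= 2 significant
    features.
    """
    ids = list(significant["feature_id"])
    if len(ids) < 2:
        raise ValueError("hierarchical clustering needs >= 2 features")
    sample_ids = schedule.ids_of(CONTROL) + schedule.ids_of(TREATED)
    lookup = {rec.feature_id: rec for rec in features}
    mat = np.array([
        [lookup[f].intensities.get(r, np.nan) for r in sample_ids]
        for f in ids
    ])
    mu = np.nanmean(mat, axis=1, keepdims=True)
    sd = np.nanstd(mat, axis=1, ddof=1, keepdims=True)
    z = (mat - mu) / np.where(sd > 0, sd, 1.0)
    link = hierarchy.ward(z)
    order = hierarchy.leaves_list(link)
    ordered = pd.DataFrame(z[order], index=[ids[i] for i in order],
                           columns=sample_ids)
    return link, ordered


# ----------------------------------------------------------------------
class DifferentialAbundance:
    """Model object for the control-vs-treated comparison.

    Parameters mirror :func:`differential_table`; ``fit()`` returns a
    :class:`DifferentialResults` carrying the per-feature table.
    """

    def __init__(
        self,
        features: list[FeatureRecord],
        schedule: InjectionSchedule,
        alpha: float = 0.05,
        log2_transform: bool = False,
        bh: bool = False,
    ) -> None:
        if not schedule.ids_of(CONTROL) or not schedule.ids_of(TREATED):
            raise ValueError("schedule must contain both sample groups")
        self.features = list(features)
        self.schedule = schedule
        self.alpha = alpha
        self.log2_transform = log2_transform
        self.bh = bh

    def fit(self) -> "DifferentialResults":
        table = differential_table(
            self.features, self.schedule, self.alpha,
            self.log2_transform, self.bh,
        )
        return DifferentialResults(self, table)


@dataclass
class DifferentialResults:
    model: DifferentialAbundance
    table: pd.DataFrame

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def hcluster(self) -> tuple[np.ndarray, pd.DataFrame]:
        return hcluster_heatmap(self.significant, self.model.features,
                                self.model.schedule)

    def summary(self) -> str:
        sig = self.significant
        up = (sig["direction"] == "up").sum()
        down = (sig["direction"] == "down").sum()
        lines = [
            "Differential abundance summary",
            "==============================",
            f"features tested: {len(self.table)}   alpha: {self.model.alpha}"
            + ("   (Benjamini-Hochberg)" if self.model.bh else ""),
            f"significant: {len(sig)} ({up} up, {down} down)",
        ]
        if len(sig):
            top = sig.nsmallest(min(5, len(sig)), "p_value")
            lines.append("top features (fold change, direction, p):")
            for _, r in top.iterrows():
                lines.append(
                    f"  {r.feature_id}: {r.fold_change:.2f} {r.direction}"
                    f"  p={r.p_value:.2e}"
                )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def plot_heatmap(self, ax=None):
        """Heatmap of z-scored significant features in leaf order."""
        import matplotlib.pyplot as plt

        _, ordered = self.hcluster()
        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="RdBu_r")
        ax.set_yticks(range(len(ordered.index)), ordered.index, fontsize=6)
        ax.set_xticks(range(len(ordered.columns)), ordered.columns,
                      rotation=90, fontsize=6)
        plt.colorbar(im, ax=ax, label="z-score")
        return ax

    def plot_density(self, ax=None):
        """Per-group intensity density plots (normality screening aid)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sched = self.model.schedule
        for klass in (CONTROL, TREATED):
            ids = sched.ids_of(klass)
            vals = np.log10([
                v
                for rec in self.model.features
                for r in ids
                if np.isfinite(v := rec.intensities.get(r, np.nan)) and v > 0
            ])
            ax.hist(vals, bins=40, density=True, alpha=0.5, label=klass)
        ax.set_xlabel("log10 intensity")
        ax.set_ylabel("density")
        ax.legend()
        return ax
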