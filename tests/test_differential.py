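"""Pooled t-test, fold changes, differential tables, Ward clustering."""

import numpy as np
import pytest

from carbonylome.differential import (
    DifferentialAbundance,
    differential_table,
    fold_change,
    hcluster_heatmap,
    lrwc,
    t_test_pooled,
)
from carbonylome.io import CONTROL, QC, TREATED, FeatureRecord, InjectionSchedule
from carbonylome.simulate import generate_batch, make_schedule


def pooled_t_oracle(x, y):
    """Textbook pooled-variance t statistic (treated minus control)."""
    from scipy import stats

    x, y = np.asarray(x), np.asarray(y)
    n1, n2 = len(x), len(y)
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    t = (y.mean() - x.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), n1 + n2 - 2)
    return t, p


class TestTTest:
    def test_identical_groups(self):
        t, p = t_test_pooled([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_large_shift_significant(self):
        _, p = t_test_pooled([1.0, 2.0, 3.0], [101.0, 102.0, 103.0])
        assert p < 0.05

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            x = rng.normal(size=rng.integers(3, 12))
            y = rng.normal(0.5, size=rng.integers(3, 12))
            t, p = t_test_pooled(x, y)
            to, po = pooled_t_oracle(x, y)
            assert t == pytest.approx(to, abs=1e-10)
            assert p == pytest.approx(po, abs=1e-10)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=6), rng.normal(1, size=6)
        t1, p1 = t_test_pooled(x, y)
        t2, p2 = t_test_pooled(3 * x + 10, 3 * y + 10)
        assert t1 == pytest.approx(t2) and p1 == pytest.approx(p2)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            t_test_pooled([1.0], [1.0, 2.0])


class TestFoldChange:
    def test_up(self):
        assert fold_change(100.0, 270.0) == (pytest.approx(2.7), "up")

    def test_down(self):
        assert fold_change(530.0, 100.0) == (pytest.approx(5.3), "down")

    def test_tie(self):
        assert fold_change(100.0, 100.0) == (1.0, "none")

    def test_antisymmetric(self):
        fc_a, dir_a = fold_change(3.0, 7.5)
        fc_b, dir_b = fold_change(7.5, 3.0)
        assert fc_a == pytest.approx(fc_b)
        assert {dir_a, dir_b} == {"up", "down"}

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fold_change(0.0, 1.0)


class TestLrwc:
    @pytest.mark.parametrize(("fresh", "dry", "expected"),
                             [(2.0, 1.0, 50.0), (1.0, 1.0, 0.0),
                              (1.0, 0.0, 100.0)])
    def test_formula(self, fresh, dry, expected):
        assert lrwc(fresh, dry) == pytest.approx(expected)

    def test_dry_above_fresh_rejected(self):
        with pytest.raises(ValueError):
            lrwc(1.0, 2.0)


def _group_schedule(n_per_group=7):
    runs = [("QC01", 0.0, QC)]
    t = 10.0
    for i in range(n_per_group):
        runs.append((f"C{i:02d}", t, CONTROL)); t += 10
        runs.append((f"T{i:02d}", t, TREATED)); t += 10
    runs.append(("QC02", t, QC))
    return InjectionSchedule(tuple(runs))


class TestDifferentialTable:
    def test_planted_effects_recovered_nulls_controlled(self):
        """3 planted 2.5-fold features out of 23 recovered; false positives
        within binomial expectation at alpha."""
        rng = np.random.default_rng(12)
        sched = _group_schedule()
        recs = []
        for i in range(23):
            ratio = 2.5 if i < 3 else 1.0
            base = 1e6
            intens = {}
            for run, _, klass in sched.runs:
                mult = ratio if klass == TREATED else 1.0
                intens[run] = base * mult * rng.lognormal(0, 0.10)
            recs.append(FeatureRecord(f"F{i:03d}", 1.0, 300.0,
                                      intensities=intens))
        df = differential_table(recs, sched).set_index("feature_id")
        planted = [f"F{i:03d}" for i in range(3)]
        assert df.loc[planted, "significant"].all()
        assert (df.loc[planted, "direction"] == "up").all()
        false_pos = df.drop(planted)["significant"].sum()
        assert false_pos <= 3  # 20 nulls at alpha 0.05: P(>3 FP) < 1e-3

    def test_alpha_zero_nothing_significant(self, small_batch):
        sched, records, _ = small_batch
        df = differential_table(records, sched, alpha=0.0)
        assert not df["significant"].any()

    def test_bh_flag_adds_adjusted_column(self, small_batch):
        sched, records, _ = small_batch
        df = differential_table(records, sched, bh=True)
        assert "p_adjusted" in df.columns
        assert (df["p_adjusted"] >= df["p_value"] - 1e-12).all()

    def test_results_object_summary(self, small_batch):
        sched, records, _ = small_batch
        res = DifferentialAbundance(records, sched).fit()
        assert "significant" in res.summary()


class TestHierarchicalClustering:
    def test_identical_rows_merge_first(self, toy_schedule):
        import pandas as pd

        recs = []
        for fid, scale in (("A1", 1.0), ("A2", 1.0), ("B1", 5.0)):
            intens = {r: scale * (i + 1) for i, r in
                      enumerate(toy_schedule.run_ids)}
            recs.append(FeatureRecord(fid, 1.0, 300.0, intensities=intens))
        sig = pd.DataFrame({"feature_id": ["A1", "A2", "B1"]})
        link, ordered = hcluster_heatmap(sig, recs, toy_schedule)
        assert link[0][2] == pytest.approx(0.0, abs=1e-12)  # A1-A2 at zero
        assert len(ordered) == 3

    def test_planted_blocks_recovered(self):
        """Two blocks of correlated features split exactly at k=2."""
        import pandas as pd
        from scipy.cluster import hierarchy

        rng = np.random.default_rng(4)
        sched = _group_schedule(4)
        sample_ids = sched.ids_of(CONTROL) + sched.ids_of(TREATED)
        base_a = rng.normal(0, 1, size=len(sample_ids))
        base_b = -base_a
        recs, names = [], []
        for block, base in (("A", base_a), ("B", base_b)):
            for i in range(5):
                vals = 1e6 * np.exp(base + rng.normal(0, 0.05,
                                                      size=len(sample_ids)))
                intens = dict(zip(sample_ids, vals))
                intens.update({q: 1e6 for q in sched.qc_ids})
                fid = f"{block}{i}"
                recs.append(FeatureRecord(fid, 1.0, 300.0,
                                          intensities=intens))
                names.append(fid)
        sig = pd.DataFrame({"feature_id": names})
        link, _ = hcluster_heatmap(sig, recs, sched)
        cut = hierarchy.fcluster(link, 2, criterion="maxclust")
        groups = {}
        for fid, c in zip(names, cut):
            groups.setdefault(c, set()).add(fid[0])
        assert sorted(v.pop() for v in groups.values()) == ["A", "B"]

    def test_single_feature_rejected(self, toy_schedule):
        import pandas as pd

        rec = FeatureRecord("A", 1.0, 300.0, intensities={
            r: 1.0 for r in toy_schedule.run_ids})
        with pytest.raises(ValueError):
            hcluster_heatmap(pd.DataFrame({"feature_id": ["A"]}), [rec],
                             toy_schedule)
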