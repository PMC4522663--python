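"""Region classification: group partition, GC measures, exclusion flags
and the combined at-risk criteria."""

import numpy as np
import pandas as pd
import pytest

from capdesign.classify import (
    annotate_exclusions,
    assign_groups,
    boxplot_summary,
    gc_content,
    gc_cutoffs,
    risk_report,
    size_stratified_completeness,
)
from capdesign.coverage import RegionCoverage, sample_coverage_summary
from capdesign.design import Design
from capdesign.intervals import IntervalSet


def rc(rid, length, min_d, max_d, covered):
    return RegionCoverage(region_id=rid, length=length, min_depth=min_d,
                          max_depth=max_d, covered_bp=covered)


class TestAssignGroups:
    def test_trichotomy(self):
        # region 0 fully covered everywhere, 1 never reaches 5x, 2 mixed
        sample_a = [rc(0, 10, 5, 9, 10), rc(1, 10, 0, 4, 0), rc(2, 10, 5, 9, 10)]
        sample_b = [rc(0, 10, 6, 9, 10), rc(1, 10, 0, 3, 0), rc(2, 10, 0, 9, 5)]
        groups = assign_groups([sample_a, sample_b])
        assert list(groups) == [1, 3, 2]

    def test_partition_is_exhaustive_and_disjoint(self, cohort_coverage):
        groups = assign_groups([r for _, r in cohort_coverage])
        counts = {g: int((groups == g).sum()) for g in (1, 2, 3)}
        assert sum(counts.values()) == len(groups)
        assert set(np.unique(groups)) <= {1, 2, 3}

    def test_mismatched_universe_rejected(self):
        a = [rc(0, 10, 5, 9, 10)]
        b = [rc(0, 10, 5, 9, 10), rc(1, 10, 5, 9, 10)]
        with pytest.raises(ValueError):
            assign_groups([a, b])


class TestGC:
    GENOME = {"chr1": "GCGCATGCANGCNNNN"}

    def test_pure_gc(self):
        from capdesign.io import GenomicInterval

        assert gc_content(self.GENOME, GenomicInterval("chr1", 0, 4)) == 100.0

    def test_half_gc(self):
        from capdesign.io import GenomicInterval

        assert gc_content(self.GENOME, GenomicInterval("chr1", 4, 8)) == 50.0

    def test_ambiguous_bases_excluded_from_denominator(self):
        from capdesign.io import GenomicInterval

        # "ANGC": 2 GC of 3 unambiguous
        v = gc_content(self.GENOME, GenomicInterval("chr1", 8, 12))
        assert v == pytest.approx(66.666, abs=0.01)

    def test_all_n_is_nan(self):
        from capdesign.io import GenomicInterval

        assert np.isnan(gc_content(self.GENOME, GenomicInterval("chr1", 12, 16)))

    def test_out_of_bounds_rejected(self):
        from capdesign.io import GenomicInterval

        with pytest.raises(ValueError):
            gc_content(self.GENOME, GenomicInterval("chr1", 10, 40))


class TestGCCutoffs:
    def test_linear_interpolation_order_statistics(self):
        lo, hi = gc_cutoffs(list(range(1, 101)))
        assert lo == pytest.approx(3.475)
        assert hi == pytest.approx(97.525)

    def test_constant_list(self):
        lo, hi = gc_cutoffs([42.0, 42.0, 42.0])
        assert lo == hi == 42.0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            gc_cutoffs([50.0])


class TestExclusionFlags:
    def test_partial_overlap_flags(self):
        d = Design("d", IntervalSet([("chr1", 0, 100), ("chr1", 200, 300)]))
        flags = annotate_exclusions(
            d,
            ns=IntervalSet([("chr1", 50, 60)]),
            repeats=IntervalSet(),
            predicted_unseq=IntervalSet([("chr1", 250, 400)]),
        )
        assert bool(flags.loc[0, "ns"]) and not bool(flags.loc[0, "repeats"])
        assert bool(flags.loc[0, "any_exclusion"])
        assert bool(flags.loc[1, "predicted_unsequenced"]) and not bool(flags.loc[1, "ns"])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_mask_overlap_oracle(self, seed):
        from conftest import mask_of, random_interval_set

        rng = np.random.default_rng(seed)
        d = Design("d", IntervalSet(
            ("chr1", int(i * 200), int(i * 200 + 120)) for i in range(40)
        ))
        tracks = {name: random_interval_set(rng, n=20) for name in ("ns", "rep", "pred")}
        flags = annotate_exclusions(d, tracks["ns"], tracks["rep"], tracks["pred"])
        masks = {k: mask_of(v) for k, v in tracks.items()}
        for rid, iv in d.iter_regions():
            assert bool(flags.loc[rid, "ns"]) == bool(masks["ns"][iv.start:iv.end].any())
            assert bool(flags.loc[rid, "repeats"]) == bool(masks["rep"][iv.start:iv.end].any())
            assert bool(flags.loc[rid, "predicted_unsequenced"]) == bool(
                masks["pred"][iv.start:iv.end].any()
            )


class TestRiskReport:
    @staticmethod
    def _flags(n, ns=(), pred=()):
        df = pd.DataFrame({
            "ns": [i in ns for i in range(n)],
            "repeats": [False] * n,
            "predicted_unsequenced": [i in pred for i in range(n)],
        })
        df["any_exclusion"] = df["ns"] | df["repeats"]
        df.index.name = "region_id"
        return df

    def test_no_risk_when_all_inside_cutoffs_unflagged(self):
        n = 10
        groups = np.ones(n, dtype=int)
        gc = np.linspace(40, 60, n)
        rep = risk_report(groups, gc, (32.0, 64.5), self._flags(n))
        g1 = rep.groups[1]
        assert g1.pct_extreme_gc == 0.0
        assert g1.pct_at_risk_gc_or_exclusion == 0.0

    def test_disjoint_criteria_add_up(self):
        # 30% extreme GC and 10% flagged, disjoint -> 40% at risk
        n = 10
        groups = np.full(n, 2, dtype=int)
        gc = np.array([80.0, 80, 80, 50, 50, 50, 50, 50, 50, 50])
        rep = risk_report(groups, gc, (32.0, 64.5), self._flags(n, ns=(5,)))
        g2 = rep.groups[2]
        assert g2.pct_extreme_gc == 30.0
        assert g2.pct_any_exclusion == 10.0
        assert g2.pct_at_risk_gc_or_exclusion == 40.0

    def test_boundary_gc_counts_as_sequenceable(self):
        groups = np.ones(4, dtype=int)
        gc = np.array([32.0, 64.5, 31.9, 64.6])
        rep = risk_report(groups, gc, (32.0, 64.5), self._flags(4))
        assert rep.groups[1].pct_extreme_gc == 50.0

    def test_invariant_to_region_relabeling(self):
        rng = np.random.default_rng(0)
        n = 50
        groups = rng.integers(1, 4, size=n)
        gc = rng.uniform(20, 80, size=n)
        flags = self._flags(n, ns=tuple(range(0, n, 7)), pred=tuple(range(0, n, 11)))
        rep1 = risk_report(groups, gc, (32.0, 64.5), flags)
        perm = rng.permutation(n)
        flags2 = flags.iloc[perm].reset_index(drop=True)
        flags2.index.name = "region_id"
        rep2 = risk_report(groups[perm], gc[perm], (32.0, 64.5), flags2)
        assert rep1 == rep2

    def test_dropping_flagged_never_increases_count(self, cohort, cohort_coverage):
        from capdesign.classify import assign_groups
        from capdesign.coverage import RegionCoverage  # noqa: F401

        groups = assign_groups([r for _, r in cohort_coverage])
        ann = cohort.annotation
        flags = annotate_exclusions(cohort.design_plus, ann.ns, ann.repeats,
                                    ann.predicted_unseq)
        for g in (1, 2, 3):
            sel = groups == g
            kept = sel & ~flags["any_exclusion"].to_numpy()
            assert kept.sum() <= sel.sum()


class TestSizeStratified:
    def _make(self, lengths, fully):
        d = Design("d", IntervalSet(
            ("chr1", int(1000 * i), int(1000 * i + L)) for i, L in enumerate(lengths)
        ))
        regions = [
            rc(i, L, 5 if f else 0, 9, L if f else 0)
            for i, (L, f) in enumerate(zip(lengths, fully))
        ]
        return d, [regions]

    def test_all_covered_no_difference(self):
        d, per = self._make([100, 100, 400, 400], [True] * 4)
        df = size_stratified_completeness(d, per)
        assert df.loc["mean", "diff_points"] == 0.0

    def test_only_short_covered_full_difference(self):
        d, per = self._make([100, 100, 400, 400], [True, True, False, False])
        df = size_stratified_completeness(d, per)
        assert df.loc["mean", "pct_full_short"] == 100.0
        assert df.loc["mean", "pct_full_long"] == 0.0
        assert df.loc["mean", "diff_points"] == 100.0

    def test_matches_direct_counting_on_simulated_dropout(self):
        rng = np.random.default_rng(2)
        lengths = rng.integers(100, 500, size=60)
        # dropout probability grows with length
        fully = rng.random(60) > lengths / 600
        d, per = self._make(lengths.tolist(), fully.tolist())
        df = size_stratified_completeness(d, per, size_cutoff=260)
        short = lengths < 260
        assert df.iloc[0]["pct_full_short"] == round(100 * fully[short].mean(), 1)
        assert df.iloc[0]["pct_full_long"] == round(100 * fully[~short].mean(), 1)


def test_boxplot_summary_quartiles_and_outliers():
    vals = list(range(1, 101)) + [1000.0]
    box = boxplot_summary(vals)
    assert box["q1"] < box["median"] < box["q3"]
    assert box["n_outliers"] == 1
    assert box["whisker_hi"] <= box["q3"] + 1.5 * (box["q3"] - box["q1"])
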