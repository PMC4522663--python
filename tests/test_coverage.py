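"""Coverage engine: threshold semantics, brute-force recount oracles,
on-target accounting, reproducibility and subset projection."""

import numpy as np
import pytest

from capdesign.coverage import (
    coverage_fraction_curve,
    pct_reads_on_target,
    project_to_subset,
    reproducibility,
    sample_coverage_summary,
)
from capdesign.design import Design
from capdesign.intervals import IntervalSet
from capdesign.io import AlignedRead, DepthTrack
from conftest import mask_of


def track_from_dense(depths, chrom="chr1", offset=0):
    runs = [(offset + i, offset + i + 1, int(d)) for i, d in enumerate(depths) if d > 0]
    return DepthTrack({chrom: runs} if runs else {})


class TestSampleCoverage:
    def test_uniform_at_threshold_fully_covered(self):
        d = Design("d", IntervalSet([("chr1", 0, 4)]))
        summary, regions = sample_coverage_summary(track_from_dense([5, 5, 5, 5]), d)
        assert regions[0].fully_covered and regions[0].frac_covered == 1.0
        assert summary.n_fully_covered == 1 and summary.n_never == 0

    def test_all_below_threshold_never_covered(self):
        d = Design("d", IntervalSet([("chr1", 0, 4)]))
        _, regions = sample_coverage_summary(track_from_dense([4, 4, 4, 4]), d)
        assert regions[0].never_covered(5) and regions[0].covered_bp == 0

    def test_absent_positions_count_as_zero(self):
        d = Design("d", IntervalSet([("chr1", 0, 10)]))
        summary, regions = sample_coverage_summary(DepthTrack({"chr1": [(0, 5, 9)]}), d)
        assert regions[0].min_depth == 0 and regions[0].covered_bp == 5
        assert not regions[0].fully_covered

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_recount(self, seed):
        rng = np.random.default_rng(seed)
        starts = np.sort(rng.choice(np.arange(0, 9900, 60), size=50, replace=False))
        d = Design("d", IntervalSet(
            ("chr1", int(s), int(s + rng.integers(10, 50))) for s in starts
        ))
        dense = rng.integers(0, 11, size=10_000)
        dense[rng.random(10_000) < 0.5] = 0  # sparse
        summary, regions = sample_coverage_summary(track_from_dense(dense), d, threshold=5)
        for rid, iv in d.iter_regions():
            window = dense[iv.start:iv.end]
            r = regions[rid]
            assert r.min_depth == window.min()
            assert r.max_depth == window.max()
            assert r.covered_bp == int((window >= 5).sum())
        total = sum(int(dense[iv.start:iv.end].sum()) for _, iv in d.iter_regions())
        assert summary.covered_bp == sum(r.covered_bp for r in regions)
        assert summary.n_fully_covered + summary.n_min_below == d.n_regions

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(5)
        d = Design("d", IntervalSet([("chr1", 0, 500)]))
        dense = rng.integers(0, 15, size=500)
        prev = None
        for t in (1, 3, 5, 8, 12):
            s, _ = sample_coverage_summary(track_from_dense(dense), d, threshold=t)
            if prev is not None:
                assert s.covered_bp <= prev.covered_bp
                assert s.n_fully_covered <= prev.n_fully_covered
            prev = s


class TestCoverageCurve:
    def test_all_fully_covered(self):
        d = Design("d", IntervalSet([("chr1", 0, 4)]))
        _, regions = sample_coverage_summary(track_from_dense([9, 9, 9, 9]), d)
        assert all(p == 100.0 for _, p in coverage_fraction_curve(regions))

    def test_half_and_full(self):
        d = Design("d", IntervalSet([("chr1", 0, 4), ("chr1", 100, 104)]))
        dense = np.zeros(104, dtype=int)
        dense[0:4] = 9       # fully covered
        dense[100:102] = 9   # 50% covered
        _, regions = sample_coverage_summary(track_from_dense(dense), d)
        curve = dict(coverage_fraction_curve(regions))
        assert curve[50] == 100.0 and curve[100] == 50.0

    @pytest.mark.parametrize("seed", [0, 1])
    def test_non_increasing_and_matches_counting(self, seed):
        rng = np.random.default_rng(seed)
        d = Design("d", IntervalSet(
            ("chr1", int(i * 100), int(i * 100 + 50)) for i in range(40)
        ))
        dense = rng.integers(0, 10, size=4000)
        _, regions = sample_coverage_summary(track_from_dense(dense), d)
        curve = coverage_fraction_curve(regions)
        pcts = [p for _, p in curve]
        assert all(a >= b for a, b in zip(pcts, pcts[1:]))
        for g, p in curve[::10]:
            n = sum(1 for r in regions if r.covered_bp * 100 >= g * r.length)
            assert p == round(100 * n / len(regions), 1)


class TestOnTarget:
    DESIGN = Design("d", IntervalSet([("chr1", 0, 100), ("chr2", 50, 150)]))

    def test_three_of_four(self):
        reads = [
            AlignedRead("chr1", 10, 60),
            AlignedRead("chr1", 90, 140),   # 10 bp overlap
            AlignedRead("chr2", 60, 110),
            AlignedRead("chr2", 300, 350),  # off target
        ]
        rep = pct_reads_on_target(reads, self.DESIGN)
        assert rep.reads_on_target == 3 and rep.total_reads == 4
        assert rep.pct_on_target == 75.0

    def test_abutting_read_is_off_target(self):
        # half-open: a read starting exactly at region end shares no base
        rep = pct_reads_on_target([AlignedRead("chr1", 100, 150)], self.DESIGN)
        assert rep.reads_on_target == 0

    def test_unknown_chromosome_counts_off_target(self):
        rep = pct_reads_on_target([AlignedRead("chrX", 0, 50)], self.DESIGN)
        assert rep.total_reads == 1 and rep.reads_on_target == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_mask_overlap_oracle(self, seed):
        rng = np.random.default_rng(seed)
        from conftest import random_interval_set

        target = random_interval_set(rng, n=40)
        d = Design("d", target)
        mask = mask_of(target)
        starts = rng.integers(0, 9900, size=1000)
        reads = [AlignedRead("chr1", int(s), int(s) + 75) for s in starts]
        rep = pct_reads_on_target(reads, d)
        expected = sum(bool(mask[r.start:r.end].any()) for r in reads)
        assert rep.reads_on_target == expected

    def test_per_chrom_sums_to_overall(self):
        reads = [AlignedRead("chr1", 0, 50), AlignedRead("chr2", 0, 10),
                 AlignedRead("chr2", 60, 70)]
        rep = pct_reads_on_target(reads, self.DESIGN)
        assert sum(t for _, t in rep.per_chrom.values()) == rep.total_reads
        assert sum(o for o, _ in rep.per_chrom.values()) == rep.reads_on_target


class TestReproducibility:
    def test_identical_tracks_reduce_to_single_sample(self):
        d = Design("d", IntervalSet([("chr1", 0, 10), ("chr1", 50, 60)]))
        dense = np.zeros(60, dtype=int)
        dense[0:10] = 8
        t = track_from_dense(dense)
        per = [sample_coverage_summary(t, d, 5, str(i)) for i in range(2)]
        rep = reproducibility(per, d, [t, t])
        assert rep.regions_fully_covered_all == per[0][0].n_fully_covered == 1
        assert rep.regions_never_all == per[0][0].n_never == 1
        assert rep.bp_covered_all == per[0][0].covered_bp

    def test_region_covered_in_only_one_sample_excluded(self):
        d = Design("d", IntervalSet([("chr1", 0, 10)]))
        full = track_from_dense([9] * 10)
        empty = DepthTrack({})
        per = [sample_coverage_summary(full, d, 5, "a"),
               sample_coverage_summary(empty, d, 5, "b")]
        rep = reproducibility(per, d, [full, empty])
        assert rep.regions_fully_covered_all == 0
        assert rep.regions_never_all == 0  # sample a reaches 5x
        assert rep.bp_covered_all == 0 and rep.bp_never_all == 0

    def test_needs_two_samples(self):
        d = Design("d", IntervalSet([("chr1", 0, 10)]))
        t = track_from_dense([9] * 10)
        with pytest.raises(ValueError):
            reproducibility([sample_coverage_summary(t, d)], d, [t])

    @pytest.mark.parametrize("seed", range(5))
    def test_bp_counts_match_and_nor_masks(self, seed):
        rng = np.random.default_rng(seed)
        d = Design("d", IntervalSet(
            ("chr1", int(i * 200), int(i * 200 + 100)) for i in range(20)
        ))
        denses = [rng.integers(0, 10, size=4000) for _ in range(4)]
        tracks = [track_from_dense(x) for x in denses]
        per = [sample_coverage_summary(t, d, 5, str(i)) for i, t in enumerate(tracks)]
        rep = reproducibility(per, d, tracks)
        design_mask = mask_of(d.regions, axis=4000)
        stack = np.stack([x >= 5 for x in denses])
        assert rep.bp_covered_all == int((stack.all(axis=0) & design_mask).sum())
        assert rep.bp_never_all == int(((~stack).all(axis=0) & design_mask).sum())
        assert rep.regions_fully_covered_all <= min(s.n_fully_covered for s, _ in per)
        assert rep.regions_never_all <= min(s.n_never for s, _ in per)


class TestProjection:
    def test_identity_on_same_design(self):
        d = Design("d", IntervalSet([("chr1", 0, 100)]))
        t = track_from_dense(np.full(100, 7))
        assert project_to_subset(t, d) == sample_coverage_summary(t, d)

    def test_subset_of_fully_covered_parent_is_fully_covered(self):
        parent = Design("p", IntervalSet([("chr1", 0, 1000)]))
        sub = Design("s", IntervalSet([("chr1", 100, 200), ("chr1", 600, 700)]))
        t = track_from_dense(np.full(1000, 9))
        s_parent, _ = sample_coverage_summary(t, parent)
        s_sub, _ = project_to_subset(t, sub)
        assert s_parent.n_fully_covered == 1
        assert s_sub.n_fully_covered == 2

    def test_projection_on_synthetic_subset_matches_direct(self, cohort):
        t = cohort.depth_tracks[0]
        direct = sample_coverage_summary(t, cohort.design_cds, 5, "0")
        projected = project_to_subset(t, cohort.design_cds, 5, "0")
        assert direct == projected
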