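"""Per-region and per-sample threshold-coverage statistics.

The working definitions, fixed across the package:

* a base is *covered* when its read depth is >= the threshold (default 5x,
  the usual minimum for variant calling);
* a region is *fully covered* when every one of its bases is covered;
* a region is *never covered* when its maximum depth is below the
  threshold (i.e. no base ever reaches it);
* a read is *on target* when it overlaps at least one design base
  (any-overlap rule, configurable to require full containment);
* bases absent from a depth track have depth 0.

Reproducibility across a cohort intersects these calls: a region (base)
counts as reproducibly covered only when it is fully covered (covered) in
every sample, and reproducibly dead only when never covered (below
threshold) in every sample.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np

from .design import Design
from .io import AlignedRead, DepthTrack
from .utils import pct, round_half_away

DEFAULT_THRESHOLD = 5


@dataclasses.dataclass(frozen=True)
class RegionCoverage:
    """Coverage of one design region at a fixed depth threshold."""

    region_id: int
    length: int
    min_depth: int
    max_depth: int
    covered_bp: int

    @property
    def frac_covered(self) -> float:
        return self.covered_bp / self.length

    @property
    def fully_covered(self) -> bool:
        return self.covered_bp == self.length

    def never_covered(self, threshold: int) -> bool:
        return self.max_depth < threshold


@dataclasses.dataclass(frozen=True)
class SampleCoverageSummary:
    """One sample's design-wide coverage summary.

    ``n_min_below`` counts regions with any base under the threshold, so
    ``n_fully_covered + n_min_below == n_regions`` always holds.
    """

    sample: str
    threshold: int
    n_regions: int
    n_fully_covered: int
    n_min_below: int
    n_never: int
    covered_bp: int
    mean_on_target_depth: float


@dataclasses.dataclass(frozen=True)
class ReproducibilityReport:
    n_samples: int
    regions_fully_covered_all: int
    regions_never_all: int
    bp_covered_all: int
    bp_never_all: int


@dataclasses.dataclass(frozen=True)
class OnTargetReport:
    """Read-enrichment accounting, per chromosome and overall."""

    per_chrom: dict[str, tuple[int, int]]  # chrom -> (on_target, total)
    reads_on_target: int
    total_reads: int

    @property
    def pct_on_target(self) -> float:
        return pct(self.reads_on_target, self.total_reads)

    def chrom_pct(self, chrom: str) -> float:
        on, total = self.per_chrom[chrom]
        return pct(on, total)


def sample_coverage_summary(
    depth: DepthTrack,
    design: Design,
    threshold: int = DEFAULT_THRESHOLD,
    sample: str = "",
) -> tuple[SampleCoverageSummary, list[RegionCoverage]]:
    """Compute per-region and design-wide coverage for one sample.

    Every base of every region is inspected (absent positions count as
    depth 0).  ``mean_on_target_depth`` is the summed depth over all
    design bases divided by the design size, reported at one decimal.
    """
    if design.n_regions == 0:
        raise ValueError("design has no regions")
    regions: list[RegionCoverage] = []
    depth_sum = 0
    for rid, iv in design.iter_regions():
        d = depth.window(iv.chrom, iv.start, iv.end)
        depth_sum += int(d.sum())
        regions.append(
            RegionCoverage(
                region_id=rid,
                length=len(iv),
                min_depth=int(d.min()),
                max_depth=int(d.max()),
                covered_bp=int((d >= threshold).sum()),
            )
        )
    n_full = sum(r.fully_covered for r in regions)
    summary = SampleCoverageSummary(
        sample=sample,
        threshold=threshold,
        n_regions=design.n_regions,
        n_fully_covered=n_full,
        n_min_below=design.n_regions - n_full,
        n_never=sum(r.never_covered(threshold) for r in regions),
        covered_bp=sum(r.covered_bp for r in regions),
        mean_on_target_depth=float(round_half_away(depth_sum / design.total_bp, 1)),
    )
    return summary, regions


def coverage_fraction_curve(
    regions: Sequence[RegionCoverage], grid: Iterable[int] = range(0, 101)
) -> list[tuple[int, float]]:
    """Percentage of regions covered at least g% of their length, for each
    grid value g in 0..100.  Non-increasing in g by construction.

    The comparison is done in integer arithmetic (covered_bp * 100 >=
    g * length) so grid points never suffer float round-off.
    """
    if not regions:
        raise ValueError("no regions given")
    covered = np.array([r.covered_bp for r in regions], dtype=np.int64)
    length = np.array([r.length for r in regions], dtype=np.int64)
    out = []
    for g in grid:
        n = int((covered * 100 >= g * length).sum())
        out.append((int(g), pct(n, len(regions))))
    return out


def pct_reads_on_target(
    reads: Iterable[AlignedRead], design: Design, rule: str = "any"
) -> OnTargetReport:
    """Classify each read as on/off target and tally per chromosome.

    rule="any" (default): a read is on target iff it overlaps >= 1 design
    base.  rule="full": the read must lie entirely within one covered
    stretch of the design.
    """
    if rule not in ("any", "full"):
        raise ValueError(f"unknown overlap rule: {rule!r}")
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for r in reads:
        by_chrom[r.chrom].append((r.start, r.end))
    per_chrom: dict[str, tuple[int, int]] = {}
    total_on = total = 0
    for chrom, pairs in by_chrom.items():
        arr = np.asarray(pairs, dtype=np.int64)
        if rule == "any":
            hits = design.regions.overlap_mask(chrom, arr[:, 0], arr[:, 1])
        else:
            a = design.regions.arrays(chrom)
            if len(a) == 0:
                hits = np.zeros(len(arr), dtype=bool)
            else:
                idx = np.searchsorted(a[:, 0], arr[:, 0], side="right")
                hits = idx > 0
                hits[hits] = a[idx[hits] - 1, 1] >= arr[hits, 1]
        on = int(hits.sum())
        per_chrom[chrom] = (on, len(arr))
        total_on += on
        total += len(arr)
    return OnTargetReport(per_chrom=dict(per_chrom), reads_on_target=total_on, total_reads=total)


def reproducibility(
    per_sample: Sequence[tuple[SampleCoverageSummary, Sequence[RegionCoverage]]],
    design: Design,
    per_base_tracks: Sequence[DepthTrack],
    threshold: int = DEFAULT_THRESHOLD,
) -> ReproducibilityReport:
    """Cohort-level reproducibility of coverage calls.

    Region counts come from the per-region summaries; base-pair counts
    re-scan the raw tracks so that a base is counted consistently covered
    (depth >= threshold in every sample) or consistently dead (depth <
    threshold in every sample) exactly as defined.
    """
    if len(per_sample) < 2:
        raise ValueError("reproducibility needs at least two samples")
    n_regions = design.n_regions
    for summary, regions in per_sample:
        if summary.n_regions != n_regions or len(regions) != n_regions:
            raise ValueError("per-sample summaries do not match the design")
    full_all = never_all = 0
    for rid in range(n_regions):
        covs = [regions[rid] for _, regions in per_sample]
        if all(c.fully_covered for c in covs):
            full_all += 1
        if all(c.never_covered(threshold) for c in covs):
            never_all += 1
    bp_all = bp_never = 0
    for _, iv in design.iter_regions():
        stack = np.stack(
            [t.window(iv.chrom, iv.start, iv.end) for t in per_base_tracks]
        )
        ok = stack >= threshold
        bp_all += int(ok.all(axis=0).sum())
        bp_never += int((~ok).all(axis=0).sum())
    return ReproducibilityReport(
        n_samples=len(per_sample),
        regions_fully_covered_all=full_all,
        regions_never_all=never_all,
        bp_covered_all=bp_all,
        bp_never_all=bp_never,
    )


def project_to_subset(
    depth: DepthTrack,
    subset: Design,
    threshold: int = DEFAULT_THRESHOLD,
    sample: str = "",
) -> tuple[SampleCoverageSummary, list[RegionCoverage]]:
    """Estimate a subset design's coverage from depth obtained under a
    superset capture.

    This is the plain coverage computation evaluated over the subset's
    regions with no depth rescaling — conservative, since a dedicated
    capture of the smaller design would spread the same bait budget over
    fewer bases.
    """
    return sample_coverage_summary(depth, subset, threshold=threshold, sample=sample)
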