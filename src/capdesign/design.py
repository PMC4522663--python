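"""Capture-design construction.

A capture design is a named, merged, non-overlapping set of target regions
with dense integer region ids assigned in (chrom, start) order.  Designs
are built from one or more annotation interval tracks: the sources are
unioned, excluded chromosomes (by default the mitochondrion, which would
otherwise be over-captured relative to nuclear DNA) are dropped, the
result is merged at gap 0, regions shorter than a minimum bait-design
length are padded to that length, and the padded set is re-merged.

Subset designs (e.g. a CDS-only design carved out of a full transcribed-
region design) intersect a parent design with a keep-set and re-apply the
same padding rule; a single parent region split by several kept fragments
yields several subset regions, so a subset can contain *more* regions
than its parent while spanning fewer bases.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

from .intervals import IntervalSet
from .io import GenomicInterval
from .utils import round_half_away

DEFAULT_MIN_REGION_LEN = 100
DEFAULT_EXCLUDE_CHROMS = ("chrM",)


@dataclasses.dataclass
class Design:
    """A named capture design: normalized regions with stable integer ids."""

    name: str
    regions: IntervalSet
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self._index: list[GenomicInterval] = list(self.regions)

    @property
    def n_regions(self) -> int:
        return len(self._index)

    @property
    def total_bp(self) -> int:
        return self.regions.total_length()

    def region(self, region_id: int) -> GenomicInterval:
        """The region with the given dense id (assigned in (chrom, start) order)."""
        return self._index[region_id]

    def iter_regions(self):
        """Yield (region_id, interval) in id order."""
        return enumerate(self._index)

    def __repr__(self) -> str:
        return f"Design({self.name!r}, {self.n_regions} regions, {self.total_bp} bp)"


@dataclasses.dataclass(frozen=True)
class DesignStats:
    """Region count, span and mean region size of a design.

    ``mean_region_bp`` keeps one decimal; summary tables report the
    integer-truncated value (``mean_region_bp_int``), which is how the
    headline per-region sizes are conventionally quoted.
    """

    n_regions: int
    total_bp: int
    mean_region_bp: float

    @property
    def mean_region_bp_int(self) -> int:
        return self.total_bp // self.n_regions


def build_design(
    sources: Sequence[IntervalSet],
    name: str,
    chrom_sizes: Mapping[str, int],
    exclude_chroms: Sequence[str] = DEFAULT_EXCLUDE_CHROMS,
    min_len: int = DEFAULT_MIN_REGION_LEN,
) -> Design:
    """Build a design from annotation sources.

    Pipeline: union sources -> drop excluded chromosomes -> merge(gap=0)
    -> pad regions under ``min_len`` bp -> re-merge -> assign ids.

    Raises ``ValueError`` if no sources are given or nothing remains after
    chromosome exclusion.
    """
    if not sources:
        raise ValueError("at least one source track is required")
    combined = sources[0]
    for src in sources[1:]:
        combined = combined.union(src)
    combined = combined.restrict_chroms(exclude_chroms)
    if combined.total_length() == 0:
        raise ValueError(f"design {name!r} is empty after chromosome exclusion")
    regions = combined.merge(gap=0).pad_to_min_length(min_len, chrom_sizes).merge(gap=0)
    return Design(name=name, regions=regions, provenance=tuple(str(i) for i in range(len(sources))))


def subset_design(
    parent: Design,
    keep: IntervalSet,
    name: str,
    chrom_sizes: Mapping[str, int],
    min_len: int = DEFAULT_MIN_REGION_LEN,
    repad: bool = True,
) -> Design:
    """Carve a subset design out of a parent design.

    Regions are ``parent.regions ∩ keep``; by default fragments shorter
    than ``min_len`` are re-padded exactly as in :func:`build_design`
    (bait design pads whatever it receives), which can push a subset
    slightly outside the parent near region edges.  Set ``repad=False``
    to keep the subset strictly inside the parent.
    """
    regions = parent.regions.intersect(keep)
    if regions.total_length() == 0:
        raise ValueError(f"subset {name!r} has empty intersection with parent")
    if repad:
        regions = regions.pad_to_min_length(min_len, chrom_sizes).merge(gap=0)
    return Design(name=name, regions=regions, provenance=(parent.name,))


def design_stats(d: Design) -> DesignStats:
    if d.n_regions == 0:
        raise ValueError("empty design has no stats")
    mean = float(round_half_away(d.total_bp / d.n_regions, 1))
    return DesignStats(n_regions=d.n_regions, total_bp=d.total_bp, mean_region_bp=mean)
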