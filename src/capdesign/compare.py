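"""N-way design comparison: exhaustive base-pair membership partitions.

Comparing capture designs means asking, for every base in their union,
which designs target it.  For n designs the bases split into 2**n - 1
disjoint membership classes; for three designs these are the familiar
seven Venn fields.  Partition sizes are computed with a boundary sweep
over the combined interval sets, so they are exact in base pairs and are
reported in Mb at two decimals for figure-style summaries.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations
from typing import Sequence

import numpy as np

from .design import Design
from .intervals import IntervalSet
from .utils import round_half_away


def membership_partition(sets: Sequence[IntervalSet]) -> dict[int, int]:
    """Base-pair size of every non-empty membership class.

    Keys are bitmasks: bit i set means "inside set i".  Classes absent
    from the genome simply do not appear; values are exact bp counts.
    Disjoint by construction, and their sum equals the union's size.
    """
    if not sets:
        raise ValueError("at least one interval set is required")
    chroms = sorted({c for s in sets for c in s.chroms})
    sizes: dict[int, int] = {}
    for chrom in chroms:
        bounds = np.unique(
            np.concatenate([s.arrays(chrom).ravel() for s in sets] or [np.empty(0)])
        )
        if len(bounds) < 2:
            continue
        starts, ends = bounds[:-1], bounds[1:]
        mask = np.zeros(len(starts), dtype=np.int64)
        for i, s in enumerate(sets):
            mask |= s.overlap_mask(chrom, starts, ends).astype(np.int64) << i
        seg_len = ends - starts
        for bits in np.unique(mask):
            if bits == 0:
                continue
            sizes[int(bits)] = sizes.get(int(bits), 0) + int(seg_len[mask == bits].sum())
    return sizes


@dataclasses.dataclass(frozen=True)
class VennPartition:
    """Three-design partition: bp per membership class, with Mb views."""

    names: tuple[str, str, str]
    sizes_bp: dict[int, int]  # bitmask (bit i = design i) -> bp

    def bp(self, *members: str) -> int:
        """Exact bp in the class containing exactly the named designs."""
        bits = 0
        for m in members:
            bits |= 1 << self.names.index(m)
        return self.sizes_bp.get(bits, 0)

    def mb(self, *members: str) -> float:
        """Class size in Mb at 2 decimals (bp / 1,000,000)."""
        return float(round_half_away(self.bp(*members) / 1e6, 2))

    def design_total_bp(self, name: str) -> int:
        i = self.names.index(name)
        return sum(v for k, v in self.sizes_bp.items() if k >> i & 1)

    def union_bp(self) -> int:
        return sum(self.sizes_bp.values())

    def as_rows(self) -> list[dict]:
        """TSV-friendly rows: member names, bp, Mb per class."""
        rows = []
        for r in range(1, 4):
            for combo in combinations(range(3), r):
                bits = sum(1 << i for i in combo)
                bp = self.sizes_bp.get(bits, 0)
                rows.append(
                    {
                        "members": "+".join(self.names[i] for i in combo),
                        "bp": bp,
                        "mb": float(round_half_away(bp / 1e6, 2)),
                    }
                )
        return rows


def venn3(a: Design, b: Design, c: Design) -> VennPartition:
    """Partition three designs' bases into the 7 Venn membership classes."""
    sizes = membership_partition([a.regions, b.regions, c.regions])
    return VennPartition(names=(a.name, b.name, c.name), sizes_bp=sizes)
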