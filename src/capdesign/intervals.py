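"""Genomic interval-set algebra.

All coordinates are 0-based half-open (BED convention) throughout the
package; 1-based inputs are converted at the I/O boundary.  An
:class:`IntervalSet` always stores the *union* representation of its
intervals: overlapping and book-ended runs are coalesced at construction,
so the number of intervals and their boundaries are well defined and the
set operations below return maximal intervals.

Chromosome names are matched by exact string comparison — there is no
"chr" aliasing, so mixing naming schemes surfaces as empty intersections
rather than silently half-working.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Mapping

import numpy as np

from .io import GenomicInterval

__all__ = ["IntervalSet", "merge", "intersect", "subtract", "pad_to_min_length"]


def _coalesce(pairs: np.ndarray, gap: int = 0) -> np.ndarray:
    """Union a (n, 2) start/end array: join overlapping runs and runs
    separated by <= gap bases (gap=0 joins book-ended runs)."""
    if len(pairs) == 0:
        return pairs.reshape(0, 2)
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    pairs = pairs[order]
    out = []
    cur_s, cur_e = int(pairs[0, 0]), int(pairs[0, 1])
    for s, e in pairs[1:]:
        s, e = int(s), int(e)
        if s <= cur_e + gap:
            cur_e = max(cur_e, e)
        else:
            out.append((cur_s, cur_e))
            cur_s, cur_e = s, e
    out.append((cur_s, cur_e))
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


class IntervalSet:
    """A set of genomic bases, held as sorted non-overlapping intervals
    grouped per chromosome.

    Parameters
    ----------
    intervals
        Any iterable of :class:`~capdesign.io.GenomicInterval` or
        ``(chrom, start, end)`` tuples.  Labels are dropped: an interval
        set models a set of bases, not a feature track.
    """

    def __init__(self, intervals: Iterable = ()) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            if isinstance(iv, GenomicInterval):
                chrom, start, end = iv.chrom, iv.start, iv.end
            else:
                chrom, start, end = iv[0], int(iv[1]), int(iv[2])
            if end <= start or start < 0 or not chrom:
                raise ValueError(f"invalid interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end))
        self._chroms: dict[str, np.ndarray] = {
            c: _coalesce(np.asarray(p, dtype=np.int64)) for c, p in by_chrom.items()
        }

    @classmethod
    def _from_arrays(cls, chroms: Mapping[str, np.ndarray]) -> "IntervalSet":
        obj = cls.__new__(cls)
        obj._chroms = {c: a for c, a in chroms.items() if len(a)}
        return obj

    # -- introspection -------------------------------------------------

    @property
    def chroms(self) -> list[str]:
        return sorted(self._chroms)

    def arrays(self, chrom: str) -> np.ndarray:
        """(n, 2) start/end array for one chromosome (empty if absent)."""
        return self._chroms.get(chrom, np.empty((0, 2), dtype=np.int64))

    def __len__(self) -> int:
        return sum(len(a) for a in self._chroms.values())

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom in self.chroms:
            for s, e in self._chroms[chrom]:
                yield GenomicInterval(chrom, int(s), int(e))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        if self.chroms != other.chroms:
            return False
        return all(np.array_equal(self._chroms[c], other._chroms[c]) for c in self._chroms)

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals, {self.total_length()} bp, {len(self._chroms)} chroms)"

    def total_length(self) -> int:
        """Total number of bases covered."""
        return int(sum((a[:, 1] - a[:, 0]).sum() for a in self._chroms.values()))

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) shares at least one base with this set."""
        a = self._chroms.get(chrom)
        if a is None:
            return False
        i = int(np.searchsorted(a[:, 0], end))  # first interval starting >= end
        return i > 0 and a[i - 1, 1] > start

    def overlap_mask(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Vectorised any-overlap test for many query intervals on one chromosome."""
        a = self._chroms.get(chrom)
        if a is None or len(a) == 0:
            return np.zeros(len(starts), dtype=bool)
        idx = np.searchsorted(a[:, 0], ends)
        hit = idx > 0
        hit[hit] = a[idx[hit] - 1, 1] > starts[hit]
        return hit

    # -- set algebra ---------------------------------------------------

    def merge(self, gap: int = 0) -> "IntervalSet":
        """Union intervals separated by <= ``gap`` bases.

        With the default gap of 0 this joins overlapping and book-ended
        intervals, matching ``bedtools merge`` defaults.  Idempotent.
        """
        if gap < 0:
            raise ValueError("gap must be non-negative")
        return IntervalSet._from_arrays(
            {c: _coalesce(a, gap=gap) for c, a in self._chroms.items()}
        )

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        """Bases present in both sets."""
        out: dict[str, np.ndarray] = {}
        for chrom in self._chroms:
            b = other._chroms.get(chrom)
            if b is None:
                continue
            a = self._chroms[chrom]
            pieces = []
            i = j = 0
            while i < len(a) and j < len(b):
                s = max(a[i, 0], b[j, 0])
                e = min(a[i, 1], b[j, 1])
                if s < e:
                    pieces.append((s, e))
                if a[i, 1] <= b[j, 1]:
                    i += 1
                else:
                    j += 1
            if pieces:
                out[chrom] = np.asarray(pieces, dtype=np.int64)
        return IntervalSet._from_arrays(out)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        """Bases in this set and not in ``other``."""
        out: dict[str, np.ndarray] = {}
        for chrom, a in self._chroms.items():
            b = other._chroms.get(chrom)
            if b is None or len(b) == 0:
                out[chrom] = a.copy()
                continue
            pieces = []
            j = 0
            for s, e in a:
                s = int(s)
                while j < len(b) and b[j, 1] <= s:
                    j += 1
                k = j
                while k < len(b) and b[k, 0] < e:
                    if b[k, 0] > s:
                        pieces.append((s, int(b[k, 0])))
                    s = max(s, int(b[k, 1]))
                    k += 1
                if s < e:
                    pieces.append((s, int(e)))
            if pieces:
                out[chrom] = np.asarray(pieces, dtype=np.int64)
        return IntervalSet._from_arrays(out)

    def union(self, other: "IntervalSet") -> "IntervalSet":
        out: dict[str, np.ndarray] = {}
        for chrom in set(self._chroms) | set(other._chroms):
            stacked = np.vstack([self.arrays(chrom), other.arrays(chrom)])
            out[chrom] = _coalesce(stacked)
        return IntervalSet._from_arrays(out)

    # -- design-construction helpers -----------------------------------

    def pad_to_min_length(self, min_len: int, chrom_sizes: Mapping[str, int]) -> "IntervalSet":
        """Extend every interval shorter than ``min_len`` to ``min_len`` bases.

        Padding is symmetric about the original midpoint with the odd extra
        base placed downstream (higher coordinate).  Intervals are clipped to
        ``[0, chrom length)``; when clipping at a boundary eats into the
        padding, the interval slides inward so the target length is still
        reached whenever the chromosome allows.  The result is re-unioned
        because padding can make neighbours touch.
        """
        out: dict[str, np.ndarray] = {}
        for chrom, a in self._chroms.items():
            if chrom not in chrom_sizes:
                raise ValueError(f"chromosome {chrom!r} missing from chrom_sizes")
            clen = int(chrom_sizes[chrom])
            pieces = []
            for s, e in a:
                s, e = int(s), int(e)
                length = e - s
                if length < min_len:
                    pad = min_len - length
                    left = pad // 2
                    s -= left
                    e += pad - left
                    if s < 0:  # slide right, keep length
                        e += -s
                        s = 0
                    if e > clen:  # slide left, keep length
                        s -= e - clen
                        e = clen
                    s = max(s, 0)
                pieces.append((s, min(e, clen)))
            out[chrom] = _coalesce(np.asarray(pieces, dtype=np.int64))
        return IntervalSet._from_arrays(out)

    def restrict_chroms(self, drop: Iterable[str]) -> "IntervalSet":
        """Remove all intervals on the given chromosomes."""
        drop = set(drop)
        return IntervalSet._from_arrays(
            {c: a for c, a in self._chroms.items() if c not in drop}
        )


# Functional aliases mirroring the method API -------------------------------

def merge(s: IntervalSet, gap: int = 0) -> IntervalSet:
    return s.merge(gap=gap)


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    return a.intersect(b)


def subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    return a.subtract(b)


def pad_to_min_length(
    s: IntervalSet, min_len: int, chrom_sizes: Mapping[str, int]
) -> IntervalSet:
    return s.pad_to_min_length(min_len, chrom_sizes)


def total_length(s: IntervalSet) -> int:
    return s.total_length()
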