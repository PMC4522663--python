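"""Readers and writers for the formats the pipeline touches.

Coordinate conventions are handled explicitly at this boundary: BED and
bedGraph are 0-based half-open; the plain per-base depth dialect
(``depth_tsv``, the shape ``samtools depth`` emits) is 1-based and is
shifted on input.  Every reader takes an explicit dialect flag — there is
no format sniffing.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np


class ParseError(ValueError):
    """A malformed record, reported with its line number."""


# ---------------------------------------------------------------------------
# domain types


@dataclasses.dataclass(frozen=True)
class GenomicInterval:
    """A labeled half-open genomic interval: bases ``[start, end)``."""

    chrom: str
    start: int
    end: int
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclasses.dataclass(frozen=True)
class AlignedRead:
    """The footprint of one mapped read on the reference."""

    chrom: str
    start: int
    end: int
    sample: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("read end must exceed start")


class DepthTrack:
    """Per-base read depth for one sample, stored as run-length intervals.

    Positions absent from the track have depth 0; zero-depth runs are never
    stored explicitly.  Runs are half-open ``[start, end)`` with a constant
    non-negative depth, non-overlapping and sorted within a chromosome.
    """

    def __init__(self, runs: Mapping[str, Iterable[tuple[int, int, int]]] = ()):
        self._runs: dict[str, np.ndarray] = {}
        runs = dict(runs)
        for chrom, triples in runs.items():
            if isinstance(triples, np.ndarray):
                arr = triples.astype(np.int64).reshape(-1, 3)
            else:
                arr = np.asarray(list(triples), dtype=np.int64).reshape(-1, 3)
            if (arr[:, 2] < 0).any():
                raise ValueError(f"negative depth on {chrom}")
            arr = arr[arr[:, 2] > 0]
            if len(arr) == 0:
                continue
            arr = arr[np.argsort(arr[:, 0], kind="stable")]
            if (arr[:-1, 1] > arr[1:, 0]).any():
                raise ValueError(f"overlapping depth runs on {chrom}")
            self._runs[chrom] = self._merge_equal(arr)

    @staticmethod
    def _merge_equal(arr: np.ndarray) -> np.ndarray:
        """Coalesce adjacent runs of equal depth into one canonical run."""
        if len(arr) == 1:
            return arr
        new_run = np.empty(len(arr), dtype=bool)
        new_run[0] = True
        new_run[1:] = (arr[1:, 0] != arr[:-1, 1]) | (arr[1:, 2] != arr[:-1, 2])
        firsts = np.flatnonzero(new_run)
        lasts = np.concatenate([firsts[1:] - 1, [len(arr) - 1]])
        return np.column_stack([arr[firsts, 0], arr[lasts, 1], arr[firsts, 2]])

    @property
    def chroms(self) -> list[str]:
        return sorted(self._runs)

    def runs(self, chrom: str) -> np.ndarray:
        """(n, 3) array of (start, end, depth) runs for one chromosome."""
        return self._runs.get(chrom, np.empty((0, 3), dtype=np.int64))

    def window(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Dense per-base depths over ``[start, end)``; absent bases are 0."""
        out = np.zeros(end - start, dtype=np.int64)
        arr = self._runs.get(chrom)
        if arr is None:
            return out
        lo = int(np.searchsorted(arr[:, 1], start, side="right"))
        hi = int(np.searchsorted(arr[:, 0], end, side="left"))
        sub = arr[lo:hi]
        if len(sub) == 0:
            return out
        s = np.clip(sub[:, 0] - start, 0, None)
        e = np.clip(sub[:, 1] - start, None, end - start)
        lens = e - s
        # scatter each run's value into its slice without a Python loop
        idx = np.repeat(s, lens) + np.arange(lens.sum()) - np.repeat(
            np.cumsum(lens) - lens, lens
        )
        out[idx] = np.repeat(sub[:, 2], lens)
        return out

    def depth_at(self, chrom: str, pos: int) -> int:
        return int(self.window(chrom, pos, pos + 1)[0])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DepthTrack):
            return NotImplemented
        if self.chroms != other.chroms:
            return False
        return all(np.array_equal(self._runs[c], other._runs[c]) for c in self._runs)

    def __repr__(self) -> str:
        nb = sum(int((a[:, 1] - a[:, 0]).sum()) for a in self._runs.values())
        return f"DepthTrack({len(self._runs)} chroms, {nb} non-zero bases)"


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED file (>=3 tab-separated columns) into intervals.

    Coordinates are taken as 0-based half-open per the BED standard; the
    4th column, when present, becomes the interval label.  Intervals are
    returned in file order.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >=3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinate") from exc
            label = fields[3] if len(fields) > 3 else None
            try:
                out.append(GenomicInterval(fields[0], start, end, label))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.label is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")


# ---------------------------------------------------------------------------
# depth tracks


def read_depth_track(path: str | Path, dialect: str) -> DepthTrack:
    """Read a per-base depth track.

    dialect="bedgraph"
        4 columns (chrom, start, end, depth), 0-based half-open.
    dialect="depth_tsv"
        3 columns (chrom, 1-based position, depth), the ``samtools depth``
        shape; converted to 0-based on input.

    Both dialects produce identical tracks for equivalent content.
    """
    if dialect not in ("bedgraph", "depth_tsv"):
        raise ValueError(f"unknown depth dialect: {dialect!r}")
    runs: dict[str, list[tuple[int, int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            try:
                if dialect == "bedgraph":
                    chrom, start, end, depth = (
                        fields[0], int(fields[1]), int(fields[2]), int(float(fields[3])),
                    )
                else:
                    chrom, pos, depth = fields[0], int(fields[1]), int(fields[2])
                    start, end = pos - 1, pos
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}: line {lineno}: malformed {dialect} record") from exc
            if depth < 0:
                raise ValueError(f"{path}: line {lineno}: negative depth {depth}")
            if start < 0:
                raise ParseError(f"{path}: line {lineno}: negative position")
            runs.setdefault(chrom, []).append((start, end, depth))
    return DepthTrack(runs)


def write_bedgraph(track: DepthTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            for s, e, v in track.runs(chrom):
                fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")


# ---------------------------------------------------------------------------
# alignments


def read_alignments(
    path: str | Path, format: str, sample: str = ""
) -> tuple[list[AlignedRead], int]:
    """Read mapped-read footprints.

    format="bam"
        Any SAM/BAM readable by pysam; unmapped records are skipped and
        counted.
    format="interval_tsv"
        Plain 0-based half-open (chrom, start, end) rows.

    Returns (reads, n_unmapped_skipped).
    """
    reads: list[AlignedRead] = []
    skipped = 0
    if format == "interval_tsv":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                try:
                    reads.append(
                        AlignedRead(fields[0], int(fields[1]), int(fields[2]), sample)
                    )
                except (IndexError, ValueError) as exc:
                    raise ParseError(f"{path}: line {lineno}: malformed read record") from exc
    elif format == "bam":
        import pysam

        with pysam.AlignmentFile(str(path), check_sq=False) as af:
            for rec in af.fetch(until_eof=True):
                if rec.is_unmapped or rec.reference_start is None:
                    skipped += 1
                    continue
                end = rec.reference_end
                if end is None:  # no CIGAR: fall back to query length
                    end = rec.reference_start + max(rec.query_length, 1)
                reads.append(AlignedRead(rec.reference_name, rec.reference_start, end, sample))
    else:
        raise ValueError(f"unknown alignment format: {format!r}")
    return reads, skipped


# ---------------------------------------------------------------------------
# chromosome sizes and FASTA


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a 2-column (name, length) TSV as emitted by ``samtools faidx``."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            try:
                sizes[fields[0]] = int(fields[1])
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}: line {lineno}: malformed sizes record") from exc
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sizes):
            fh.write(f"{name}\t{sizes[name]}\n")


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    """Write sequences as FASTA with fixed line wrapping (deterministic bytes)."""
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")
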