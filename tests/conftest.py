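"""Shared fixtures: random interval machinery, per-base mask oracles and
one session-scoped synthetic cohort reused by the slower end-to-end tests."""

from __future__ import annotations

import numpy as np
import pytest

from capdesign.intervals import IntervalSet
from capdesign.simulate import SimConfig, simulate_cohort

AXIS = 10_000  # length of the toy chromosome used by mask oracles


def random_interval_set(rng: np.random.Generator, n: int = 100, chrom: str = "chr1",
                        axis: int = AXIS, max_len: int = 200) -> IntervalSet:
    starts = rng.integers(0, axis - 1, size=n)
    lens = rng.integers(1, max_len, size=n)
    ends = np.minimum(starts + lens, axis)
    return IntervalSet((chrom, int(s), int(e)) for s, e in zip(starts, ends))


def mask_of(iset: IntervalSet, chrom: str = "chr1", axis: int = AXIS) -> np.ndarray:
    m = np.zeros(axis, dtype=bool)
    for s, e in iset.arrays(chrom):
        m[s:e] = True
    return m


def set_of_mask(mask: np.ndarray, chrom: str = "chr1") -> IntervalSet:
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return IntervalSet(
        (chrom, int(s), int(e)) for s, e in zip(edges[::2], edges[1::2])
    )


@pytest.fixture(scope="session")
def cohort():
    """Default-condition synthetic experiment shared across test modules."""
    return simulate_cohort(SimConfig(seed=1))


@pytest.fixture(scope="session")
def cohort_coverage(cohort):
    from capdesign.coverage import sample_coverage_summary

    return [
        sample_coverage_summary(t, cohort.design_plus, 5, str(i))
        for i, t in enumerate(cohort.depth_tracks)
    ]
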