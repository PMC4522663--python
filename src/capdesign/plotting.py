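"""Minimal plot helpers for coverage QC reports."""

from __future__ import annotations

from typing import Sequence

from .coverage import RegionCoverage, coverage_fraction_curve


def plot_coverage_curve(regions: Sequence[RegionCoverage], ax=None, **line_kw):
    """Plot the share of regions reaching each minimum covered fraction.

    The x axis is the minimal percentage of a region covered at the depth
    threshold; the y axis is the percentage of regions meeting it.  The
    curve is non-increasing; its right end is the fully-covered rate.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    curve = coverage_fraction_curve(regions)
    ax.plot([g for g, _ in curve], [p for _, p in curve], **line_kw)
    ax.set_xlabel("minimal percentage of region covered (%)")
    ax.set_ylabel("regions (%)")
    ax.set_xlim(0, 100)
    ax.set_ylim(0, 100)
    return ax


def plot_group_gc_boxes(gc_by_group: dict[int, Sequence[float]], cutoffs=None, ax=None):
    """Box plots of per-region %GC for the three performance groups, with
    optional vertical band markers at the sequenceable-GC cutoffs."""
    import matplotlib.pyplot as plt
    import numpy as np

    if ax is None:
        _, ax = plt.subplots()
    keys = sorted(gc_by_group)
    data = [np.asarray(gc_by_group[k], dtype=float) for k in keys]
    data = [d[~np.isnan(d)] for d in data]
    ax.boxplot(data, tick_labels=[f"group {k}" for k in keys], vert=False)
    if cutoffs is not None:
        for c in cutoffs:
            ax.axvline(c, linestyle="--", linewidth=1)
    ax.set_xlabel("%GC")
    return ax
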