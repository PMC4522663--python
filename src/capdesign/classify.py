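"""Three-group region classification and GC / bait-exclusion risk analysis.

Capture designs show a characteristic trichotomy across a cohort:

* **group 1** — regions fully covered at the depth threshold in every
  sample (the reliable core of the design);
* **group 3** — regions whose maximum depth stays below the threshold in
  every sample (capture dead zones);
* **group 2** — everything else: regions whose coverage varies by sample
  or that are only partially covered.

Two mechanisms explain most of groups 2 and 3: extreme GC content (both
GC-rich and GC-poor fragments amplify and hybridise poorly) and bait
exclusion (no baits designed over repeats or runs of Ns, or baits the
vendor predicted would not sequence).  Group 1 serves as the empirical
reference for a "sequenceable" GC range: its 2.5th/97.5th GC percentiles
become the cutoffs, and a region outside them counts as extreme.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import DEFAULT_THRESHOLD, RegionCoverage
from .design import Design
from .intervals import IntervalSet
from .io import GenomicInterval
from .utils import pct, round_half_away

GROUP_FULL, GROUP_VARIABLE, GROUP_NEVER = 1, 2, 3


def assign_groups(
    per_sample_regions: Sequence[Sequence[RegionCoverage]],
    threshold: int = DEFAULT_THRESHOLD,
) -> np.ndarray:
    """Partition regions into performance groups 1/2/3 across a cohort.

    Returns an int array indexed by region id.  Groups are disjoint and
    exhaustive by construction: group 1 requires full coverage in *all*
    samples, group 3 requires max depth < threshold in *all* samples, and
    group 2 is the remainder.
    """
    if not per_sample_regions:
        raise ValueError("at least one sample is required")
    n = len(per_sample_regions[0])
    for regions in per_sample_regions:
        if len(regions) != n or any(r.region_id != i for i, r in enumerate(regions)):
            raise ValueError("samples do not share a region universe")
    groups = np.full(n, GROUP_VARIABLE, dtype=np.int8)
    for rid in range(n):
        covs = [regions[rid] for regions in per_sample_regions]
        if all(c.fully_covered for c in covs):
            groups[rid] = GROUP_FULL
        elif all(c.never_covered(threshold) for c in covs):
            groups[rid] = GROUP_NEVER
    return groups


def gc_content(genome, region: GenomicInterval) -> float:
    """%GC of a region, case-insensitive, over unambiguous bases only.

    ``genome`` is anything sliceable as ``genome[chrom][start:end]`` (a
    ``pyfaidx.Fasta`` or a plain dict of strings).  Returns NaN for a
    region with no A/C/G/T at all (e.g. all Ns).
    """
    seq = str(genome[region.chrom][region.start : region.end]).upper()
    if len(seq) < len(region):
        raise ValueError(f"region {region.chrom}:{region.start}-{region.end} out of bounds")
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        return float("nan")
    return 100.0 * gc / (gc + at)


def gc_cutoffs(
    group1_gc: Sequence[float], lo_pct: float = 2.5, hi_pct: float = 97.5
) -> tuple[float, float]:
    """GC cutoffs for a "sequenceable" region, taken as percentiles of the
    reliably covered group's GC distribution.

    Percentiles use linear interpolation between order statistics (the
    numpy default, R type 7).  NaNs are dropped.
    """
    vals = np.asarray(group1_gc, dtype=float)
    vals = vals[~np.isnan(vals)]
    if len(vals) < 2:
        raise ValueError("need at least two finite GC values")
    lo, hi = np.percentile(vals, [lo_pct, hi_pct], method="linear")
    return float(lo), float(hi)


def annotate_exclusions(
    design: Design,
    ns: IntervalSet,
    repeats: IntervalSet,
    predicted_unseq: IntervalSet,
) -> pd.DataFrame:
    """Flag each region that at-least-partially (>=1 bp) overlaps each
    vendor exclusion track.

    Columns: region_id, ns, repeats, any_exclusion (ns OR repeats),
    predicted_unsequenced.
    """
    rows = []
    for rid, iv in design.iter_regions():
        f_ns = ns.overlaps(iv.chrom, iv.start, iv.end)
        f_rep = repeats.overlaps(iv.chrom, iv.start, iv.end)
        rows.append(
            {
                "region_id": rid,
                "ns": f_ns,
                "repeats": f_rep,
                "any_exclusion": f_ns or f_rep,
                "predicted_unsequenced": predicted_unseq.overlaps(iv.chrom, iv.start, iv.end),
            }
        )
    return pd.DataFrame(rows).set_index("region_id")


@dataclasses.dataclass(frozen=True)
class GroupRisk:
    """Risk annotations for one performance group (percentages, 1 decimal)."""

    n_regions: int
    median_gc: float
    pct_extreme_gc: float
    pct_ns: float
    pct_repeats: float
    pct_any_exclusion: float
    pct_predicted_unsequenced: float
    # combined at-risk criteria
    pct_at_risk_gc_or_exclusion: float
    pct_at_risk_gc_or_predicted: float
    # the same GC summaries after dropping flagged regions
    median_gc_excl_predicted: float
    pct_extreme_excl_predicted: float
    median_gc_excl_any: float
    pct_extreme_excl_any: float


@dataclasses.dataclass(frozen=True)
class GCRiskReport:
    cutoffs: tuple[float, float]
    groups: dict[int, GroupRisk]


def _median(vals: np.ndarray) -> float:
    vals = vals[~np.isnan(vals)]
    return float(round_half_away(float(np.median(vals)), 1)) if len(vals) else float("nan")


def risk_report(
    groups: np.ndarray,
    gc: Sequence[float],
    cutoffs: tuple[float, float],
    flags: pd.DataFrame,
) -> GCRiskReport:
    """Per-group GC and bait-exclusion risk summary.

    "Extreme" GC is strict: gc < lo or gc > hi — the cutoffs themselves,
    being derived from sequenced regions, count as sequenceable.  The two
    combined at-risk criteria are (extreme GC OR Ns/repeat exclusion) and
    (extreme GC OR predicted-unsequenced).
    """
    lo, hi = cutoffs
    if not lo < hi:
        raise ValueError("cutoffs must satisfy lo < hi")
    gc = np.asarray(gc, dtype=float)
    if not (len(gc) == len(groups) == len(flags)):
        raise ValueError("groups, gc and flags must align on region ids")
    extreme = (gc < lo) | (gc > hi)
    out: dict[int, GroupRisk] = {}
    for g in (GROUP_FULL, GROUP_VARIABLE, GROUP_NEVER):
        sel = groups == g
        n = int(sel.sum())
        if n == 0:
            continue
        f = flags.loc[np.flatnonzero(sel)]
        ext = extreme[sel]
        keep_pred = sel & ~flags["predicted_unsequenced"].to_numpy()
        keep_any = sel & ~flags["any_exclusion"].to_numpy()
        out[g] = GroupRisk(
            n_regions=n,
            median_gc=_median(gc[sel]),
            pct_extreme_gc=pct(int(ext.sum()), n),
            pct_ns=pct(int(f["ns"].sum()), n),
            pct_repeats=pct(int(f["repeats"].sum()), n),
            pct_any_exclusion=pct(int(f["any_exclusion"].sum()), n),
            pct_predicted_unsequenced=pct(int(f["predicted_unsequenced"].sum()), n),
            pct_at_risk_gc_or_exclusion=pct(int((ext | f["any_exclusion"].to_numpy()).sum()), n),
            pct_at_risk_gc_or_predicted=pct(
                int((ext | f["predicted_unsequenced"].to_numpy()).sum()), n
            ),
            median_gc_excl_predicted=_median(gc[keep_pred]),
            pct_extreme_excl_predicted=pct(int(extreme[keep_pred].sum()), int(keep_pred.sum())),
            median_gc_excl_any=_median(gc[keep_any]),
            pct_extreme_excl_any=pct(int(extreme[keep_any].sum()), int(keep_any.sum())),
        )
    return GCRiskReport(cutoffs=(float(lo), float(hi)), groups=out)


def size_stratified_completeness(
    design: Design,
    per_sample_regions: Sequence[Sequence[RegionCoverage]],
    size_cutoff: int = 260,
) -> pd.DataFrame:
    """Full-coverage rates for short (< cutoff) vs long (>= cutoff) regions.

    Returns one row per sample with columns pct_full_short, pct_full_long
    and diff_points (short minus long, in percentage points), plus a
    final "mean" row.  Shorter regions are completely covered more often
    simply because a single under-threshold base disqualifies a region.
    """
    if not per_sample_regions:
        raise ValueError("at least one sample is required")
    lengths = np.array([len(iv) for _, iv in design.iter_regions()])
    short = lengths < size_cutoff
    rows = []
    for i, regions in enumerate(per_sample_regions):
        full = np.array([r.fully_covered for r in regions])
        p_short = pct(int(full[short].sum()), int(short.sum()))
        p_long = pct(int(full[~short].sum()), int((~short).sum()))
        rows.append({"sample": str(i), "pct_full_short": p_short, "pct_full_long": p_long,
                     "diff_points": round_half_away(p_short - p_long, 1)})
    mean_diff = round_half_away(float(np.mean([r["diff_points"] for r in rows])), 1)
    rows.append({
        "sample": "mean",
        "pct_full_short": round_half_away(float(np.mean([r["pct_full_short"] for r in rows])), 1),
        "pct_full_long": round_half_away(float(np.mean([r["pct_full_long"] for r in rows])), 1),
        "diff_points": mean_diff,
    })
    return pd.DataFrame(rows).set_index("sample")


def boxplot_summary(values: Sequence[float]) -> dict[str, float]:
    """Five-number box summary with Tukey whiskers (1.5 x IQR) and an
    outlier count, for box-plot style reporting of per-group GC."""
    vals = np.asarray(values, dtype=float)
    vals = vals[~np.isnan(vals)]
    q1, q2, q3 = np.percentile(vals, [25, 50, 75], method="linear")
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
    return {
        "q1": float(q1),
        "median": float(q2),
        "q3": float(q3),
        "whisker_lo": float(inside.min()),
        "whisker_hi": float(inside.max()),
        "n_outliers": int(((vals < lo_fence) | (vals > hi_fence)).sum()),
    }
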