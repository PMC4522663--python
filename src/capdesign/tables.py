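"""Cohort summary tables.

Aggregates per-sample sequencing/coverage/variant statistics into the
headline averages a capture-validation study reports: reads generated,
reads retained after mapping and duplicate removal, on-target depth,
fully-covered regions, covered base pairs and variant counts.  The
per-sample tables of the validation cohort (16 Labrador Retriever
samples, four pre-capture pools of four) ship as TSV fixtures under
``capdesign/data``; every average is recomputed from them — never quoted.

All printed-precision rounding is half away from zero.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .utils import pct, round_half_away


@dataclasses.dataclass(frozen=True)
class SampleStats:
    """One sample's row across the per-sample statistics tables."""

    sample: str
    pool: str
    total_reads: int
    mapped_reads: int
    duplicate_reads: int
    remaining_reads: int
    remaining_pct: float
    depth_x: float
    n_regions_min_below: int
    n_regions_never: int
    bp_covered_plus: int
    bp_covered_cds: int
    variants_plus: int
    variants_cds: int


@dataclasses.dataclass(frozen=True)
class SummaryRow:
    metric: str
    value: float
    unit: str = ""


def _data_path(name: str):
    return resources.files("capdesign").joinpath("data", name)


def load_table(name: str) -> pd.DataFrame:
    """Load one of the packaged per-sample tables (``table1`` .. ``table4``)."""
    with resources.as_file(_data_path(f"{name}.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"sample": str, "pool": str})


def load_published_constants() -> dict:
    """Published design sizes, reproducibility counts and Venn classes."""
    with resources.as_file(_data_path("published_constants.yaml")) as p:
        with open(p) as fh:
            return yaml.safe_load(fh)


def load_sample_stats() -> list[SampleStats]:
    """Join the four packaged per-sample tables into SampleStats rows."""
    t1, t2 = load_table("table1"), load_table("table2")
    t3, t4 = load_table("table3"), load_table("table4")
    merged = t1.merge(t2, on=["sample", "pool"]).merge(t3, on=["sample", "pool"]).merge(
        t4, on=["sample", "pool"]
    )
    return [
        SampleStats(
            sample=r.sample,
            pool=r.pool,
            total_reads=int(r.total_reads),
            mapped_reads=int(r.mapped_reads),
            duplicate_reads=int(r.duplicate_reads),
            remaining_reads=int(r.remaining_reads),
            remaining_pct=float(r.remaining_pct),
            depth_x=float(r.depth_x),
            n_regions_min_below=int(r.n_regions_min_below),
            n_regions_never=int(r.n_regions_never),
            bp_covered_plus=int(r.bp_covered_plus),
            bp_covered_cds=int(r.bp_covered_cds),
            variants_plus=int(r.variants_plus),
            variants_cds=int(r.variants_cds),
        )
        for r in merged.itertuples()
    ]


def validate_sample_stats(rows: Sequence[SampleStats]) -> pd.DataFrame:
    """Check each row's internal arithmetic at printed precision.

    Two identities must hold: remaining = mapped - duplicates (exact), and
    remaining% = 100 x remaining / total rounded to one decimal.
    """
    recs = []
    for r in rows:
        recs.append(
            {
                "sample": r.sample,
                "remaining_ok": r.remaining_reads == r.mapped_reads - r.duplicate_reads,
                "remaining_pct_ok": pct(r.remaining_reads, r.total_reads) == r.remaining_pct,
            }
        )
    df = pd.DataFrame(recs).set_index("sample")
    df["ok"] = df.all(axis=1)
    return df


def average_metrics(
    rows: Sequence[SampleStats], design_sizes: Mapping[str, int]
) -> list[SummaryRow]:
    """Cohort averages recomputed from per-sample rows.

    ``design_sizes`` needs plus_bp, plus_regions, cds_bp (cds_regions is
    accepted for symmetry).  Headline read counts round to the nearest
    million, percentages to one decimal, region and variant means to the
    nearest integer — all half away from zero.
    """
    if not rows:
        raise ValueError("no sample rows given")
    n = len(rows)
    mean = lambda f: sum(f(r) for r in rows) / n  # noqa: E731

    plus_regions = design_sizes["plus_regions"]
    mean_min_below = mean(lambda r: r.n_regions_min_below)
    mean_full = plus_regions - mean_min_below
    out = [
        SummaryRow("mean_reads_millions", round_half_away(mean(lambda r: r.total_reads) / 1e6), "M reads"),
        SummaryRow("mean_remaining_pct", round_half_away(100 * mean(lambda r: r.remaining_reads / r.total_reads), 1), "%"),
        SummaryRow("mean_depth_x", round_half_away(mean(lambda r: r.depth_x), 1), "x"),
        SummaryRow("mean_fully_covered_regions", round_half_away(mean_full), "regions"),
        SummaryRow("pct_fully_covered_regions", pct(mean_full, plus_regions), "%"),
        SummaryRow("mean_never_covered_regions", round_half_away(mean(lambda r: r.n_regions_never)), "regions"),
        SummaryRow("pct_never_covered_regions", pct(mean(lambda r: r.n_regions_never), plus_regions), "%"),
        SummaryRow("pct_bp_covered_plus", pct(mean(lambda r: r.bp_covered_plus), design_sizes["plus_bp"]), "%"),
        SummaryRow("pct_bp_covered_cds", pct(mean(lambda r: r.bp_covered_cds), design_sizes["cds_bp"]), "%"),
        SummaryRow("mean_variants_plus", round_half_away(mean(lambda r: r.variants_plus)), "variants"),
        SummaryRow("mean_variants_cds", round_half_away(mean(lambda r: r.variants_cds)), "variants"),
    ]
    return out


def metrics_dict(summary: Sequence[SummaryRow]) -> dict[str, float]:
    return {row.metric: row.value for row in summary}


def reproducibility_percentages(
    counts: Mapping[str, int], design_sizes: Mapping[str, int]
) -> dict[str, float]:
    """Turn cohort-consistent counts into percentages of the design.

    ``counts`` holds regions_all / regions_never (vs plus_regions) and
    bp_all / bp_never (vs plus_bp); each percentage is one decimal.
    """
    pairs = {
        "regions_all": "plus_regions",
        "regions_never": "plus_regions",
        "bp_all": "plus_bp",
        "bp_never": "plus_bp",
    }
    out = {}
    for key, size_key in pairs.items():
        if key not in counts:
            continue
        if counts[key] > design_sizes[size_key]:
            raise ValueError(f"{key} exceeds {size_key}")
        out[f"pct_{key}"] = pct(counts[key], design_sizes[size_key])
    return out
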