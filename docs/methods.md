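# Methods

## Coordinates and interval algebra

Every internal coordinate is 0-based half-open (the BED convention).
The 1-based `depth_tsv` dialect (the `samtools depth` shape) is shifted
at the I/O boundary; nothing downstream ever sees 1-based positions.
Chromosome names match by exact string — no "chr" aliasing — so mixed
naming surfaces as empty intersections instead of silently half-working.

An `IntervalSet` always stores the union representation: overlapping and
book-ended runs are coalesced at construction. This makes region counts
well defined and matches the construction flow (merge, pad, re-merge);
`merge(gap=g)` additionally joins runs separated by ≤ g bases, matching
`bedtools merge` semantics at `-d g`. The algebra is implemented as
two-pointer sweeps over sorted per-chromosome arrays; the test-suite
cross-checks every operation against per-base boolean-mask brute force
and against `bedtools` itself on random fixtures.

## Design construction

`build_design`: union sources → drop excluded chromosomes (default
`chrM`, because an un-excluded mitochondrion is massively over-captured
relative to nuclear DNA) → merge(gap 0) → pad regions under `min_len`
(default 100 bp, the bait-design minimum) → re-merge → assign dense
integer region ids in (chrom, start) order.

Padding is symmetric about the original midpoint with the odd extra base
placed downstream; at a chromosome boundary the interval slides inward
so the target length is still reached when space allows. The vendor's
actual placement rule is not public; this one is deterministic,
documented and testable, which is what matters for reproducibility.
Padding is applied after merging (the order used when the construction
is driven from merged author-side tracks); subset designs re-apply the
padding rule by default, since bait design pads whatever it receives —
a flag (`repad=False`) keeps a subset strictly inside its parent.

Mean region size is kept at one decimal internally and reported
integer-truncated in summaries, matching how per-region sizes are
conventionally quoted (e.g. 151,698,592 bp / 242,914 regions → 624.5 →
"624 bp").

## Coverage semantics

All depth comparisons are inclusive: a base is covered when depth ≥ t
("at least 5x"), a region is never-covered when its maximum depth is
< t. Bases absent from a track have depth 0 and participate fully. The
per-sample summary stores `n_min_below` (any base under threshold), so
`n_fully_covered + n_min_below == n_regions` holds by construction.

`mean_on_target_depth` is defined as the summed depth over all design
bases divided by the design size (one decimal). Published per-sample
depth columns may use a different, unstated formula; they are therefore
treated as opaque inputs in the summary tables, never recomputed.

A read is on target iff it overlaps at least one design base
(any-overlap, the common convention; a full-containment rule is
available via `rule="full"`). Each mate of a pair counts as one read.
Percentages are rounded half away from zero to one decimal everywhere a
printed-table convention applies — Python's default banker's rounding
would disagree with printed tables on exact ties.

Reproducibility intersects calls across samples: a region counts only if
fully covered in *every* sample (or never covered in every sample), a
base only if ≥ t in every sample (or < t in every sample). Region counts
come from the per-region summaries; base counts re-scan the raw tracks.

Subset projection (`project_to_subset`) evaluates the identical
computation over the subset's regions with no depth rescaling. When the
depth was generated under a superset capture this is conservative: a
dedicated capture of the smaller design would spread the same bait
budget over fewer bases.

## Three-group classification and risk criteria

Group 1 = fully covered in all samples; group 3 = never covered in all
samples; group 2 = remainder. The partition is exhaustive and disjoint
by construction.

%GC is computed case-insensitively over unambiguous bases only
(all-N regions are NaN and excluded from percentiles). The sequenceable
band is the 2.5th/97.5th percentile of group 1's per-region %GC, using
linear interpolation between order statistics (numpy default, R type 7 —
no method is canonical, so the choice is documented and configurable).
"Extreme" is strict (< lo or > hi): the cutoffs derive from sequenced
regions, so boundary values count as sequenceable. Exclusion-track flags
use any-overlap (≥ 1 bp). Group medians are unweighted by region length.
The report also recomputes medians and extreme fractions after dropping
predicted-unsequenced regions and after dropping all Ns/repeat-flagged
regions, which shows whether the surviving regions of a group shift
toward worse GC.

## Summary tables

The 16-sample validation cohort's per-sample tables ship as TSV fixtures;
`average_metrics` recomputes every cohort average from them (reads to
the nearest million, percentages to one decimal, region/variant means to
the nearest integer, all half away from zero). `validate_sample_stats`
checks each row's internal arithmetic (remaining = mapped − duplicates;
remaining% recomputed at printed precision). The grand "% on target"
average is not recomputed: it depends on per-chromosome supplementary
data whose weighting (chromosome- vs read-weighted) is not recoverable,
so it is treated as an opaque published value.

## Design comparison

Membership partitioning is a boundary sweep: all interval boundaries on
a chromosome cut it into elementary segments, each segment's membership
bitmask is evaluated per design, and segment lengths accumulate per
class. This generalizes to any n; the 3-way `venn3` reporter is a view.
Conservation (classes are disjoint, sum to the union, and each design's
total equals the sum of classes containing it) is asserted on random
fixtures.

## Synthetic-data generator

The generator emulates the features of real capture data that the
analysis exercises, at a scale that keeps a full run in seconds:

* **Genome**: 3 chromosomes × 1 Mb tiled into 50 kb GC zones, plus a
  16 kb mitochondrion carrying decoy regions (exercising chromosome
  exclusion). 20% of zones are extreme (22% / 78% GC, alternating);
  the rest get targets evenly spaced across 33–63.5% GC and shuffled.
  Even spacing (rather than uniform draws) makes the group-1 GC
  percentiles stable estimates of the band edges under any seed.
* **Annotation**: ~2,000 exons (150–1,200 bp) with a central 60% CDS;
  UTR is exons − CDS by construction; 60 short ncRNAs. Exclusion
  blocks (30 repeats, 8 N-runs, with predicted-unsequenced as the inner
  half of every other block — a subset of Ns ∪ repeats, as vendor
  prediction tracks are) carry planted exons so exclusion-driven
  dropout exists independent of GC.
* **Depth**: expected depth = 80x baseline × per-sample scale
  (1.0/0.85/1.1/0.95) × GC multiplier × exclusion multiplier. The GC
  multiplier is 1 inside [32, 64.5]%, decaying linearly to 0.02 over 6
  points; window GC uses a 100 bp centered window with N bases dropped
  from both numerator and denominator. Realised depth is negative
  binomial (dispersion 10) — overdispersed counts, the standard model
  for sequencing depth. Depth exists only over design bases: the track
  is the capture's contract.
* **Reads**: the on-target count is Binomial(n, 0.75); on-target reads
  cover a uniformly chosen design base, off-target reads start uniformly
  in the complement of the design expanded by read_len−1, guaranteeing
  zero overlap. The measured on-target fraction is therefore an
  unbiased binomial estimate of the rate (SE ≈ 0.14 points at n = 10⁵).

Everything derives from `numpy.random.SeedSequence((seed, stream, ...))`
so each artifact is byte-identical under a fixed seed and independent
across streams.

What the generator does **not** emulate: bait tiling and hybridization
kinetics, fragment-length structure, mappability, duplicate reads, and
base-level errors. Passing tests therefore demonstrate the correctness
of the interval arithmetic, the coverage/classification statistics and
the qualitative GC/exclusion phenomenology — not quantitative agreement
with any real capture. The published cohort's group sizes and medians
require the original sequencing data and appear only as documented
constants, never as recomputation targets.

## Numerical choices and degenerate inputs

* Rounding: half away from zero wherever printed-table precision applies.
* Percentiles and quartiles: linear interpolation; box-plot whiskers at
  1.5 × IQR with outliers counted, not dropped.
* Empty interval sets are legal everywhere in the algebra (empty in →
  empty out); empty designs and empty GC lists raise `ValueError`.
* Coverage-curve grid comparisons use integer arithmetic
  (covered_bp × 100 ≥ g × length) so grid points never suffer float
  round-off.
* The depth-track reader rejects negative depths and overlapping runs;
  zero-depth runs are never stored (absence means zero).

## Problem sizes

The default synthetic experiment (3 × 1 Mb genome, ~2,000 regions,
4 samples, 100,000 simulated reads) was chosen so a complete end-to-end
run — generation, coverage, classification, recovery — finishes in a few
seconds while leaving every statistic comfortably inside its asymptotic
regime (binomial SEs well under the asserted tolerances). Oracle
equivalence tests use 10 kb chromosomes where per-base masks are exact
and cheap.
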