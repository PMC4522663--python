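"""Deterministic synthetic data with the statistical structure the
coverage analysis assumes.

The generator emulates, at toy scale, what a hybrid-capture validation
experiment produces: a genome with heterogeneous GC composition, several
annotation sources (exons split into CDS and UTR, plus non-coding RNA
intervals), vendor-style exclusion tracks (Ns, repeats, and a
predicted-unsequenced subset of those), and per-sample per-base depth
tracks whose expected depth is depressed where window GC leaves a
"sequenceable" band — so that all three region performance groups arise
and their planted causes are known.

The depth model: expected depth at a base is

    baseline x sample_scale x gc_multiplier(window GC) x exclusion_multiplier

where the GC multiplier is 1 inside the ok band, decays linearly to a
floor just outside it, and the exclusion multiplier is 0 over
predicted-unsequenced bases.  Realised depth is negative binomial around
the expectation.  Chromosomes are tiled with fixed-size GC zones; most
zones get targets evenly spread across the sequenceable band (so the
reliably covered group spans the band and its GC percentiles are stable
estimates of the band edges), and a fixed fraction get extreme targets
(22% / 78% GC) far outside it.

Everything is deterministic given (seed, sample_index): seeds are spawned
through ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .design import Design, build_design, subset_design
from .intervals import IntervalSet
from .io import AlignedRead, DepthTrack

BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclasses.dataclass
class SimConfig:
    """Parameters of the synthetic capture experiment.

    Defaults describe the standard study conditions used throughout the
    test-suite: 3 chromosomes x 1 Mb tiled into 50 kb GC zones, ~2,000
    target regions, 4 samples at baseline depth 80x with a sequenceable
    GC band of [32, 64.5] %, and an on-target read rate of 0.75.
    """

    seed: int = 0
    n_chroms: int = 3
    chrom_length: int = 1_000_000
    zone_length: int = 50_000
    frac_extreme_zones: float = 0.2
    extreme_gc_targets: tuple[float, float] = (22.0, 78.0)
    mid_gc_range: tuple[float, float] = (33.0, 63.5)
    n_regions: int = 2000
    region_len_range: tuple[int, int] = (150, 1200)
    cds_frac: float = 0.6            # central fraction of an exon that is CDS
    n_ncrna: int = 60
    ncrna_len_range: tuple[int, int] = (60, 200)
    n_repeat_blocks: int = 30
    n_ns_blocks: int = 8
    exclusion_len_range: tuple[int, int] = (500, 2000)
    n_samples: int = 4
    sample_scales: tuple[float, ...] = (1.0, 0.85, 1.1, 0.95)
    baseline_depth: float = 80.0
    gc_ok_band: tuple[float, float] = (32.0, 64.5)
    gc_decay_width: float = 6.0
    gc_floor_mult: float = 0.02
    nb_dispersion: float = 10.0
    smooth_window: int = 100
    on_target_rate: float = 0.75
    read_len: int = 75
    with_chrm: bool = True
    chrm_length: int = 16_000

    def __post_init__(self) -> None:
        if self.n_chroms <= 0 or self.chrom_length <= 0 or self.n_regions <= 0:
            raise ValueError("counts and lengths must be positive")
        if not 0.0 <= self.on_target_rate <= 1.0:
            raise ValueError("on_target_rate must be in [0, 1]")
        if not self.gc_ok_band[0] < self.gc_ok_band[1]:
            raise ValueError("gc_ok_band must satisfy lo < hi")
        if len(self.sample_scales) < self.n_samples:
            raise ValueError("need a depth scale per sample")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


@dataclasses.dataclass
class SimGenome:
    """Generated sequences plus the GC-zone layout used to build them."""

    seqs: dict[str, str]
    chrom_sizes: dict[str, int]
    # per chrom: (zone_start, zone_end, target_gc, is_extreme)
    zones: dict[str, list[tuple[int, int, float, bool]]]

    def __getitem__(self, chrom: str) -> str:
        return self.seqs[chrom]


def _rng(cfg: SimConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((cfg.seed, *stream)))


def generate_genome(cfg: SimConfig) -> SimGenome:
    """Build the zoned genome. Realised zone GC tracks the target to within
    sampling noise (binomial at zone length); deterministic under seed."""
    rng = _rng(cfg, 1)
    zones: dict[str, list[tuple[int, int, float, bool]]] = {}
    seqs: dict[str, str] = {}
    n_zones_per_chrom = cfg.chrom_length // cfg.zone_length
    total_zones = cfg.n_chroms * n_zones_per_chrom
    n_extreme = int(round(total_zones * cfg.frac_extreme_zones))
    # extreme zones spread evenly across the genome, alternating low/high GC
    extreme_ids = set(
        np.linspace(0, total_zones - 1, n_extreme).round().astype(int).tolist()
    ) if n_extreme else set()
    n_mid = total_zones - len(extreme_ids)
    mid_targets = np.linspace(cfg.mid_gc_range[0], cfg.mid_gc_range[1], max(n_mid, 1))
    rng.shuffle(mid_targets)
    mid_iter = iter(mid_targets)
    extreme_flip = 0
    zone_id = 0
    for chrom in cfg.chrom_names():
        chrom_zones = []
        seq_parts = []
        for z in range(n_zones_per_chrom):
            start = z * cfg.zone_length
            end = start + cfg.zone_length if z < n_zones_per_chrom - 1 else cfg.chrom_length
            if zone_id in extreme_ids:
                target = cfg.extreme_gc_targets[extreme_flip % 2]
                extreme_flip += 1
                is_extreme = True
            else:
                target = float(next(mid_iter))
                is_extreme = False
            p_gc = target / 100.0
            L = end - start
            is_gc = rng.random(L) < p_gc
            # choose G vs C and A vs T uniformly
            gc_pick = rng.integers(0, 2, L)
            idx = np.where(is_gc, np.where(gc_pick == 0, 1, 2), np.where(gc_pick == 0, 0, 3))
            seq_parts.append(BASES[idx].tobytes().decode())
            chrom_zones.append((start, end, target, is_extreme))
            zone_id += 1
        zones[chrom] = chrom_zones
        seqs[chrom] = "".join(seq_parts)
    sizes = {c: len(s) for c, s in seqs.items()}
    if cfg.with_chrm:
        is_gc = rng.random(cfg.chrm_length) < 0.45
        gc_pick = rng.integers(0, 2, cfg.chrm_length)
        idx = np.where(is_gc, np.where(gc_pick == 0, 1, 2), np.where(gc_pick == 0, 0, 3))
        seqs["chrM"] = BASES[idx].tobytes().decode()
        sizes["chrM"] = cfg.chrm_length
        zones["chrM"] = [(0, cfg.chrm_length, 45.0, False)]
    return SimGenome(seqs=seqs, chrom_sizes=sizes, zones=zones)


@dataclasses.dataclass
class SimAnnotation:
    """Annotation and exclusion tracks plus the per-exon ground truth."""

    exons: IntervalSet
    cds: IntervalSet
    utr: IntervalSet
    ncrna: IntervalSet
    ns: IntervalSet
    repeats: IntervalSet
    predicted_unseq: IntervalSet
    # parallel to the placed exons, before design merging:
    exon_list: list[tuple[str, int, int]]
    exon_is_extreme: list[bool]


def _place_nonoverlapping(
    rng: np.random.Generator,
    chrom_sizes: dict[str, int],
    chroms: list[str],
    n: int,
    len_range: tuple[int, int],
    min_gap: int = 220,
) -> list[tuple[str, int, int]]:
    """Place n intervals without overlap, keeping a safety gap so later
    padding (up to 100 bp total) cannot merge neighbours."""
    placed: list[tuple[str, int, int]] = []
    per_chrom = {c: [] for c in chroms}
    attempts = 0
    while len(placed) < n and attempts < n * 60:
        attempts += 1
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        L = int(rng.integers(len_range[0], len_range[1] + 1))
        clen = chrom_sizes[chrom]
        start = int(rng.integers(min_gap, clen - L - min_gap))
        ok = all(
            start >= e + min_gap or start + L + min_gap <= s
            for s, e in per_chrom[chrom]
        )
        if ok:
            per_chrom[chrom].append((start, start + L))
            placed.append((chrom, start, start + L))
    if len(placed) < n:
        raise RuntimeError("could not place all intervals; genome too crowded")
    return placed


def generate_annotation(cfg: SimConfig, genome: SimGenome) -> SimAnnotation:
    """Emit annotation sources and exclusion tracks.

    Guarantees by construction: CDS ⊂ exons; UTR = exons − CDS;
    predicted-unsequenced ⊆ Ns ∪ repeats.  A tranche of exons is placed
    inside repeat blocks (and some inside predicted-unsequenced cores) so
    that exclusion-driven dropout exists independent of GC.
    """
    rng = _rng(cfg, 2)
    chroms = cfg.chrom_names()
    sizes = {c: genome.chrom_sizes[c] for c in chroms}

    # exclusion blocks first so some exons can be planted inside them
    n_excl = cfg.n_repeat_blocks + cfg.n_ns_blocks
    excl_blocks = _place_nonoverlapping(
        rng, sizes, chroms, n_excl, cfg.exclusion_len_range, min_gap=2500
    )
    repeats_list = excl_blocks[: cfg.n_repeat_blocks]
    ns_list = excl_blocks[cfg.n_repeat_blocks :]
    # predicted-unsequenced: the inner half of every other exclusion block
    predicted_list = []
    for i, (c, s, e) in enumerate(excl_blocks):
        if i % 2 == 0:
            q = (e - s) // 4
            predicted_list.append((c, s + q, e - q))

    # N runs overwrite the genome sequence
    for c, s, e in ns_list:
        seq = genome.seqs[c]
        genome.seqs[c] = seq[:s] + "N" * (e - s) + seq[e:]

    # exons: most free-standing, a tranche inside exclusion blocks
    n_in_excl = min(len(excl_blocks), max(cfg.n_regions // 20, 1))
    n_free = cfg.n_regions - n_in_excl
    free_exons = _place_nonoverlapping(rng, sizes, chroms, n_free, cfg.region_len_range)
    excl_exons = []
    for c, s, e in excl_blocks[:n_in_excl]:
        mid = (s + e) // 2
        L = min(int(rng.integers(*cfg.region_len_range)), (e - s) // 2)
        excl_exons.append((c, mid - L // 2, mid - L // 2 + L))
    exon_list = sorted(free_exons + excl_exons)

    zone_lookup = {c: genome.zones[c] for c in chroms}

    def is_extreme(chrom: str, s: int, e: int) -> bool:
        mid = (s + e) // 2
        for zs, ze, _t, ext in zone_lookup[chrom]:
            if zs <= mid < ze:
                return ext
        return False

    exon_is_extreme = [is_extreme(c, s, e) for c, s, e in exon_list]

    cds_pieces = []
    for c, s, e in exon_list:
        L = e - s
        cds_len = max(int(L * cfg.cds_frac), 30)
        off = (L - cds_len) // 2
        cds_pieces.append((c, s + off, s + off + cds_len))

    ncrna = _place_nonoverlapping(rng, sizes, chroms, cfg.n_ncrna, cfg.ncrna_len_range)
    # a few decoy regions on the mitochondrion exercise chromosome exclusion
    mito = []
    if cfg.with_chrm:
        mito = [("chrM", 1000 + 800 * i, 1000 + 800 * i + 300) for i in range(5)]

    exons_set = IntervalSet(exon_list + mito)
    cds_set = IntervalSet(cds_pieces)
    return SimAnnotation(
        exons=exons_set,
        cds=cds_set,
        utr=exons_set.subtract(cds_set),
        ncrna=IntervalSet(ncrna),
        ns=IntervalSet(ns_list),
        repeats=IntervalSet(repeats_list),
        predicted_unseq=IntervalSet(predicted_list),
        exon_list=exon_list,
        exon_is_extreme=exon_is_extreme,
    )


def gc_multiplier(window_gc: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Piecewise-linear GC response: 1 inside the ok band, decaying to the
    floor multiplier over ``gc_decay_width`` percentage points outside."""
    lo, hi = cfg.gc_ok_band
    dist = np.where(window_gc < lo, lo - window_gc, np.where(window_gc > hi, window_gc - hi, 0.0))
    frac = np.clip(dist / cfg.gc_decay_width, 0.0, 1.0)
    return 1.0 - frac * (1.0 - cfg.gc_floor_mult)


def _window_gc(seq: str, window: int) -> np.ndarray:
    """Centered sliding-window %GC (0..100); N bases drop out of both the
    numerator and the denominator, defaulting to 50 where nothing remains."""
    arr = np.frombuffer(seq.encode(), dtype="S1")
    gc = np.isin(arr, np.array([b"G", b"C", b"g", b"c"])).astype(np.float64)
    valid = ~np.isin(arr, np.array([b"N", b"n"]))
    kernel = np.ones(window)
    gc_sum = np.convolve(gc, kernel, mode="same")
    val_sum = np.convolve(valid.astype(np.float64), kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(val_sum > 0, gc_sum / np.maximum(val_sum, 1), 0.5)
    return frac * 100.0


def simulate_depth(
    cfg: SimConfig,
    genome: SimGenome,
    design: Design,
    ann: SimAnnotation,
    sample_index: int,
) -> DepthTrack:
    """Per-base depth for one sample over the design's bases.

    Expected depth = baseline x sample scale x GC multiplier (on a
    ``smooth_window`` sliding window) x 0 over predicted-unsequenced
    bases; realised depth is negative binomial with dispersion
    ``nb_dispersion``.  Bases outside the design are left at depth 0 —
    the track is the capture's contract.
    """
    rng = _rng(cfg, 3, sample_index)
    scale = cfg.sample_scales[sample_index]
    r = cfg.nb_dispersion
    runs: dict[str, np.ndarray] = {}
    for chrom in design.regions.chroms:
        wgc = _window_gc(genome.seqs[chrom], cfg.smooth_window)
        chrom_runs: list[np.ndarray] = []
        pu = ann.predicted_unseq.arrays(chrom)
        for s, e in design.regions.arrays(chrom):
            s, e = int(s), int(e)
            mu = cfg.baseline_depth * scale * gc_multiplier(wgc[s:e], cfg)
            # zero out predicted-unsequenced bases
            for ps, pe in pu:
                a, b = max(int(ps), s), min(int(pe), e)
                if a < b:
                    mu[a - s : b - s] = 0.0
            depth = np.zeros(e - s, dtype=np.int64)
            pos = mu > 0
            if pos.any():
                p = r / (r + mu[pos])
                depth[pos] = rng.negative_binomial(r, p)
            # run-length encode, dropping zero runs
            if depth.any():
                change = np.flatnonzero(np.diff(depth) != 0) + 1
                starts = np.concatenate([[0], change])
                ends = np.concatenate([change, [len(depth)]])
                vals = depth[starts]
                keep = vals > 0
                chrom_runs.append(
                    np.column_stack([s + starts[keep], s + ends[keep], vals[keep]])
                )
        if chrom_runs:
            runs[chrom] = np.vstack(chrom_runs)
    return DepthTrack(runs)


def simulate_reads(
    cfg: SimConfig,
    design: Design,
    chrom_sizes: dict[str, int],
    n_reads: int,
    sample_index: int,
) -> list[AlignedRead]:
    """Simulate mapped-read footprints with a known on-target rate.

    The on-target count is Binomial(n_reads, on_target_rate); on-target
    reads cover a uniformly chosen design base, off-target reads start
    uniformly in the complement of the design expanded by read_len-1, so
    they are guaranteed not to touch it.
    """
    rng = _rng(cfg, 4, sample_index)
    rl = cfg.read_len
    n_on = int(rng.binomial(n_reads, cfg.on_target_rate))

    # cumulative design-base index for weighted on-target placement
    chroms, spans = [], []
    for chrom in design.regions.chroms:
        for s, e in design.regions.arrays(chrom):
            chroms.append(chrom)
            spans.append((int(s), int(e)))
    lengths = np.array([e - s for s, e in spans], dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(lengths)])

    reads: list[AlignedRead] = []
    base_idx = rng.integers(0, cum[-1], size=n_on)
    offsets = rng.integers(0, rl, size=n_on)
    for bi, off in zip(base_idx, offsets):
        k = int(np.searchsorted(cum, bi, side="right")) - 1
        chrom = chroms[k]
        base = spans[k][0] + int(bi - cum[k])
        start = max(base - int(off), 0)
        start = min(start, chrom_sizes[chrom] - rl)
        start = max(start, base - rl + 1)  # keep the chosen base inside the read
        start = max(start, 0)
        reads.append(AlignedRead(chrom, start, start + rl, str(sample_index)))

    # off-target start space: complement of design expanded left by rl-1
    expanded = IntervalSet(
        (c, max(s - (rl - 1), 0), e)
        for c in design.regions.chroms
        for s, e in design.regions.arrays(c)
    )
    genome_space = IntervalSet(
        (c, 0, max(L - rl, 1)) for c, L in chrom_sizes.items()
    )
    safe = genome_space.subtract(expanded)
    s_chroms, s_spans = [], []
    for chrom in safe.chroms:
        for s, e in safe.arrays(chrom):
            s_chroms.append(chrom)
            s_spans.append((int(s), int(e)))
    s_len = np.array([e - s for s, e in s_spans], dtype=np.int64)
    s_cum = np.concatenate([[0], np.cumsum(s_len)])
    off_idx = rng.integers(0, s_cum[-1], size=n_reads - n_on)
    for oi in off_idx:
        k = int(np.searchsorted(s_cum, oi, side="right")) - 1
        chrom = s_chroms[k]
        start = s_spans[k][0] + int(oi - s_cum[k])
        reads.append(AlignedRead(chrom, start, start + rl, str(sample_index)))
    rng.shuffle(reads)  # type: ignore[arg-type]
    return reads


@dataclasses.dataclass
class SimCohort:
    """A complete synthetic experiment: genome, tracks, designs, truth."""

    cfg: SimConfig
    genome: SimGenome
    annotation: SimAnnotation
    design_plus: Design
    design_cds: Design
    depth_tracks: list[DepthTrack]
    truth: "np.ndarray"  # structured per design_plus region

    def region_truth(self):
        return self.truth


def simulate_cohort(cfg: SimConfig) -> SimCohort:
    """Run the full generator: genome -> annotation -> designs -> depth.

    The "plus"-style design unions exons and ncRNA; the CDS-style subset
    keeps CDS plus ncRNA.  Truth records, per final design region,
    whether it lies in an extreme-GC zone and its exclusion overlaps.
    """
    genome = generate_genome(cfg)
    ann = generate_annotation(cfg, genome)
    design_plus = build_design(
        [ann.exons, ann.ncrna], "sim-plus", genome.chrom_sizes
    )
    keep = ann.cds.union(ann.ncrna)
    design_cds = subset_design(design_plus, keep, "sim-cds", genome.chrom_sizes)
    tracks = [
        simulate_depth(cfg, genome, design_plus, ann, i) for i in range(cfg.n_samples)
    ]
    extreme_zones = IntervalSet(
        (c, zs, ze)
        for c, zlist in genome.zones.items()
        for zs, ze, _t, ext in zlist
        if ext
    )
    truth = np.zeros(
        design_plus.n_regions,
        dtype=[
            ("extreme_gc", bool),
            ("ns", bool),
            ("repeats", bool),
            ("predicted_unseq", bool),
        ],
    )
    for rid, iv in design_plus.iter_regions():
        mid = (iv.start + iv.end) // 2
        truth["extreme_gc"][rid] = extreme_zones.overlaps(iv.chrom, mid, mid + 1)
        truth["ns"][rid] = ann.ns.overlaps(iv.chrom, iv.start, iv.end)
        truth["repeats"][rid] = ann.repeats.overlaps(iv.chrom, iv.start, iv.end)
        truth["predicted_unseq"][rid] = ann.predicted_unseq.overlaps(
            iv.chrom, iv.start, iv.end
        )
    return SimCohort(
        cfg=cfg,
        genome=genome,
        annotation=ann,
        design_plus=design_plus,
        design_cds=design_cds,
        depth_tracks=tracks,
        truth=truth,
    )
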