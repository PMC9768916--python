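"""Synthetic data generator for the whole pipeline.

Emulates the statistical structure the downstream analysis assumes, so every
stage is testable without external downloads:

* a genome annotation (TSS table with per-replicate FPKM values spanning the
  0.5 FPKM activity threshold),
* ChIP-seq-like peak sets and NDRs with realistic widths (regulatory
  elements < 2 kb, NDRs < 1 kb on average),
* ~450 kb contact domains (TADs) and planted loops whose anchor-category
  frequencies are configurable,
* contact maps with power-law distance decay, multiplicative TAD-block and
  loop-pixel enrichment, and Poisson counting noise,
* oscillatory (phased-nucleosome) MNase, accessibility and methylation
  tracks whose shape differs by in-loop status.

Randomness: one global integer seed; each operation draws from its own
sub-stream derived from (seed, crc32(operation name)), so module call order
does not change results and a fixed seed gives byte-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from math import ceil
from typing import Mapping, Sequence

import numpy as np

from .contacts import ContactMap
from .elements import PRIORITY_RANK, RegElement
from .genomic_io import GenomicInterval, IntervalIndex, SignalTrack, TssRecord

__all__ = [
    "SynthConfig",
    "SignalParams",
    "TrueLoop",
    "TrueLoopSet",
    "MARKS",
    "generate_genome",
    "generate_peaks",
    "generate_tads",
    "plant_loops",
    "simulate_contact_map",
    "simulate_signal_tracks",
    "downsample_contacts",
]

MARKS = ("H3K27ac", "CTCF", "H3K27me3", "H3K9me3", "NDR")


def _default_peak_width_law() -> dict[str, tuple[float, float]]:
    # (mean, sd) in bp; active elements < 2 kb, NDRs < 1 kb
    return {
        "H3K27ac": (1200.0, 300.0),
        "CTCF": (350.0, 100.0),
        "H3K27me3": (1500.0, 400.0),
        "H3K9me3": (1500.0, 400.0),
        "NDR": (600.0, 150.0),
    }


def _default_n_peaks() -> dict[str, int]:
    return {"H3K27ac": 250, "CTCF": 250, "H3K27me3": 200, "H3K9me3": 200, "NDR": 300}


def _default_category_weights() -> dict[tuple[str, str], float]:
    """Planted anchor-category frequencies: insulator-involved loops dominate,
    then promoter-involved, mirroring the rank structure of deep contact maps.
    """
    return {
        ("insulator", "insulator"): 0.22,
        ("promoter", "insulator"): 0.17,
        ("promoter", "promoter"): 0.13,
        ("promoter", "enhancer"): 0.10,
        ("enhancer", "insulator"): 0.09,
        ("enhancer", "enhancer"): 0.06,
        ("promoter", "ndr_nofeat"): 0.06,
        ("insulator", "ndr_nofeat"): 0.05,
        ("ndr_nofeat", "ndr_nofeat"): 0.04,
        ("promoter", "repressed"): 0.03,
        ("insulator", "repressed"): 0.02,
        ("repressed", "repressed"): 0.02,
        ("enhancer", "ndr_nofeat"): 0.005,
        ("promoter", "heterochromatin"): 0.005,
    }


@dataclass
class SignalParams:
    """Shapes and effect sizes for the synthetic signal tracks.

    MNase is in arbitrary coverage units; accessibility and methylation are
    percentages. The in-loop/not-in-loop contrasts follow the direction seen
    at looped active elements: deeper nucleosome dip, stronger phasing,
    higher accessibility, lower methylation.
    """

    nucleosome_period: float = 190.0  # bp; not a literature constant, a default
    mnase_baseline: float = 1.0
    dip_depth_out: float = 0.5
    dip_depth_in: float = 0.7
    dip_sigma: float = 150.0  # bp
    phasing_amp_out: float = 0.12
    phasing_amp_in: float = 0.25
    phasing_decay: float = 800.0  # bp e-folding of the flank oscillation
    mnase_noise_sd: float = 0.05
    step: int = 10  # bp; tracks are piecewise constant over this grid
    accessibility_baseline: float = 30.0  # %
    accessibility_effect: float = 20.0  # % points added for in-loop elements
    accessibility_peak: float = 25.0  # % central bump
    methylation_baseline: float = 70.0  # %
    methylation_effect: float = 15.0  # % points subtracted for in-loop
    methylation_dip: float = 20.0  # % central dip
    percent_noise_sd: float = 3.0


@dataclass
class SynthConfig:
    """Study-condition parameters for the synthetic genome.

    Scaled-down single-chromosome defaults (20 Mb) keep every simulation
    desk-sized while preserving the structure of the analysis: TADs average
    ~450 kb, elements are sub-2 kb, NDRs sub-1 kb, expression spans the
    0.5 FPKM threshold, and contact counts decay as a power law of distance.
    """

    chrom_sizes: dict[str, int] = field(default_factory=lambda: {"chrS": 20_000_000})
    n_tss: int = 400
    n_fpkm_reps: int = 3
    fpkm_law: tuple[float, float] = (0.0, 1.5)  # log-normal (mu, sigma) of ln FPKM
    peak_width_law: dict[str, tuple[float, float]] = field(
        default_factory=_default_peak_width_law
    )
    n_peaks: dict[str, int] = field(default_factory=_default_n_peaks)
    tss_free_frac: float = 0.5  # fraction of peaks placed >2 kb from every TSS
    tad_size_mean: int = 450_000
    tad_fold: float = 3.0
    loop_category_weights: dict[tuple[str, str], float] = field(
        default_factory=_default_category_weights
    )
    n_loops: int = 60
    loop_fold: float = 6.0
    loop_anchor_window: int = 2_000  # fuzzy-join half-width anchors are vetted at
    loop_distance_law: tuple[float, float] = (np.log(350_000.0), 0.5)
    min_loop_distance: int = 60_000
    max_loop_distance: int = 2_000_000
    decay_exponent: float = 1.0
    depth: int = 5_000_000
    binsize: int = 10_000
    signal: SignalParams = field(default_factory=SignalParams)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length")
        if self.n_tss < 0:
            raise ValueError("n_tss must be >= 0")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.tad_size_mean <= 0:
            raise ValueError("tad_size_mean must be > 0")
        w = self.loop_category_weights
        if w:
            if any(v < 0 for v in w.values()):
                raise ValueError("category weights must be >= 0")
            if abs(sum(w.values()) - 1.0) > 1e-9:
                raise ValueError("category weights must sum to 1 (within 1e-9)")
        for mark in self.peak_width_law:
            if mark not in MARKS:
                raise ValueError(f"unknown mark {mark!r}")

    def rng(self, stream: str) -> np.random.Generator:
        """Sub-stream generator: stable per (seed, operation name)."""
        return np.random.default_rng([self.seed, zlib.crc32(stream.encode())])


# ---------------------------------------------------------------------------
# true-loop ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrueLoop:
    anchor1: GenomicInterval
    anchor2: GenomicInterval
    category: tuple[str, str]
    fold: float

    def __post_init__(self) -> None:
        if self.anchor1.chrom != self.anchor2.chrom:
            raise ValueError("true-loop anchors must share a chromosome")
        if self.anchor1.start > self.anchor2.start:
            raise ValueError("anchor1 must precede anchor2")
        if self.fold < 1.0:
            raise ValueError("planted fold must be >= 1")

    @property
    def chrom(self) -> str:
        return self.anchor1.chrom

    @property
    def distance(self) -> int:
        return self.anchor2.midpoint - self.anchor1.midpoint


@dataclass
class TrueLoopSet:
    loops: list[TrueLoop]

    def __len__(self) -> int:
        return len(self.loops)

    def __iter__(self):
        return iter(self.loops)


# ---------------------------------------------------------------------------
# genome annotation
# ---------------------------------------------------------------------------


def generate_genome(
    cfg: SynthConfig,
) -> tuple[dict[str, int], list[TssRecord]]:
    """TSS table with log-normal FPKM replicates; positions uniform per chrom.

    TSS positions keep a 10 kb margin from chromosome ends (when the
    chromosome allows it) so that promoter windows and profile flanks stay in
    bounds; boundary clipping is still exercised by direct construction.
    """
    cfg.validate()
    rng = cfg.rng("generate_genome")
    chroms = sorted(cfg.chrom_sizes)
    total = sum(cfg.chrom_sizes[c] for c in chroms)
    # largest-remainder apportionment of n_tss across chromosomes
    quotas = [cfg.n_tss * cfg.chrom_sizes[c] / total for c in chroms]
    counts = [int(q) for q in quotas]
    for _ in range(cfg.n_tss - sum(counts)):
        i = int(np.argmax([q - c for q, c in zip(quotas, counts)]))
        counts[i] += 1
    mu, sigma = cfg.fpkm_law
    records: list[TssRecord] = []
    for chrom, n in zip(chroms, counts):
        size = cfg.chrom_sizes[chrom]
        margin = 10_000 if size > 40_000 else 0
        pos = np.sort(rng.integers(margin, size - margin, size=n))
        strands = rng.choice(["+", "-"], size=n)
        fpkm = rng.lognormal(mu, sigma, size=(n, cfg.n_fpkm_reps))
        for i in range(n):
            records.append(
                TssRecord(
                    chrom=chrom,
                    pos=int(pos[i]),
                    strand=str(strands[i]),
                    gene_id=f"{chrom}_g{i:04d}",
                    fpkm=tuple(float(v) for v in fpkm[i]),
                )
            )
    return dict(cfg.chrom_sizes), records


def generate_peaks(
    chrom_sizes: Mapping[str, int],
    mark: str,
    cfg: SynthConfig,
    tss: Sequence[TssRecord],
    n_peaks: int | None = None,
    tss_free_frac: float | None = None,
    near_intervals: Sequence[GenomicInterval] | None = None,
) -> list[GenomicInterval]:
    """Peak set for one mark with configurable placement relative to TSSs.

    A ``tss_free_frac`` fraction of peaks is rejection-sampled to lie > 2 kb
    from every TSS (zero overlap with TSS ±2 kb windows), so the
    enhancer/insulator exclusion rules are exercised; the rest are centered
    near a random TSS (or near ``near_intervals`` when given, e.g. to drop
    NDRs inside enhancer peaks).
    """
    if mark not in MARKS:
        raise ValueError(f"unknown mark {mark!r}; expected one of {MARKS}")
    n = cfg.n_peaks.get(mark, 0) if n_peaks is None else n_peaks
    if n == 0:
        return []
    frac = cfg.tss_free_frac if tss_free_frac is None else tss_free_frac
    rng = cfg.rng(f"generate_peaks:{mark}")
    mean_w, sd_w = cfg.peak_width_law[mark]
    widths = np.maximum(np.round(rng.normal(mean_w, sd_w, size=n)), 50).astype(int)
    tss_windows = [
        GenomicInterval(t.chrom, max(0, t.pos - 2000), t.pos + 2000) for t in tss
    ]
    tss_index = IntervalIndex(tss_windows)
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    n_far = int(round(n * frac))
    peaks: list[GenomicInterval] = []
    for k in range(n):
        w = int(widths[k])
        if k < n_far:
            # rejection-sample a placement clear of every TSS window
            for _ in range(10_000):
                ci = int(rng.choice(len(chroms), p=probs))
                chrom, size = chroms[ci], int(sizes[ci])
                if size <= w:
                    continue
                start = int(rng.integers(0, size - w))
                iv = GenomicInterval(chrom, start, start + w)
                if not tss_index.any_overlap(iv):
                    peaks.append(iv)
                    break
            else:
                raise RuntimeError(
                    f"could not place a TSS-free {mark} peak; genome too crowded"
                )
        else:
            if near_intervals:
                target = near_intervals[int(rng.integers(len(near_intervals)))]
                center = target.midpoint + int(rng.integers(-200, 201))
                chrom, size = target.chrom, chrom_sizes[target.chrom]
            elif tss:
                t = tss[int(rng.integers(len(tss)))]
                center = t.pos + int(rng.integers(-1000, 1001))
                chrom, size = t.chrom, chrom_sizes[t.chrom]
            else:
                ci = int(rng.choice(len(chroms), p=probs))
                chrom, size = chroms[ci], int(sizes[ci])
                center = int(rng.integers(0, size))
            start = max(0, min(center - w // 2, size - w))
            peaks.append(GenomicInterval(chrom, start, start + w))
    return peaks


def generate_tads(
    chrom: str, cfg: SynthConfig, binsize: int = 50_000
) -> list[GenomicInterval]:
    """Partition a chromosome into adjacent domains averaging tad_size_mean.

    Domain sizes are gamma-distributed (shape 4) and snapped to ``binsize``
    multiples so that planted boundaries sit exactly on analysis-bin edges;
    a trailing fragment shorter than 2 bins is merged into the last domain.
    """
    rng = cfg.rng(f"generate_tads:{chrom}")
    size = cfg.chrom_sizes[chrom]
    tads: list[GenomicInterval] = []
    pos = 0
    while pos < size:
        raw = rng.gamma(shape=4.0, scale=cfg.tad_size_mean / 4.0)
        nb = max(4, int(round(raw / binsize)))
        end = min(pos + nb * binsize, size)
        if size - end < 2 * binsize:
            end = size
        tads.append(GenomicInterval(chrom, pos, end))
        pos = end
    return tads


def plant_loops(
    elements: Sequence[RegElement],
    cfg: SynthConfig,
    n_loops: int | None = None,
    distance_tolerance: int = 90_000,
) -> TrueLoopSet:
    """Sample true loops between element pairs with configured category weights.

    For each loop a category is drawn from ``loop_category_weights``, a
    target separation from the (log-normal) distance law, and the second
    anchor is the eligible element whose center lands closest to the target;
    draws missing the target by more than ``distance_tolerance`` are
    rejected and resampled. Anchors are the element intervals themselves.

    Only *unambiguous* elements are eligible as anchors: an element whose
    ±``loop_anchor_window`` expansion overlaps a higher-priority element
    would be re-labeled by the downstream fuzzy-join annotation, which
    would make the planted category ill-defined as ground truth.
    """
    from .annotate import ElementIndex, _annotate  # no cycle: annotate <- elements

    n = cfg.n_loops if n_loops is None else n_loops
    weights = {
        tuple(sorted(k, key=lambda lab: PRIORITY_RANK[lab])): v
        for k, v in cfg.loop_category_weights.items()
        if v > 0
    }
    if n == 0:
        return TrueLoopSet([])
    index = ElementIndex(list(elements))
    by_label: dict[str, list[RegElement]] = {}
    for el in elements:
        al = _annotate(el.interval, index, cfg.loop_anchor_window)
        if al.label == el.label and al.element_id == el.source_id:
            by_label.setdefault(el.label, []).append(el)
    for lab1, lab2 in weights:
        pool1 = by_label.get(lab1, [])
        pool2 = by_label.get(lab2, [])
        ok = (
            len(pool1) >= 2
            if lab1 == lab2
            else any(
                e1.chrom == e2.chrom for e1 in pool1 for e2 in pool2
            )
            if pool1 and pool2
            else False
        )
        if not ok:
            raise ValueError(
                f"category {lab1}-{lab2} has nonzero weight but no eligible pair"
            )
    rng = cfg.rng("plant_loops")
    cats = list(weights)
    probs = np.array([weights[c] for c in cats])
    probs = probs / probs.sum()
    mu, sigma = cfg.loop_distance_law
    loops: list[TrueLoop] = []
    used: set[tuple[int, int, str]] = set()
    for _ in range(n):
        placed = False
        # the category is drawn once per loop and held fixed across placement
        # retries: redrawing it on failure would bias frequencies toward
        # categories whose element pools are easier to place
        cat = cats[int(rng.choice(len(cats), p=probs))]
        lab1, lab2 = cat
        for _attempt in range(500):
            pool1, pool2 = by_label[lab1], by_label[lab2]
            a = pool1[int(rng.integers(len(pool1)))]
            partners = [
                e for e in pool2 if e.chrom == a.chrom and e.interval != a.interval
            ]
            if not partners:
                continue
            d = float(np.clip(rng.lognormal(mu, sigma),
                              cfg.min_loop_distance, cfg.max_loop_distance))
            side = 1 if rng.random() < 0.5 else -1
            target = a.center + side * d
            b = min(partners, key=lambda e: abs(e.center - target))
            dist = abs(b.center - a.center)
            if abs(dist - d) > distance_tolerance or dist < cfg.min_loop_distance:
                continue
            left, right = (a, b) if a.center <= b.center else (b, a)
            key = (left.center, right.center, a.chrom)
            if key in used:
                continue
            used.add(key)
            loops.append(
                TrueLoop(
                    anchor1=left.interval,
                    anchor2=right.interval,
                    category=cat,
                    fold=cfg.loop_fold,
                )
            )
            placed = True
            break
        if not placed:
            raise RuntimeError(
                "could not place a planted loop after 500 draws; "
                "element set too sparse for the configured distance law"
            )
    return TrueLoopSet(loops)


# ---------------------------------------------------------------------------
# contact maps
# ---------------------------------------------------------------------------


def simulate_contact_map(
    chrom: str,
    binsize: int,
    tads: Sequence[GenomicInterval],
    true_loops: TrueLoopSet | Sequence[TrueLoop],
    cfg: SynthConfig,
    depth: int | None = None,
    rng: np.random.Generator | None = None,
) -> ContactMap:
    """Poisson contact map with power-law decay, TAD blocks and loop dots.

    Expected count at genomic distance d is proportional to
    ``(d + binsize) ** -decay_exponent`` (the +binsize offset removes the
    d = 0 singularity; the diagonal is included). Pixels with both bins
    inside one TAD are multiplied by ``tad_fold``; the pixel at each true
    loop's anchor pair is multiplied by that loop's planted fold (folds are
    log-additive with the decay). The expectation is scaled so the total
    upper-triangle count equals ``depth``, then counts are drawn Poisson.
    """
    depth = cfg.depth if depth is None else depth
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if rng is None:
        rng = cfg.rng(f"simulate_contact_map:{chrom}")
    size = cfg.chrom_sizes[chrom]
    n = ceil(size / binsize)
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
    expect = np.power(d * binsize + binsize, -cfg.decay_exponent)
    for tad in tads:
        if tad.chrom != chrom:
            continue
        b0, b1 = tad.start // binsize, min(ceil(tad.end / binsize), n)
        expect[b0:b1, b0:b1] *= cfg.tad_fold
    for lp in true_loops:
        if lp.chrom != chrom:
            continue
        bi = min(lp.anchor1.midpoint // binsize, n - 1)
        bj = min(lp.anchor2.midpoint // binsize, n - 1)
        bi, bj = min(bi, bj), max(bi, bj)
        expect[bi, bj] *= lp.fold
        expect[bj, bi] = expect[bi, bj]
    upper = np.triu(expect)
    total = upper.sum()
    if total > 0 and depth > 0:
        upper *= depth / total
    else:
        upper[:] = 0.0
    counts = rng.poisson(upper).astype(np.int64)
    return ContactMap.from_dense_upper(chrom, binsize, counts)


def downsample_contacts(
    cmap: ContactMap,
    fraction: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ContactMap:
    """Binomially thin every stored count: Binomial(count, fraction).

    Preserves the expectation times ``fraction``; models sequencing a
    smaller library from the same material.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    if fraction == 1.0:
        return ContactMap(cmap.chrom, cmap.binsize, cmap.upper.copy())
    if rng is None:
        rng = np.random.default_rng(seed)
    coo = cmap.upper.tocoo()
    thinned = rng.binomial(coo.data.astype(np.int64), fraction)
    return ContactMap.from_coo(
        cmap.chrom, cmap.binsize, cmap.n_bins, coo.row, coo.col, thinned
    )


# ---------------------------------------------------------------------------
# signal tracks
# ---------------------------------------------------------------------------


def simulate_signal_tracks(
    elements: Sequence[RegElement],
    in_loop: Sequence[bool],
    cfg: SynthConfig,
    chrom_sizes: Mapping[str, int] | None = None,
    window: int = 2_600,
    rng: np.random.Generator | None = None,
) -> dict[str, dict[str, SignalTrack]]:
    """MNase / accessibility / methylation tracks around element centers.

    Each element gets a ±``window`` bp signal footprint at its center:
    MNase shows a central nucleosome-depleted dip plus damped-cosine flanks
    (phased nucleosomes); accessibility a central bump; methylation a
    central trough. In-loop elements get the configured contrasts (deeper
    dip, stronger phasing, +accessibility, -methylation). Bases outside all
    footprints stay NaN (missing), matching coverage-track semantics.
    """
    if len(elements) != len(in_loop):
        raise ValueError("in_loop flags must align with elements")
    if chrom_sizes is None:
        chrom_sizes = cfg.chrom_sizes
    if rng is None:
        rng = cfg.rng("simulate_signal_tracks")
    p = cfg.signal
    tracks = {
        name: {
            chrom: SignalTrack(chrom, np.full(size, np.nan))
            for chrom, size in chrom_sizes.items()
        }
        for name in ("mnase", "accessibility", "methylation")
    }
    step = p.step
    for el, flag in zip(elements, in_loop):
        size = chrom_sizes[el.chrom]
        lo = max(0, el.center - window)
        hi = min(size, el.center + window + 1)
        n_blocks = -(-(hi - lo) // step)
        # piecewise-constant signal on a `step`-bp grid (site-level assays
        # do not resolve single bases); x = block-center offset from center
        x = lo + step * np.arange(n_blocks) + step / 2 - el.center
        dip = p.dip_depth_in if flag else p.dip_depth_out
        amp = p.phasing_amp_in if flag else p.phasing_amp_out
        gauss = np.exp(-(x**2) / (2 * p.dip_sigma**2))
        osc = (
            amp
            * np.cos(2 * np.pi * x / p.nucleosome_period)
            * np.exp(-np.abs(x) / p.phasing_decay)
        )
        mnase = (
            p.mnase_baseline
            - dip * gauss
            + osc
            + rng.normal(0, p.mnase_noise_sd, size=n_blocks)
        )
        acc_gauss = np.exp(-(x**2) / (2 * 300.0**2))
        acc = (
            p.accessibility_baseline
            + (p.accessibility_effect if flag else 0.0)
            + p.accessibility_peak * acc_gauss
            + rng.normal(0, p.percent_noise_sd, size=n_blocks)
        )
        meth = (
            p.methylation_baseline
            - (p.methylation_effect if flag else 0.0)
            - p.methylation_dip * acc_gauss
            + rng.normal(0, p.percent_noise_sd, size=n_blocks)
        )
        span = hi - lo
        tracks["mnase"][el.chrom].values[lo:hi] = np.repeat(mnase, step)[:span]
        tracks["accessibility"][el.chrom].values[lo:hi] = np.repeat(
            np.clip(acc, 0.0, 100.0), step
        )[:span]
        tracks["methylation"][el.chrom].values[lo:hi] = np.repeat(
            np.clip(meth, 0.0, 100.0), step
        )[:span]
    return tracks
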