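"""Regulatory-element classification by the exclusion hierarchy.

Seven-label vocabulary (in priority order): active promoter, active
enhancer, active insulator, NDR without features, repressed region,
heterochromatin region, and "none" (used downstream for unannotated loop
anchors). Classification is order-dependent by design:

* promoter   — ±2 kb window around a TSS whose mean FPKM exceeds 0.5
* enhancer   — H3K27ac peak with zero overlap with any TSS ±2 kb window
* insulator  — CTCF peak clear of TSS windows and of enhancers
* ndr_nofeat — nucleosome-depleted region clear of all active elements
* repressed  — H3K27me3 peak clear of all active elements
* heterochromatin — H3K9me3 peak clear of active elements and repressed

"Clear of" means zero shared bases under half-open interval arithmetic;
">2 kb from TSS" is interpreted as no overlap with the TSS ±2 kb window,
consistent with the windowed promoter definition. The FPKM threshold is a
strict inequality (mean FPKM 0.5 exactly is excluded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

from .genomic_io import GenomicInterval, IntervalIndex, TssRecord

logger = logging.getLogger("loopscape")

__all__ = [
    "LABELS",
    "PRIORITY",
    "RegElement",
    "active_promoters",
    "classify_elements",
    "element_centers",
]

# priority order: first label wins when a loop anchor overlaps several elements
PRIORITY: tuple[str, ...] = (
    "promoter",
    "enhancer",
    "insulator",
    "ndr_nofeat",
    "repressed",
    "heterochromatin",
)
LABELS = PRIORITY  # the six element labels; "none" exists only for anchors

PRIORITY_RANK = {label: i for i, label in enumerate(PRIORITY + ("none",))}

DEFAULT_FPKM_MIN = 0.5
TSS_HALF_WINDOW = 2_000


@dataclass(frozen=True)
class RegElement:
    """A classified regulatory element.

    ``center`` is the anchor point used for signal profiles (TSS for
    promoters, NDR midpoint for enhancers, CTCF motif midpoint for
    insulators); ``center_fallback`` flags elements where no NDR/motif was
    available and the raw interval midpoint was used instead.
    """

    interval: GenomicInterval
    label: str
    source_id: str
    center: int
    rule: str = ""
    center_fallback: bool = False

    def __post_init__(self) -> None:
        if self.label not in PRIORITY:
            raise ValueError(f"unknown element label {self.label!r}")
        if not (self.interval.start <= self.center < self.interval.end):
            raise ValueError(
                f"center {self.center} outside {self.interval.chrom}:"
                f"{self.interval.start}-{self.interval.end}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom


def _tss_windows(
    tss: Sequence[TssRecord], half_window: int = TSS_HALF_WINDOW
) -> list[GenomicInterval]:
    return [
        GenomicInterval(t.chrom, max(0, t.pos - half_window), t.pos + half_window)
        for t in tss
    ]


def active_promoters(
    tss: Sequence[TssRecord],
    fpkm_min: float = DEFAULT_FPKM_MIN,
    half_window: int = TSS_HALF_WINDOW,
    chrom_sizes: dict[str, int] | None = None,
) -> list[RegElement]:
    """Active promoters: TSS ±2 kb windows of expressed transcripts.

    A TSS qualifies when its mean FPKM across replicates is strictly greater
    than ``fpkm_min``. Windows are clipped to chromosome bounds (left bound
    always; right bound when ``chrom_sizes`` is given); the profile center
    stays at the TSS itself regardless of clipping.
    """
    out: list[RegElement] = []
    for t in tss:
        if t.mean_fpkm <= fpkm_min:
            continue
        start = max(0, t.pos - half_window)
        end = t.pos + half_window
        if chrom_sizes is not None and t.chrom in chrom_sizes:
            end = min(end, chrom_sizes[t.chrom])
        out.append(
            RegElement(
                interval=GenomicInterval(t.chrom, start, end),
                label="promoter",
                source_id=t.gene_id,
                center=t.pos,
                rule=f"mean FPKM {t.mean_fpkm:.3g} > {fpkm_min}",
            )
        )
    return out


def _exclude(
    peaks: Sequence[GenomicInterval],
    excluders: Sequence[GenomicInterval],
) -> list[bool]:
    """keep-flag per peak: True when the peak overlaps no excluder."""
    if not excluders:
        return [True] * len(peaks)
    index = IntervalIndex(excluders)
    return [not index.any_overlap(p) for p in peaks]


def classify_elements(
    promoters: Sequence[RegElement],
    k27ac_peaks: Sequence[GenomicInterval],
    ctcf_peaks: Sequence[GenomicInterval],
    ndrs: Sequence[GenomicInterval],
    k27me3_peaks: Sequence[GenomicInterval],
    k9me3_peaks: Sequence[GenomicInterval],
    tss: Sequence[TssRecord],
    tss_half_window: int = TSS_HALF_WINDOW,
) -> list[RegElement]:
    """Apply the full exclusion hierarchy; returns all elements, promoters first.

    TSS windows (all TSS, expressed or not) exclude peaks from the enhancer
    and insulator classes; active elements exclude NDRs, repressed and
    heterochromatin regions; repressed regions additionally exclude
    heterochromatin. Each element records the rule that admitted it.
    """
    tssw = _tss_windows(tss, tss_half_window)

    def mk(peaks, keep, label, rule, prefix):
        return [
            RegElement(
                interval=p,
                label=label,
                source_id=f"{prefix}{i:05d}",
                center=p.midpoint,
                rule=rule,
            )
            for i, (p, k) in enumerate(zip(peaks, keep))
            if k
        ]

    enhancers = mk(
        k27ac_peaks,
        _exclude(k27ac_peaks, tssw),
        "enhancer",
        "H3K27ac peak >2 kb from all TSS",
        "enh",
    )
    enh_iv = [e.interval for e in enhancers]
    insulators = mk(
        ctcf_peaks,
        _exclude(ctcf_peaks, list(tssw) + enh_iv),
        "insulator",
        "CTCF peak >2 kb from TSS, not in an enhancer",
        "ins",
    )
    active_iv = (
        [p.interval for p in promoters] + enh_iv + [i.interval for i in insulators]
    )
    ndr_nofeat = mk(
        ndrs,
        _exclude(ndrs, active_iv),
        "ndr_nofeat",
        "NDR outside promoter/enhancer/insulator",
        "ndr",
    )
    repressed = mk(
        k27me3_peaks,
        _exclude(k27me3_peaks, active_iv),
        "repressed",
        "H3K27me3 peak outside active elements",
        "rep",
    )
    hetero = mk(
        k9me3_peaks,
        _exclude(k9me3_peaks, active_iv + [r.interval for r in repressed]),
        "heterochromatin",
        "H3K9me3 peak outside active and repressed",
        "het",
    )
    out = list(promoters) + enhancers + insulators + ndr_nofeat + repressed + hetero
    logger.info(
        "classified elements: %s",
        {lab: sum(1 for e in out if e.label == lab) for lab in PRIORITY},
    )
    return out


def element_centers(
    elements: Sequence[RegElement],
    ctcf_motifs: Sequence[GenomicInterval] = (),
    ndrs: Sequence[GenomicInterval] = (),
) -> list[RegElement]:
    """Set profile anchor points per label.

    promoter — TSS (already set); enhancer — midpoint of the widest
    overlapping NDR; insulator — midpoint of the leftmost overlapping CTCF
    motif; ndr_nofeat — own midpoint. Enhancers without an NDR and
    insulators without a motif fall back to the interval midpoint and are
    flagged. Centers falling outside the element (possible for partially
    overlapping NDRs/motifs) are clamped to the interval.
    """
    motif_index = IntervalIndex(list(ctcf_motifs))
    ndr_index = IntervalIndex(list(ndrs))
    out: list[RegElement] = []
    for el in elements:
        if el.label == "enhancer":
            hits = ndr_index.overlapping(el.interval)
            if hits:
                widest = max(
                    (ndr_index.intervals[h] for h in hits),
                    key=lambda iv: (iv.width, -iv.start),
                )
                center = _clamp(widest.midpoint, el.interval)
                out.append(replace(el, center=center, center_fallback=False))
            else:
                out.append(
                    replace(el, center=el.interval.midpoint, center_fallback=True)
                )
        elif el.label == "insulator":
            hits = motif_index.overlapping(el.interval)
            if hits:
                leftmost = min(
                    (motif_index.intervals[h] for h in hits),
                    key=lambda iv: (iv.start, iv.end),
                )
                center = _clamp(leftmost.midpoint, el.interval)
                out.append(replace(el, center=center, center_fallback=False))
            else:
                out.append(
                    replace(el, center=el.interval.midpoint, center_fallback=True)
                )
        else:
            out.append(el)
    n_fallback = sum(1 for e in out if e.center_fallback)
    if n_fallback:
        logger.info("element_centers: %d elements used midpoint fallback", n_fallback)
    return out


def _clamp(pos: int, iv: GenomicInterval) -> int:
    return min(max(pos, iv.start), iv.end - 1)
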