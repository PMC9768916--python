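"""Sequencing-depth saturation analysis and promoter-capture probe bookkeeping.

Saturation subsamples a contact map by binomial thinning, re-runs a loop
caller at each depth tier, and reports the loop-count curve plus the first
depth where the relative gain to the next tier drops below a threshold
(default 5%; saturation needs an operational rule, and this is the
package's). Depth is measured in contact counts as a proxy for read
pairs; the valid-pair-to-contact conversion of real libraries is out of
scope and this proxy is stated on every output.

In capture mode the recorded depth is the *captured* depth — the counts in
pixels touching a bait — because a capture library only sequences
bait-overlapping fragments. This is what lets a bait-restricted experiment
reach its plateau with far fewer sequenced reads than a genome-wide one on
the same material.

Probe design mirrors the capture panel arithmetic: four 120 bp probes per
TSS at strand-aware offsets -1 kb, -0.5 kb, +0.5 kb, +1 kb, with identical
duplicates collapsed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .contacts import ContactMap
from .genomic_io import GenomicInterval, LoopRecord, TssRecord, union_length
from .synth import downsample_contacts

logger = logging.getLogger("loopscape")

__all__ = [
    "ProbePanel",
    "SaturationCurve",
    "PROBE_OFFSETS",
    "PROBE_SIZE",
    "design_probes",
    "reads_per_probe",
    "probe_span",
    "saturation",
    "nested_tiers",
    "plateau_of",
    "captured_depth",
]

PROBE_SIZE = 120
PROBE_OFFSETS = (-1_000, -500, 500, 1_000)


@dataclass
class ProbePanel:
    """Capture probes (each exactly 120 bp) plus collapse bookkeeping."""

    probes: list[GenomicInterval]
    n_collapsed: int = 0

    def __post_init__(self) -> None:
        for p in self.probes:
            if p.width != PROBE_SIZE:
                raise ValueError(f"probe width {p.width} != {PROBE_SIZE}")

    def __len__(self) -> int:
        return len(self.probes)


def design_probes(
    tss: Sequence[TssRecord], offsets: Sequence[int] = PROBE_OFFSETS
) -> ProbePanel:
    """Four probes per TSS, centered at strand-aware offsets, width 120 bp.

    Offsets flip sign on the minus strand (so -1 kb stays upstream).
    Identical intervals produced by nearby TSSs collapse to one probe;
    the number removed is recorded. Probes that would start before the
    chromosome origin are clipped out of the panel (counted as collapsed).
    """
    seen: set[tuple[str, int, int]] = set()
    probes: list[GenomicInterval] = []
    n_dropped = 0
    for t in tss:
        sign = 1 if t.strand == "+" else -1
        for off in offsets:
            center = t.pos + sign * off
            start = center - PROBE_SIZE // 2
            end = start + PROBE_SIZE
            if start < 0:
                n_dropped += 1
                continue
            key = (t.chrom, start, end)
            if key in seen:
                n_dropped += 1
                continue
            seen.add(key)
            probes.append(GenomicInterval(t.chrom, start, end))
    probes.sort()
    return ProbePanel(probes=probes, n_collapsed=n_dropped)


def reads_per_probe(valid_pairs: int, n_probes: int) -> int:
    """floor(valid read pairs / probes): mean on-target pairs per probe."""
    if n_probes <= 0:
        raise ValueError("n_probes must be positive")
    if valid_pairs < 0:
        raise ValueError("valid_pairs must be >= 0")
    return valid_pairs // n_probes


def probe_span(panel: ProbePanel) -> int:
    """Total genomic span of the panel (union of probe intervals)."""
    return union_length(panel.probes) if panel.probes else 0


@dataclass
class SaturationCurve:
    """(depth, loop count) points sorted by depth, plus the plateau call."""

    points: list[tuple[int, int]]
    plateau_depth: int | None
    epsilon: float

    def __post_init__(self) -> None:
        depths = [d for d, _ in self.points]
        if depths != sorted(depths):
            raise ValueError("saturation points must be sorted by depth")
        if any(n < 0 for _, n in self.points):
            raise ValueError("loop counts must be >= 0")


def captured_depth(cmap: ContactMap, baits: Sequence[GenomicInterval]) -> int:
    """Contacts with at least one bin overlapping a bait interval."""
    from .genomic_io import IntervalIndex

    n, res = cmap.n_bins, cmap.binsize
    index = IntervalIndex(list(baits))
    on_bait = np.array(
        [
            index.any_overlap(GenomicInterval(cmap.chrom, b * res, (b + 1) * res))
            for b in range(n)
        ]
    )
    coo = cmap.upper.tocoo()
    keep = on_bait[coo.row] | on_bait[coo.col]
    return int(coo.data[keep].sum())


def _relative_gain(n_cur: int, n_next: int) -> float:
    if n_cur == 0:
        return 0.0 if n_next == 0 else float("inf")
    return (n_next - n_cur) / n_cur


def nested_tiers(
    cmap: ContactMap, fractions: Sequence[float], seed: int = 0
) -> list[ContactMap]:
    """Nested binomial thinnings of a map, one per ascending fraction.

    Tier k is a sub-draw of tier k+1 (the last tier at fraction 1.0 is the
    map itself), mirroring a titration that combines sequencing libraries
    cumulatively.
    """
    fr = list(fractions)
    if not fr or any(not (0 < f <= 1) for f in fr) or fr != sorted(fr):
        raise ValueError("fractions must be ascending values in (0, 1]")
    tiers: list[ContactMap] = []
    cur, cur_f = cmap, 1.0
    for k, f in reversed(list(enumerate(fr))):
        cur = downsample_contacts(cur, f / cur_f, rng=np.random.default_rng([seed, k]))
        cur_f = f
        tiers.append(cur)
    tiers.reverse()
    return tiers


def plateau_of(points: Sequence[tuple[int, int]], epsilon: float) -> int | None:
    """First depth whose relative gain to the next point is below epsilon."""
    for (d1, n1), (_, n2) in zip(points, points[1:]):
        if _relative_gain(n1, n2) < epsilon:
            return d1
    return None


def saturation(
    cmap: ContactMap,
    fractions: Sequence[float],
    caller: Callable[[ContactMap], list[LoopRecord]],
    seed: int = 0,
    epsilon: float = 0.05,
    baits: Sequence[GenomicInterval] | None = None,
) -> SaturationCurve:
    """Loop counts across a ladder of subsampled depths.

    Depth tiers are *nested*: the reads at a lower fraction are a binomial
    sub-draw of the next tier up, mirroring a titration that combines
    sequencing libraries cumulatively (tier k is a subset of tier k+1).
    ``caller`` runs on each tier and (depth, n_loops) is recorded; when
    ``baits`` is given, depth is the captured depth (see module
    docstring). The plateau is the smallest depth whose relative gain to
    the next tier is below ``epsilon``; None when the curve never flattens
    before its last point.
    """
    fr = list(fractions)
    tiers = nested_tiers(cmap, fr, seed)
    points: list[tuple[int, int]] = []
    for f, sub in zip(fr, tiers):
        try:
            n_loops = len(caller(sub))
        except Exception as exc:
            raise RuntimeError(f"loop caller failed at fraction {f}") from exc
        depth = captured_depth(sub, baits) if baits is not None else sub.total()
        points.append((depth, n_loops))
    points.sort(key=lambda dn: dn[0])
    plateau = plateau_of(points, epsilon)
    return SaturationCurve(points=points, plateau_depth=plateau, epsilon=epsilon)
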