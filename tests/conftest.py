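"""Shared fixtures and independent brute-force oracles for the test suite."""

from __future__ import annotations

import pytest

import loopscape as L
from loopscape.genomic_io import GenomicInterval, TssRecord


# ---------------------------------------------------------------------------
# brute-force oracles (O(n^2) pairwise overlap; independent of the package's
# sorted-array index machinery)
# ---------------------------------------------------------------------------


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def brute_force_classify(
    promoters, k27ac, ctcf, ndrs, k27me3, k9me3, tss
) -> dict[str, int]:
    """Label multiset from a direct pairwise re-statement of the hierarchy."""
    tssw = [
        GenomicInterval(t.chrom, max(0, t.pos - 2000), t.pos + 2000) for t in tss
    ]
    prom_iv = [p.interval for p in promoters]
    enh = [p for p in k27ac if not any(overlaps(p, w) for w in tssw)]
    ins = [
        p
        for p in ctcf
        if not any(overlaps(p, w) for w in tssw)
        and not any(overlaps(p, e) for e in enh)
    ]
    active = prom_iv + enh + ins
    ndr = [p for p in ndrs if not any(overlaps(p, a) for a in active)]
    rep = [p for p in k27me3 if not any(overlaps(p, a) for a in active)]
    het = [
        p
        for p in k9me3
        if not any(overlaps(p, a) for a in active + rep)
    ]
    return {
        "promoter": len(prom_iv),
        "enhancer": len(enh),
        "insulator": len(ins),
        "ndr_nofeat": len(ndr),
        "repressed": len(rep),
        "heterochromatin": len(het),
    }


def brute_force_anchor_label(anchor, elements, window):
    """Priority/overlap/leftmost tie-break restated directly."""
    from loopscape.elements import PRIORITY_RANK

    expanded = GenomicInterval(
        anchor.chrom, max(0, anchor.start - window), anchor.end + window
    )
    hits = [e for e in elements if overlaps(expanded, e.interval)]
    if not hits:
        return "none", None
    best = min(
        hits,
        key=lambda e: (
            PRIORITY_RANK[e.label],
            -(min(expanded.end, e.interval.end) - max(expanded.start, e.interval.start)),
            e.interval.start,
            e.interval.end,
        ),
    )
    return best.label, best.source_id


# ---------------------------------------------------------------------------
# synthetic-scene fixtures
# ---------------------------------------------------------------------------


def make_scene(
    seed: int,
    chrom_size: int = 6_000_000,
    n_tss: int = 160,
    n_peaks: int = 80,
    depth: int = 2_000_000,
    n_loops: int = 30,
    **cfg_kw,
):
    """Genome + peaks + classified elements for one seed."""
    cfg = L.SynthConfig(
        seed=seed,
        chrom_sizes={"chrS": chrom_size},
        n_tss=n_tss,
        depth=depth,
        n_loops=n_loops,
        **cfg_kw,
    )
    sizes, tss = L.generate_genome(cfg)
    peaks = {
        m: L.generate_peaks(sizes, m, cfg, tss, n_peaks=n_peaks)
        for m in ("H3K27ac", "CTCF", "H3K27me3", "H3K9me3", "NDR")
    }
    promoters = L.active_promoters(tss, chrom_sizes=sizes)
    elements = L.classify_elements(
        promoters,
        peaks["H3K27ac"],
        peaks["CTCF"],
        peaks["NDR"],
        peaks["H3K27me3"],
        peaks["H3K9me3"],
        tss,
    )
    return cfg, sizes, tss, peaks, elements


@pytest.fixture(scope="session")
def scene():
    return make_scene(seed=42)


def random_intervals(rng, n, chrom="chr1", max_pos=1_000_000, max_len=5_000):
    out = []
    for _ in range(n):
        s = int(rng.integers(0, max_pos))
        w = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, s, s + w))
    return out


def make_tss(chrom="chr1", pos=100_000, strand="+", gene="g1", fpkm=(1.0,)):
    return TssRecord(chrom=chrom, pos=pos, strand=strand, gene_id=gene, fpkm=fpkm)
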