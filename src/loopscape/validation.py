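"""Self-contained validation experiments for the whole pipeline.

Each experiment builds its inputs from the synthetic generator at a fixed
seed, runs the relevant pipeline stage, and measures recovery of the
planted structure. They are the package's benchmark suite: scaled-down,
single-chromosome study conditions (a few Mb of genome, millions of
contacts) chosen so each experiment runs in seconds while preserving the
statistical structure the methods assume.

All seeds are small integers; sub-streams are derived per experiment.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np

from . import annotate as ann
from . import elements as el
from . import loops as lp
from . import profiles as pr
from . import synth as sy
from . import tads as td
from . import titration as ti
from .genomic_io import LoopRecord

__all__ = [
    "build_scene",
    "loop_recovery",
    "category_ranking",
    "null_false_calls",
    "tad_recovery",
    "saturation_comparison",
    "profile_effects",
]

RESOLUTION = 10_000


def build_scene(
    seed: int,
    chrom_size: int = 6_000_000,
    n_tss: int = 160,
    n_peaks: int = 80,
    depth: int = 2_500_000,
    n_loops: int = 35,
    **cfg_kw,
):
    """Genome, peaks, classified elements and a config, all from one seed."""
    cfg = sy.SynthConfig(
        seed=seed,
        chrom_sizes={"chrS": chrom_size},
        n_tss=n_tss,
        depth=depth,
        n_loops=n_loops,
        **cfg_kw,
    )
    sizes, tss = sy.generate_genome(cfg)
    peaks = {
        m: sy.generate_peaks(sizes, m, cfg, tss, n_peaks=n_peaks)
        for m in sy.MARKS
    }
    promoters = el.active_promoters(tss, chrom_sizes=sizes)
    elements = el.classify_elements(
        promoters,
        peaks["H3K27ac"],
        peaks["CTCF"],
        peaks["NDR"],
        peaks["H3K27me3"],
        peaks["H3K9me3"],
        tss,
    )
    return cfg, sizes, tss, peaks, elements


def _match_sets(true_loops, calls, res: int = RESOLUTION, tol: int = 1):
    truth = {
        (t.anchor1.midpoint // res, t.anchor2.midpoint // res) for t in true_loops
    }

    def hits(c):
        bi, bj = c.anchor1.start // res, c.anchor2.start // res
        return [
            (ti_, tj_)
            for ti_, tj_ in truth
            if abs(bi - ti_) <= tol and abs(bj - tj_) <= tol
        ]

    tp = sum(1 for c in calls if hits(c))
    recovered = set()
    for c in calls:
        recovered.update(hits(c))
    return tp, recovered, truth


def loop_recovery(seed: int) -> dict:
    """Recall/precision of the donut caller against planted fold-6 loops.

    Conditions: one 6 Mb chromosome at 10 kb bins, 35 planted loops at the
    default fold of 6, depth giving ~10 counts per pixel at typical loop
    distances ("adequate depth"), ±1 bin anchor matching.
    """
    cfg, sizes, tss, peaks, elements = build_scene(seed)
    true_loops = sy.plant_loops(elements, cfg)
    tads = sy.generate_tads("chrS", cfg)
    cmap = sy.simulate_contact_map("chrS", RESOLUTION, tads, true_loops, cfg)
    calls = lp.call_loops(cmap, lp.LoopCallParams(resolution=RESOLUTION))
    tp, recovered, truth = _match_sets(true_loops, calls)
    return {
        "n_true": len(truth),
        "n_called": len(calls),
        "recall": len(recovered) / len(truth),
        "precision": tp / len(calls) if calls else 0.0,
    }


def category_ranking(seed: int, n_loops: int = 1_500) -> dict:
    """Does the annotated loop-category ranking recover the planted ranking?

    Plants ``n_loops`` loops with the default category weights on a 20 Mb
    scene, annotates them with the ±2 kb fuzzy window (1 kb-resolution
    convention), and compares the top-3 of the ranked table with the top-3
    planted weights.
    """
    cfg, _, _, _, elements = build_scene(
        seed, chrom_size=20_000_000, n_tss=400, n_peaks=250
    )
    true_loops = sy.plant_loops(elements, cfg, n_loops=n_loops)
    recs = [LoopRecord.make(t.anchor1, t.anchor2, 1_000) for t in true_loops]
    cat = ann.categorize_loops(recs, elements, window=2_000)
    planted = sorted(cfg.loop_category_weights.items(), key=lambda kv: -kv[1])
    planted_top3 = [f"{a}-{b}" for (a, b), _ in planted[:3]]
    empirical_top3 = list(cat.table["category"][:3])
    return {
        "top3_exact": empirical_top3 == planted_top3,
        "empirical_top3": empirical_top3,
        "planted_top3": planted_top3,
    }


def null_false_calls(seed: int) -> int:
    """Loop calls on a map with distance decay but no planted structure."""
    cfg = sy.SynthConfig(
        seed=seed,
        chrom_sizes={"chrS": 4_000_000},
        n_tss=0,
        depth=1_000_000,
        loop_category_weights={},
    )
    cmap = sy.simulate_contact_map("chrS", RESOLUTION, [], sy.TrueLoopSet([]), cfg)
    return len(lp.call_loops(cmap, lp.LoopCallParams(resolution=RESOLUTION)))


def tad_recovery(seed: int) -> dict:
    """Boundary recall and mean error against planted ~450 kb domains.

    Conditions: 20 Mb at 50 kb bins, domain fold 3, window 5, depth chosen
    so near-diagonal pixels carry well over 10 counts.
    """
    binsize = 50_000
    cfg = sy.SynthConfig(
        seed=seed,
        chrom_sizes={"chrS": 20_000_000},
        n_tss=0,
        depth=800_000,
        loop_category_weights={},
        tad_fold=3.0,
    )
    tads = sy.generate_tads("chrS", cfg, binsize)
    cmap = sy.simulate_contact_map("chrS", binsize, tads, sy.TrueLoopSet([]), cfg)
    called = td.call_tads(cmap, w=5)
    true_bounds = [t.end // binsize for t in tads[:-1]]
    called_bounds = called.boundary_bins()
    dists = [
        min((abs(b - c) for c in called_bounds), default=10**9) for b in true_bounds
    ]
    matched = [d for d in dists if d <= 3]
    return {
        "recall": float(np.mean([d <= 1 for d in dists])) if dists else 0.0,
        "mean_error_bins": float(np.mean(matched)) if matched else float("inf"),
        "n_true_boundaries": len(true_bounds),
    }


def saturation_comparison(
    seed: int, fractions: Sequence[float] = (0.05, 0.1, 0.2, 0.4, 0.7, 1.0)
) -> dict:
    """Depth titration, genome-wide vs promoter-capture, on one loops-only map.

    The map carries planted loops but no TAD blocks (domain corner dots
    would otherwise keep crossing the significance threshold as depth grows
    and mask the loop-count plateau). Reports, per mode: the total-count
    curve and its plateau depth, and whether the planted-loop recovery
    count is non-decreasing across the nested tiers.
    """
    cfg, sizes, tss, peaks, elements = build_scene(
        seed, depth=6_000_000, n_tss=160, n_loops=30
    )
    true_loops = sy.plant_loops(elements, cfg)
    cmap = sy.simulate_contact_map("chrS", RESOLUTION, [], true_loops, cfg)
    params = lp.LoopCallParams(resolution=RESOLUTION)
    baits = [e.interval for e in elements if e.label == "promoter"]

    def recovered_count(calls):
        _, recovered, _ = _match_sets(true_loops, calls)
        return len(recovered)

    tiers = ti.nested_tiers(cmap, list(fractions), seed=seed)
    out = {}
    for mode in ("global", "capture"):
        points, rec_counts = [], []
        for sub in tiers:
            if mode == "global":
                calls = lp.call_loops(sub, params)
                depth = sub.total()
            else:
                calls = lp.capture_score(sub, baits, params)
                depth = ti.captured_depth(sub, baits)
            points.append((depth, len(calls)))
            rec_counts.append(recovered_count(calls))
        out[mode] = {
            "points": points,
            "plateau_depth": ti.plateau_of(points, epsilon=0.05),
            "recovery_counts": rec_counts,
            "recovery_monotone": rec_counts == sorted(rec_counts),
        }
    g, c = out["global"]["plateau_depth"], out["capture"]["plateau_depth"]
    out["capture_plateau_smaller"] = (
        g is not None and c is not None and c < g
    )
    return out


def profile_effects(seed: int, null: bool = False) -> dict:
    """Sign recovery of the in-loop signal contrasts (or their absence).

    Builds a small scene, assigns half the elements to the in-loop group at
    random, simulates MNase/accessibility/methylation tracks, and compares
    groups. With ``null=True`` every in-loop contrast is switched off, so
    the group tests should come out non-significant.
    """
    sig = sy.SignalParams()
    if null:
        sig = replace(
            sig,
            dip_depth_in=sig.dip_depth_out,
            phasing_amp_in=sig.phasing_amp_out,
            accessibility_effect=0.0,
            methylation_effect=0.0,
        )
    cfg, sizes, tss, peaks, elements = build_scene(
        seed, chrom_size=4_000_000, n_tss=120, n_peaks=60, signal=sig
    )
    rng = np.random.default_rng([seed, 9_001])
    flags = rng.random(len(elements)) < 0.5
    tracks = sy.simulate_signal_tracks(elements, flags, cfg)
    centers = [(e.chrom, e.center) for e in elements]
    labels = [e.label for e in elements]
    out = {}
    mnase_comp = None
    for name in ("mnase", "accessibility", "methylation"):
        pm = pr.profile(
            tracks[name], centers, in_loop=flags, labels=labels
        )
        comp = pr.compare_groups(pm)
        out[name] = {"effect": comp.effect, "p_value": comp.p_value}
        if name == "mnase":
            mnase_comp = comp
            offsets = pm.offsets
    out["phasing_in"] = pr.phasing_score(mnase_comp.mean_in, offsets)
    out["phasing_out"] = pr.phasing_score(mnase_comp.mean_out, offsets)
    out["signs_recovered"] = (
        out["mnase"]["effect"] < 0
        and out["accessibility"]["effect"] > 0
        and out["methylation"]["effect"] < 0
        and out["phasing_in"] > out["phasing_out"]
    )
    out["null_nonsignificant"] = (
        out["accessibility"]["p_value"] > 0.05
        and out["methylation"]["p_value"] > 0.05
    )
    return out
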