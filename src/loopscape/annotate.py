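"""Loop-anchor annotation, loop categories, in-loop fractions, shared loops.

A loop anchor is annotated by fuzzy overlap against the classified element
sets: the anchor is expanded by a resolution-keyed window (±2 kb for 1 kb
loops, ±10 kb for 5 kb loops) and, among intersecting elements, the label
highest in the priority order promoter > enhancer > insulator > NDR-without-
features > repressed > heterochromatin wins; no intersection gives "none".
The window expands the *anchor*, not the element — the expansion exists to
tolerate interactions that fall one bin away from the element.

A loop category is the unordered pair of its two anchor labels,
canonicalized by priority rank; over 7 labels there are exactly
C(7,2) + 7 = 28 categories.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

from .elements import PRIORITY_RANK, RegElement
from .genomic_io import GenomicInterval, IntervalIndex, LoopRecord, TssRecord

logger = logging.getLogger("loopscape")

__all__ = [
    "ALL_LABELS",
    "MATCH_WINDOWS",
    "AnchorLabel",
    "all_categories",
    "window_for_resolution",
    "annotate_anchor",
    "categorize_loops",
    "CategorizedLoops",
    "in_loop_fraction",
    "element_loop_flags",
    "shared_loops",
    "expression_by_category",
]

ALL_LABELS = (
    "promoter",
    "enhancer",
    "insulator",
    "ndr_nofeat",
    "repressed",
    "heterochromatin",
    "none",
)

# resolution (bp) -> fuzzy-join half-width (bp)
MATCH_WINDOWS: dict[int, int] = {1_000: 2_000, 5_000: 10_000}


def window_for_resolution(resolution: int) -> int:
    """±window used to expand anchors; 2x the resolution when not tabulated."""
    return MATCH_WINDOWS.get(resolution, 2 * resolution)


def all_categories() -> list[tuple[str, str]]:
    """The 28 canonical unordered label pairs (priority-ranked order)."""
    cats = [
        (a, b)
        for a, b in itertools.combinations_with_replacement(ALL_LABELS, 2)
    ]
    assert len(cats) == 28
    return cats


def canonical_category(lab1: str, lab2: str) -> tuple[str, str]:
    pair = sorted((lab1, lab2), key=lambda lab: PRIORITY_RANK[lab])
    return (pair[0], pair[1])


@dataclass(frozen=True)
class AnchorLabel:
    """Priority-winning label of one loop anchor plus the matched element."""

    label: str
    element_id: str | None = None

    def __post_init__(self) -> None:
        if self.label not in ALL_LABELS:
            raise ValueError(f"unknown anchor label {self.label!r}")
        if (self.label == "none") != (self.element_id is None):
            raise ValueError('"none" exactly when no element matched')


class ElementIndex:
    """Overlap index retaining the RegElement objects."""

    def __init__(self, elements: Sequence[RegElement]):
        self.elements = list(elements)
        self._index = IntervalIndex([e.interval for e in self.elements])

    def overlapping(self, query: GenomicInterval) -> list[RegElement]:
        return [self.elements[i] for i in self._index.overlapping(query)]


def _overlap_len(a: GenomicInterval, b: GenomicInterval) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _annotate(
    anchor: GenomicInterval, index: ElementIndex, window: int
) -> AnchorLabel:
    expanded = anchor.expanded(window)
    hits = index.overlapping(expanded)
    if not hits:
        return AnchorLabel("none", None)
    best = min(
        hits,
        key=lambda el: (
            PRIORITY_RANK[el.label],
            -_overlap_len(expanded, el.interval),
            el.interval.start,
            el.interval.end,
        ),
    )
    return AnchorLabel(best.label, best.source_id)


@dataclass
class CategorizedLoops:
    """Per-loop anchor labels, category map, and the ranked count table."""

    loops: list[LoopRecord]
    anchor_labels: list[tuple[AnchorLabel, AnchorLabel]]
    by_category: dict[tuple[str, str], list[LoopRecord]]
    table: pd.DataFrame  # columns: category, count; sorted desc, canonical ties

    def category_of(self, i: int) -> tuple[str, str]:
        a, b = self.anchor_labels[i]
        return canonical_category(a.label, b.label)


def categorize_loops(
    loops: Sequence[LoopRecord],
    elements: Sequence[RegElement],
    window: int | None = None,
) -> CategorizedLoops:
    """Annotate both anchors of every loop and tabulate category counts.

    The table is sorted by descending count; ties follow canonical category
    order. The count total always equals the number of loops.
    """
    loops = list(loops)
    if window is None:
        window = window_for_resolution(loops[0].resolution) if loops else 0
    index = ElementIndex(elements)
    anchor_labels = []
    by_cat: dict[tuple[str, str], list[LoopRecord]] = {}
    for lp in loops:
        la = _annotate(lp.anchor1, index, window)
        lb = _annotate(lp.anchor2, index, window)
        anchor_labels.append((la, lb))
        by_cat.setdefault(canonical_category(la.label, lb.label), []).append(lp)
    order = {cat: i for i, cat in enumerate(all_categories())}
    rows = sorted(
        ((cat, len(lps)) for cat, lps in by_cat.items()),
        key=lambda kv: (-kv[1], order[kv[0]]),
    )
    table = pd.DataFrame(
        {
            "category": [f"{a}-{b}" for (a, b), _ in rows],
            "count": [c for _, c in rows],
        }
    )
    assert int(table["count"].sum()) == len(loops)
    return CategorizedLoops(loops, anchor_labels, by_cat, table)


def annotate_anchor(
    anchor: GenomicInterval,
    elements: Sequence[RegElement],
    window: int,
) -> AnchorLabel:
    """Expand the anchor ±window; highest-priority intersecting label wins.

    Ties between same-priority elements break to the larger overlap with the
    expanded anchor, then to the leftmost element. Elements merely abutting
    the expanded anchor (shared boundary under half-open coordinates) do not
    match. Returns "none" when nothing intersects.
    """
    return _annotate(anchor, ElementIndex(elements), window)


def in_loop_fraction(
    elements: Sequence[RegElement],
    loop_sets: Mapping[str, Sequence[LoopRecord]],
    window: int | None = None,
) -> pd.DataFrame:
    """Per-label fraction of elements intersecting any expanded loop anchor.

    One column per dataset plus a "union" column (in a loop in >= 1
    dataset); the union fraction is therefore >= every per-dataset
    fraction. Rows are element labels present in the input.
    """
    if not loop_sets:
        raise ValueError("need at least one loop dataset")
    elements = list(elements)
    labels = sorted({e.label for e in elements}, key=lambda l: PRIORITY_RANK[l])
    flags: dict[str, np.ndarray] = {}
    for name, loops in loop_sets.items():
        w = window
        if w is None:
            w = window_for_resolution(loops[0].resolution) if loops else 0
        anchors = []
        for lp in loops:
            anchors.append(lp.anchor1.expanded(w))
            anchors.append(lp.anchor2.expanded(w))
        index = IntervalIndex(anchors)
        flags[name] = np.array(
            [index.any_overlap(e.interval) for e in elements], dtype=bool
        )
    union = np.logical_or.reduce(list(flags.values()))
    data = {}
    for name, fl in list(flags.items()) + [("union", union)]:
        data[name] = [
            float(np.mean([f for f, e in zip(fl, elements) if e.label == lab]))
            if any(e.label == lab for e in elements)
            else np.nan
            for lab in labels
        ]
    return pd.DataFrame(data, index=labels)


def element_loop_flags(
    elements: Sequence[RegElement],
    loops: Sequence[LoopRecord],
    window: int | None = None,
) -> np.ndarray:
    """0/1 per element: does it intersect any expanded anchor of the set?"""
    if window is None:
        window = window_for_resolution(loops[0].resolution) if loops else 0
    anchors: list[GenomicInterval] = []
    for lp in loops:
        anchors.append(lp.anchor1.expanded(window))
        anchors.append(lp.anchor2.expanded(window))
    index = IntervalIndex(anchors)
    return np.array([index.any_overlap(e.interval) for e in elements], dtype=bool)


def shared_loops(
    a: Sequence[LoopRecord],
    b: Sequence[LoopRecord],
    window: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Fuzzy-join shared flags, computed in both directions.

    A loop x in set a is shared when some loop y in b has anchor1
    overlapping x's expanded anchor1 AND anchor2 overlapping x's expanded
    anchor2 (anchors are canonically ordered, so corresponding anchors are
    compared). Because one loop can match several in the other set, the two
    directions may count different numbers of shared loops; both flag
    arrays are returned.
    """

    def flags(xs: Sequence[LoopRecord], ys: Sequence[LoopRecord]) -> np.ndarray:
        i1 = IntervalIndex([y.anchor1 for y in ys])
        out = np.zeros(len(xs), dtype=bool)
        for i, x in enumerate(xs):
            cands = i1.overlapping(x.anchor1.expanded(window))
            for c in cands:
                if ys[c].anchor2.overlaps(x.anchor2.expanded(window)):
                    out[i] = True
                    break
        return out

    return flags(a, b), flags(b, a)


def expression_by_category(
    categorized: CategorizedLoops,
    tss: Sequence[TssRecord],
    min_promoters: int = 2,
) -> tuple[dict[tuple[str, str], np.ndarray], pd.DataFrame]:
    """FPKM of promoters at loop anchors, per promoter-containing category.

    Returns the per-category mean-FPKM arrays and a symmetric matrix of
    two-sided Student's t-test p-values for every category pair. Categories
    with fewer than ``min_promoters`` promoter observations are skipped
    with a warning.
    """
    fpkm_by_gene = {t.gene_id: t.mean_fpkm for t in tss}
    values: dict[tuple[str, str], list[float]] = {}
    for i, lp in enumerate(categorized.loops):
        cat = categorized.category_of(i)
        if "promoter" not in cat:
            continue
        for al in categorized.anchor_labels[i]:
            if al.label == "promoter" and al.element_id in fpkm_by_gene:
                values.setdefault(cat, []).append(fpkm_by_gene[al.element_id])
    arrays: dict[tuple[str, str], np.ndarray] = {}
    for cat, vals in values.items():
        if len(vals) < min_promoters:
            warnings.warn(
                f"category {cat[0]}-{cat[1]} has {len(vals)} promoter values; skipped"
            )
            continue
        arrays[cat] = np.asarray(vals)
    cats = list(arrays)
    names = [f"{a}-{b}" for a, b in cats]
    pmat = pd.DataFrame(np.ones((len(cats), len(cats))), index=names, columns=names)
    for i, c1 in enumerate(cats):
        for j, c2 in enumerate(cats):
            if i < j:
                p = ttest_ind(arrays[c1], arrays[c2]).pvalue
                pmat.iloc[i, j] = pmat.iloc[j, i] = p
    return arrays, pmat
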