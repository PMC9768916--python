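"""Strict readers and writers for the on-disk formats the pipeline touches.

Coordinates are 0-based, half-open throughout (BED native convention). Every
reader rejects malformed input with the offending line number rather than
silently coercing; every writer's output re-reads to an equal in-memory value.

Formats handled here:

* BED (3+ columns) for peaks, NDRs, motifs, elements
* BEDPE (6+ columns) for loops; columns 7-9 carry dataset, score, q-value
* TSV TSS/expression tables (chrom, pos, strand, gene_id, fpkm_1..n)
* bedGraph signal tracks (values are means over the stated interval; gaps
  are missing data, not zero)
* a plain-text COO contact format (header line + ``bin_i bin_j count`` rows)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("loopscape")

__all__ = [
    "GenomicInterval",
    "LoopRecord",
    "TssRecord",
    "SignalTrack",
    "read_bed",
    "write_bed",
    "read_bedpe",
    "write_bedpe",
    "read_contacts",
    "write_contacts",
    "read_tss_table",
    "write_tss_table",
    "read_bedgraph",
    "write_bedgraph",
    "find_overlaps",
    "overlaps_any",
    "union_length",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """>=1 shared base under half-open arithmetic."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def expanded(self, pad: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, max(0, self.start - pad), self.end + pad)


@dataclass(frozen=True)
class LoopRecord:
    """A two-anchor chromatin interaction.

    Anchors are canonicalized so anchor1 is the leftmost; both lie on the
    same chromosome (trans interactions are out of scope).
    """

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    resolution: int
    score: float = 0.0
    qvalue: float | None = None
    dataset: str = ""
    bait_id: str | None = None

    def __post_init__(self) -> None:
        if self.anchor1.chrom != self.anchor2.chrom:
            raise ValueError("loop anchors must share a chromosome")
        if self.anchor1.start > self.anchor2.start:
            raise ValueError("anchor1 must precede anchor2 (canonical order)")
        if self.qvalue is not None and not (0.0 <= self.qvalue <= 1.0):
            raise ValueError(f"q-value {self.qvalue} outside [0, 1]")

    @property
    def chrom(self) -> str:
        return self.anchor1.chrom

    @property
    def distance(self) -> int:
        return abs(self.anchor2.midpoint - self.anchor1.midpoint)

    @staticmethod
    def make(
        a: GenomicInterval,
        b: GenomicInterval,
        resolution: int,
        **kw,
    ) -> "LoopRecord":
        """Build a loop with anchors put in canonical (leftmost-first) order."""
        if (b.start, b.end) < (a.start, a.end):
            a, b = b, a
        return LoopRecord(a, b, resolution, **kw)


@dataclass(frozen=True)
class TssRecord:
    """Transcription start site with per-replicate expression (FPKM)."""

    chrom: str
    pos: int
    strand: str
    gene_id: str
    fpkm: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if any(v < 0 for v in self.fpkm):
            raise ValueError(f"negative FPKM for {self.gene_id}")

    @property
    def mean_fpkm(self) -> float:
        return float(np.mean(self.fpkm)) if self.fpkm else 0.0


@dataclass
class SignalTrack:
    """Per-base numeric coverage on one chromosome; NaN marks missing data."""

    chrom: str
    values: np.ndarray  # float array, length = chromosome length

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("signal track must be one-dimensional")

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# interval overlap machinery (sorted-array sweeps; the O(n^2) oracle used in
# the test suite is the independent cross-check)
# ---------------------------------------------------------------------------


class IntervalIndex:
    """Overlap queries against a fixed interval set, grouped by chromosome."""

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self.intervals = list(intervals)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        groups: dict[str, list[int]] = {}
        for idx, iv in enumerate(self.intervals):
            groups.setdefault(iv.chrom, []).append(idx)
        for chrom, idxs in groups.items():
            starts = np.array([self.intervals[i].start for i in idxs])
            order = np.argsort(starts, kind="stable")
            idx_arr = np.array(idxs)[order]
            starts = starts[order]
            ends = np.array([self.intervals[i].end for i in idx_arr])
            # prefix max of ends supports fast "any overlap" existence tests
            self._by_chrom[chrom] = (starts, ends, idx_arr)

    def overlapping(self, query: GenomicInterval) -> list[int]:
        """Indices (into the original list) of intervals overlapping query."""
        entry = self._by_chrom.get(query.chrom)
        if entry is None:
            return []
        starts, ends, idx_arr = entry
        hi = int(np.searchsorted(starts, query.end, side="left"))
        hits = np.nonzero(ends[:hi] > query.start)[0]
        return [int(idx_arr[h]) for h in hits]

    def any_overlap(self, query: GenomicInterval) -> bool:
        entry = self._by_chrom.get(query.chrom)
        if entry is None:
            return False
        starts, ends, _ = entry
        hi = int(np.searchsorted(starts, query.end, side="left"))
        return bool(hi > 0 and np.max(ends[:hi]) > query.start)


def find_overlaps(
    query: GenomicInterval, targets: Sequence[GenomicInterval]
) -> list[int]:
    """Indices of ``targets`` sharing >=1 base with ``query``."""
    return IntervalIndex(targets).overlapping(query)


def overlaps_any(
    queries: Sequence[GenomicInterval], targets: Sequence[GenomicInterval]
) -> np.ndarray:
    """Boolean array: does each query overlap at least one target?"""
    index = IntervalIndex(targets)
    return np.array([index.any_overlap(q) for q in queries], dtype=bool)


def union_length(intervals: Iterable[GenomicInterval]) -> int:
    """Total genomic span covered by the union of the intervals."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    total = 0
    for spans in by_chrom.values():
        spans.sort()
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total += cur_e - cur_s
    return total


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a 3+ column BED file into intervals.

    Malformed lines raise :class:`FormatError` with the line number.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 columns")
            chrom, s, e = fields[0], fields[1], fields[2]
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinates {s!r}/{e!r}"
                ) from exc
            try:
                out.append(GenomicInterval(chrom, start, end))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    extra_columns: Sequence[Sequence] | None = None,
) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            row = [iv.chrom, str(iv.start), str(iv.end)]
            if extra_columns is not None:
                row.extend(str(x) for x in extra_columns[i])
            fh.write("\t".join(row) + "\n")
    logger.info("wrote %d intervals to %s", len(intervals), path)


# ---------------------------------------------------------------------------
# BEDPE
# ---------------------------------------------------------------------------

_BEDPE_HEADER = (
    "#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tdataset\tscore\tqvalue\tresolution"
)


def read_bedpe(path: str | Path) -> list[LoopRecord]:
    """Read loops from BEDPE; anchors are canonicalized leftmost-first.

    Interchromosomal rows are excluded (trans interactions are out of scope);
    their count is logged.
    """
    loops: list[LoopRecord] = []
    n_trans = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected >=6 columns")
            try:
                a = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                b = GenomicInterval(fields[3], int(fields[4]), int(fields[5]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if a.chrom != b.chrom:
                n_trans += 1
                continue
            dataset = fields[6] if len(fields) > 6 else ""
            score = float(fields[7]) if len(fields) > 7 and fields[7] != "." else 0.0
            qvalue = (
                float(fields[8]) if len(fields) > 8 and fields[8] != "." else None
            )
            resolution = (
                int(fields[9]) if len(fields) > 9 and fields[9] != "." else a.width
            )
            loops.append(
                LoopRecord.make(
                    a, b, resolution, score=score, qvalue=qvalue, dataset=dataset
                )
            )
    if n_trans:
        logger.warning("%s: excluded %d interchromosomal rows", path, n_trans)
    return loops


def write_bedpe(loops: Sequence[LoopRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_BEDPE_HEADER + "\n")
        for lp in loops:
            q = "." if lp.qvalue is None else repr(lp.qvalue)
            fh.write(
                "\t".join(
                    [
                        lp.anchor1.chrom,
                        str(lp.anchor1.start),
                        str(lp.anchor1.end),
                        lp.anchor2.chrom,
                        str(lp.anchor2.start),
                        str(lp.anchor2.end),
                        lp.dataset,
                        repr(lp.score),
                        q,
                        str(lp.resolution),
                    ]
                )
                + "\n"
            )
    logger.info("wrote %d loops to %s", len(loops), path)


# ---------------------------------------------------------------------------
# contact COO text
# ---------------------------------------------------------------------------


def read_contacts(path: str | Path):
    """Read the plain-text COO contact format into a ContactMap.

    Layout: one header line ``chrom<TAB>binsize<TAB>n_bins`` followed by rows
    ``bin_i<TAB>bin_j<TAB>count`` with ``i <= j`` (upper triangle). Duplicate
    (i, j) entries are summed (and logged); bins out of range are rejected.
    """
    from .contacts import ContactMap  # local import: avoids a module cycle

    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        parts = header.lstrip("#").split("\t")
        if len(parts) != 3:
            raise FormatError(f"{path}:1: header must be 'chrom binsize n_bins'")
        chrom = parts[0]
        try:
            binsize, n_bins = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise FormatError(f"{path}:1: non-integer header fields") from exc
        if binsize <= 0 or n_bins <= 0:
            raise FormatError(f"{path}:1: binsize and n_bins must be positive")
        rows, cols, vals = [], [], []
        seen: set[tuple[int, int]] = set()
        n_dup = 0
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(f"{path}:{lineno}: expected 'bin_i bin_j count'")
            try:
                i, j, c = int(fields[0]), int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer entry") from exc
            if i > j:
                raise FormatError(f"{path}:{lineno}: require bin_i <= bin_j")
            if not (0 <= i < n_bins and 0 <= j < n_bins):
                raise FormatError(f"{path}:{lineno}: bin out of range [0,{n_bins})")
            if c < 0:
                raise FormatError(f"{path}:{lineno}: negative count")
            if (i, j) in seen:
                n_dup += 1
            seen.add((i, j))
            rows.append(i)
            cols.append(j)
            vals.append(c)
    if n_dup:
        logger.info("%s: summed %d duplicate pixel entries", path, n_dup)
    return ContactMap.from_coo(chrom, binsize, n_bins, rows, cols, vals)


def write_contacts(cmap, path: str | Path) -> None:
    coo = cmap.upper.tocoo()
    with open(path, "w") as fh:
        fh.write(f"{cmap.chrom}\t{cmap.binsize}\t{cmap.n_bins}\n")
        order = np.lexsort((coo.col, coo.row))
        for i, j, c in zip(coo.row[order], coo.col[order], coo.data[order]):
            if c:
                fh.write(f"{i}\t{j}\t{int(c)}\n")
    logger.info("wrote contact map (%s, %d bins) to %s", cmap.chrom, cmap.n_bins, path)


# ---------------------------------------------------------------------------
# TSS / expression TSV
# ---------------------------------------------------------------------------


def read_tss_table(path: str | Path) -> list[TssRecord]:
    """TSV with columns: chrom, pos, strand, gene_id, fpkm_1..fpkm_n."""
    out: list[TssRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise FormatError(f"{path}:{lineno}: expected >=5 columns")
            try:
                rec = TssRecord(
                    chrom=fields[0],
                    pos=int(fields[1]),
                    strand=fields[2],
                    gene_id=fields[3],
                    fpkm=tuple(float(v) for v in fields[4:]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            out.append(rec)
    return out


def write_tss_table(records: Sequence[TssRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    [r.chrom, str(r.pos), r.strand, r.gene_id]
                    + [repr(v) for v in r.fpkm]
                )
                + "\n"
            )
    logger.info("wrote %d TSS records to %s", len(records), path)


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------


def read_bedgraph(
    path: str | Path, chrom_sizes: dict[str, int]
) -> dict[str, SignalTrack]:
    """Read a bedGraph into per-chromosome tracks.

    Interval values are means over the stated span; uncovered bases stay NaN
    (missing, not zero).
    """
    tracks = {
        chrom: SignalTrack(chrom, np.full(size, np.nan))
        for chrom, size in chrom_sizes.items()
    }
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            chrom = fields[0]
            if chrom not in tracks:
                raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad coordinates/value") from exc
            if not (0 <= start < end <= chrom_sizes[chrom]):
                raise FormatError(f"{path}:{lineno}: span outside chromosome")
            tracks[chrom].values[start:end] = value
    return tracks


def write_bedgraph(tracks: dict[str, SignalTrack], path: str | Path) -> None:
    """Write tracks run-length encoded; NaN runs (missing data) are omitted."""
    with open(path, "w") as fh:
        for chrom in sorted(tracks):
            vals = tracks[chrom].values
            n = len(vals)
            if n == 0:
                continue
            # run boundaries: value change or NaN-status change
            same = (vals[1:] == vals[:-1]) | (np.isnan(vals[1:]) & np.isnan(vals[:-1]))
            starts = np.concatenate([[0], np.flatnonzero(~same) + 1])
            ends = np.concatenate([starts[1:], [n]])
            for s, e in zip(starts, ends):
                v = vals[s]
                if np.isnan(v):
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{float(v)!r}\n")
    logger.info("wrote bedGraph to %s", path)
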