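"""Binned contact-matrix model: coarsening, expected-by-distance, O/E, pileups.

A :class:`ContactMap` is a symmetric intrachromosomal count matrix stored as
its upper triangle (diagonal included). One stored entry is one contact
event, so the sum of the stored counts is the map's sequencing depth.

Observed/expected (O/E) normalization divides each pixel by the mean count at
its genomic distance, removing the power-law distance decay so that punctate
loop enrichment and domain structure stand out. Explicit matrix balancing
(ICE/KR) is deliberately omitted: simulated maps carry no systematic bin
bias. For real data this is a documented limitation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .genomic_io import LoopRecord

__all__ = [
    "ContactMap",
    "ExpectedProfile",
    "coarsen",
    "expected_by_distance",
    "observed_over_expected",
    "pileup",
]


class ContactMap:
    """Symmetric binned contact matrix for one chromosome.

    Parameters
    ----------
    chrom : chromosome name
    binsize : bin width in bp (> 0)
    upper : scipy sparse matrix holding the upper triangle (i <= j) of the
        symmetric count matrix; entries are non-negative integers.
    """

    def __init__(self, chrom: str, binsize: int, upper: sp.spmatrix):
        if binsize <= 0:
            raise ValueError("binsize must be positive")
        upper = sp.csr_matrix(upper)
        if upper.shape[0] != upper.shape[1]:
            raise ValueError("contact matrix must be square")
        if sp.tril(upper, k=-1).count_nonzero():
            raise ValueError("counts must be stored in the upper triangle (i <= j)")
        if upper.count_nonzero() and upper.data.min() < 0:
            raise ValueError("contact counts must be non-negative")
        self.chrom = chrom
        self.binsize = int(binsize)
        self.upper = upper

    @property
    def n_bins(self) -> int:
        return self.upper.shape[0]

    def total(self) -> int:
        """Total contact events (sum of stored upper-triangle counts)."""
        return int(self.upper.sum())

    def dense(self) -> np.ndarray:
        """Full symmetric matrix as a dense float array."""
        u = self.upper.toarray().astype(np.float64)
        return u + u.T - np.diag(np.diag(u))

    @classmethod
    def from_dense_upper(cls, chrom: str, binsize: int, upper: np.ndarray):
        """Build from a dense array whose lower triangle is ignored."""
        u = np.triu(np.asarray(upper))
        return cls(chrom, binsize, sp.csr_matrix(u))

    @classmethod
    def from_coo(
        cls,
        chrom: str,
        binsize: int,
        n_bins: int,
        rows: Sequence[int],
        cols: Sequence[int],
        vals: Sequence[int],
    ):
        m = sp.coo_matrix(
            (np.asarray(vals, dtype=np.int64), (rows, cols)), shape=(n_bins, n_bins)
        )
        m.sum_duplicates()
        return cls(chrom, binsize, m.tocsr())

    def bin_of(self, pos: int) -> int:
        return int(pos // self.binsize)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ContactMap)
            and self.chrom == other.chrom
            and self.binsize == other.binsize
            and self.n_bins == other.n_bins
            and (self.upper != other.upper).nnz == 0
        )


@dataclass
class ExpectedProfile:
    """Mean count per diagonal offset d = 0 .. n_bins-1 of the full matrix."""

    binsize: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < 0):
            raise ValueError("expected profile values must be >= 0")


def coarsen(cmap: ContactMap, factor: int) -> ContactMap:
    """Sum counts into ``factor``-times-larger bins; total count is conserved.

    Operates on the stored upper triangle, so off-diagonal stored entries
    aggregate into coarse diagonal blocks without double-counting events.
    """
    if factor <= 0:
        raise ValueError("coarsening factor must be a positive integer")
    if factor == 1:
        return ContactMap(cmap.chrom, cmap.binsize, cmap.upper.copy())
    n_new = -(-cmap.n_bins // factor)  # ceil division
    coo = cmap.upper.tocoo()
    rows = coo.row // factor
    cols = coo.col // factor
    return ContactMap.from_coo(
        cmap.chrom, cmap.binsize * factor, n_new, rows, cols, coo.data
    )


def expected_by_distance(cmap: ContactMap) -> ExpectedProfile:
    """Mean pixel value of the full symmetric matrix at each diagonal offset."""
    n = cmap.n_bins
    if n == 0:
        raise ValueError("empty contact map")
    coo = cmap.upper.tocoo()
    offs = coo.col - coo.row
    sums = np.bincount(offs, weights=coo.data.astype(np.float64), minlength=n)
    n_pixels = n - np.arange(n)  # pixels per off-diagonal of the full matrix
    return ExpectedProfile(cmap.binsize, sums / n_pixels)


def observed_over_expected(
    cmap: ContactMap, expected: ExpectedProfile | None = None
) -> np.ndarray:
    """Dense full-matrix ratio observed / expected[distance].

    Diagonals whose expected value is 0 get ratio 0 (flagged via a log-free
    convention: a zero row of expectation carries no information).
    """
    if expected is None:
        expected = expected_by_distance(cmap)
    n = cmap.n_bins
    obs = cmap.dense()
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    exp_mat = expected.values[d]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(exp_mat > 0, obs / np.where(exp_mat > 0, exp_mat, 1.0), 0.0)
    return ratio


def pileup(
    cmap: ContactMap,
    loops: Sequence[LoopRecord],
    flank: int = 100_000,
    pile_binsize: int = 1_000,
) -> np.ndarray:
    """Mean O/E submatrix stacked over loop anchor pairs.

    Submatrices are centered on the (anchor1, anchor2) midpoints and span
    ``±flank`` at ``pile_binsize`` resolution (defaults: 100 kb window, 1 kb
    bins). Loops whose window would cross the matrix edge are skipped, not
    padded — padding would bias the mean. Returns the (2k+1) x (2k+1) mean
    matrix where k = flank // pile_binsize.
    """
    if not loops:
        raise ValueError("no loops supplied for pileup")
    if flank % pile_binsize != 0:
        raise ValueError("flank must be a multiple of pile_binsize")
    if pile_binsize % cmap.binsize != 0:
        raise ValueError("pile_binsize must be a multiple of the map binsize")
    work = coarsen(cmap, pile_binsize // cmap.binsize)
    oe = observed_over_expected(work)
    n = work.n_bins
    half = flank // pile_binsize
    acc = np.zeros((2 * half + 1, 2 * half + 1))
    used = 0
    skipped = 0
    for lp in loops:
        if lp.chrom != work.chrom:
            skipped += 1
            continue
        bi = lp.anchor1.midpoint // pile_binsize
        bj = lp.anchor2.midpoint // pile_binsize
        if bi - half < 0 or bj - half < 0 or bi + half >= n or bj + half >= n:
            skipped += 1
            continue
        acc += oe[bi - half : bi + half + 1, bj - half : bj + half + 1]
        used += 1
    if used == 0:
        raise ValueError(f"no usable loops for pileup ({skipped} skipped)")
    return acc / used
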