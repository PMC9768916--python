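"""Signal aggregation around element centers; in-loop vs not-in-loop tests.

A profile matrix has one row per element and one column per position offset
(default ±2 kb around the center at 10 bp steps). Promoter rows are
strand-flipped so downstream of the TSS is always the positive axis.
Group comparisons reduce each row to a scalar (mean over a central ±250 bp
summary window) and apply a two-sided Student's t-test, matching the
in-loop vs not-in-loop testing of accessibility/methylation levels; the
equal-size resampling (10 draws of a fixed n per element class) controls
for group-size imbalance.

Nucleosome phasing is quantified as the autocovariance of the detrended
flank signal at one nucleosome period (default 190 bp) — a pure cosine of
amplitude A scores approximately A^2 / 2, white noise approximately 0. The
published comparison is visual with a single p-value; this score is this
package's operationalization of it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import ttest_ind

from .genomic_io import SignalTrack

logger = logging.getLogger("loopscape")

__all__ = [
    "ProfileMatrix",
    "GroupComparison",
    "profile",
    "compare_groups",
    "balanced_resample",
    "phasing_score",
]


@dataclass
class ProfileMatrix:
    """Element-by-position signal matrix with group flags.

    values[r, c] = mean track signal over the 10 bp (= step) window at
    offset offsets[c] from element r's center. in_loop flags the group of
    each row; labels carries each row's element class (used by the
    balanced resampler).
    """

    values: np.ndarray  # (n_rows, n_cols)
    offsets: np.ndarray  # (n_cols,) left edge of each step window, bp
    in_loop: np.ndarray  # (n_rows,) bool
    labels: np.ndarray  # (n_rows,) str
    flank: int
    step: int

    def __post_init__(self) -> None:
        n_cols = 2 * self.flank // self.step + 1
        if self.values.shape[1] != n_cols:
            raise ValueError(
                f"expected {n_cols} columns for flank {self.flank} step {self.step}"
            )
        if not (
            len(self.in_loop) == len(self.labels) == self.values.shape[0]
        ):
            raise ValueError("row metadata must align with the matrix")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def subset(self, rows: np.ndarray) -> "ProfileMatrix":
        return ProfileMatrix(
            self.values[rows],
            self.offsets,
            self.in_loop[rows],
            self.labels[rows],
            self.flank,
            self.step,
        )


def profile(
    tracks: SignalTrack | Mapping[str, SignalTrack],
    centers: Sequence[tuple[str, int]],
    flank: int = 2_000,
    step: int = 10,
    strands: Sequence[str] | None = None,
    in_loop: Sequence[bool] | None = None,
    labels: Sequence[str] | None = None,
) -> ProfileMatrix:
    """Aggregate a track around (chrom, center) anchor points.

    Column c covers [center + offsets[c], center + offsets[c] + step) with
    offsets from -flank to +flank; NaN bases are excluded from window
    means. Minus-strand rows are mirrored so downstream is positive.
    Centers whose window leaves the chromosome are skipped (and counted in
    the log). Raises on an empty center list.
    """
    if len(centers) == 0:
        raise ValueError("no centers supplied")
    if flank % step != 0:
        raise ValueError("flank must be a multiple of step")
    track_map = (
        {tracks.chrom: tracks} if isinstance(tracks, SignalTrack) else dict(tracks)
    )
    n_cols = 2 * flank // step + 1
    offsets = -flank + step * np.arange(n_cols)
    rows = []
    keep_idx = []
    skipped = 0
    for r, (chrom, center) in enumerate(centers):
        track = track_map.get(chrom)
        if track is None:
            skipped += 1
            continue
        lo, hi = center - flank, center + flank + step
        if lo < 0 or hi > len(track.values):
            skipped += 1
            continue
        window = track.values[lo:hi].reshape(n_cols, step)
        with np.errstate(invalid="ignore"):
            row = np.nanmean(window, axis=1)
        if strands is not None and strands[r] == "-":
            row = row[::-1]
        rows.append(row)
        keep_idx.append(r)
    if skipped:
        logger.info("profile: skipped %d out-of-bounds centers", skipped)
    if not rows:
        raise ValueError("all centers were out of bounds")
    keep = np.array(keep_idx)
    return ProfileMatrix(
        values=np.vstack(rows),
        offsets=offsets,
        in_loop=(
            np.asarray(in_loop, dtype=bool)[keep]
            if in_loop is not None
            else np.zeros(len(keep), dtype=bool)
        ),
        labels=(
            np.asarray(labels, dtype=object)[keep]
            if labels is not None
            else np.array(["element"] * len(keep), dtype=object)
        ),
        flank=flank,
        step=step,
    )


@dataclass
class GroupComparison:
    mean_in: np.ndarray
    mean_out: np.ndarray
    scalars_in: np.ndarray
    scalars_out: np.ndarray
    effect: float  # mean(in) - mean(out) of the summary scalars
    t_stat: float
    p_value: float


def compare_groups(
    pm: ProfileMatrix, summary_half_width: int = 250
) -> GroupComparison:
    """In-loop vs not-in-loop mean curves and a t-test on central levels.

    The per-element scalar is the mean signal over the central
    ±summary_half_width bp; the test is a two-sided Student's t-test on
    those scalars.
    """
    for name, mask in (("in loop", pm.in_loop), ("not in loop", ~pm.in_loop)):
        if not mask.any():
            raise ValueError(f"group {name!r} is empty")
    central = np.abs(pm.offsets) <= summary_half_width
    with np.errstate(invalid="ignore"):
        scalars = np.nanmean(pm.values[:, central], axis=1)
        mean_in = np.nanmean(pm.values[pm.in_loop], axis=0)
        mean_out = np.nanmean(pm.values[~pm.in_loop], axis=0)
    s_in = scalars[pm.in_loop]
    s_out = scalars[~pm.in_loop]
    res = ttest_ind(s_in, s_out)
    return GroupComparison(
        mean_in=mean_in,
        mean_out=mean_out,
        scalars_in=s_in,
        scalars_out=s_out,
        effect=float(np.nanmean(s_in) - np.nanmean(s_out)),
        t_stat=float(res.statistic),
        p_value=float(res.pvalue),
    )


def balanced_resample(
    pm: ProfileMatrix,
    n_per_class: Mapping[str, int],
    repeats: int = 10,
    seed: int | None = None,
) -> list[ProfileMatrix]:
    """Equal-size draws per (label, group), repeated ``repeats`` times.

    For each element class, each repeat samples ``n_per_class[label]`` rows
    without replacement from the in-loop rows and the same number from the
    not-in-loop rows; a group smaller than the request contributes all of
    its rows (with a log warning). Mirrors the 10x equal-size selection
    used to remove group-size effects.
    """
    for lab, n in n_per_class.items():
        if n <= 0:
            raise ValueError(f"n for class {lab!r} must be positive")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(repeats):
        take: list[np.ndarray] = []
        for lab, n in n_per_class.items():
            for group_mask in (pm.in_loop, ~pm.in_loop):
                rows = np.nonzero((pm.labels == lab) & group_mask)[0]
                if len(rows) == 0:
                    continue
                if len(rows) < n:
                    logger.warning(
                        "balanced_resample: class %r group has %d < %d rows; "
                        "taking all",
                        lab,
                        len(rows),
                        n,
                    )
                    take.append(rows)
                else:
                    take.append(rng.choice(rows, size=n, replace=False))
        idx = np.sort(np.concatenate(take)) if take else np.array([], dtype=int)
        out.append(pm.subset(idx))
    return out


def phasing_score(
    curve: np.ndarray,
    offsets: np.ndarray,
    period: float = 190.0,
    step: int | None = None,
    exclude_center: int = 300,
) -> float:
    """Autocovariance of the detrended flank signal at one nucleosome period.

    Both flanks (|offset| >= exclude_center, which drops the central dip)
    are linearly detrended and their lag-``period`` autocovariances
    averaged. Requires each flank to cover at least two periods.
    """
    offsets = np.asarray(offsets)
    if step is None:
        step = int(offsets[1] - offsets[0])
    lag = int(round(period / step))
    scores = []
    for side_mask in (offsets <= -exclude_center, offsets >= exclude_center):
        x = np.asarray(curve)[side_mask]
        span = len(x) * step
        if span < 2 * period or lag >= len(x):
            raise ValueError(
                f"flank spans {span} bp; need >= 2 periods ({2 * period:.0f} bp)"
            )
        t = np.arange(len(x))
        good = np.isfinite(x)
        coef = np.polyfit(t[good], x[good], 1)
        resid = x - np.polyval(coef, t)
        a, b = resid[:-lag], resid[lag:]
        ok = np.isfinite(a) & np.isfinite(b)
        scores.append(float(np.mean(a[ok] * b[ok])))
    return float(np.mean(scores))
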