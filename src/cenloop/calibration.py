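"""Spike-in calibrated ChIP-seq quantification.

The calibration uses a two-species spike-in design: target-species cells
(S. cerevisiae) are mixed with a fixed proportion of spike-in cells
(C. glabrata) before chromatin immunoprecipitation, so that cross-species
read-count ratios report *absolute* changes in target occupancy that a
conventional ChIP/input ratio cannot see.

Definitions
-----------
Occupancy ratio
    ``OR = (ChIP_Scer * input_Cgla) / (input_Scer * ChIP_Cgla)`` where each
    term is the number of non-redundant reads of that fraction mapped to
    that genome.  OR is invariant to the sequencing depth of either
    fraction.

Normalization factor
    ``NF = OR_treated / OR_control`` against a declared control sample;
    NF of the control against itself is 1 by construction.

Normalized fold-enrichment (nFE)
    The binned ChIP vector is rescaled so its genome-wide total equals
    ``1,500,000 * NF``; the input vector is rescaled to total 1,500,000;
    nFE per bin is the ratio of the two scaled vectors.  Bins whose raw
    input coverage falls below ``min_input_reads`` are masked rather than
    smoothed — no pseudocounts are fabricated at uncovered bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from intervaltree import IntervalTree
from scipy import ndimage, stats

from .core import BinnedTrack, GenomicInterval

#: Genome-wide scaled ChIP total for NF = 1; the input track uses the same
#: constant symmetrically.
CHIP_SCALE = 1_500_000.0


@dataclass(frozen=True)
class ReadCounts:
    """Non-redundant mapped read totals per fraction per genome."""

    chip_target: float
    chip_spike: float
    input_target: float
    input_spike: float

    def __post_init__(self) -> None:
        for f in ("chip_target", "chip_spike", "input_target", "input_spike"):
            if getattr(self, f) < 0:
                raise ValueError(f"negative read count: {f}")


@dataclass(frozen=True)
class CalibrationResult:
    or_value: float
    nf: float

    @property
    def scaled_total(self) -> float:
        return CHIP_SCALE * self.nf


def occupancy_ratio(counts: ReadCounts) -> float:
    """Cross-species occupancy ratio of one ChIP experiment.

    Raises on zero denominators rather than returning infinity.
    """
    if counts.input_target <= 0 or counts.chip_spike <= 0:
        raise ValueError(
            "occupancy_ratio requires input_target > 0 and chip_spike > 0"
        )
    return (counts.chip_target * counts.input_spike) / (
        counts.input_target * counts.chip_spike
    )


def normalization_factor(or_treated: float, or_control: float) -> float:
    if or_treated <= 0 or or_control <= 0:
        raise ValueError("occupancy ratios must be positive")
    return or_treated / or_control


def nfe_track(
    chip: BinnedTrack,
    input_: BinnedTrack,
    nf: float,
    min_input_reads: float = 1.0,
    smooth_bins: int = 0,
) -> BinnedTrack:
    """Normalized fold-enrichment track from raw binned ChIP and input.

    The output is invariant to uniform rescaling of either raw vector
    (depth independence) and exactly linear in ``nf``.  ``smooth_bins``
    applies an optional boxcar to both scaled vectors before the ratio
    (default off).
    """
    if nf <= 0:
        raise ValueError("nf must be positive")
    if not chip.same_grid(input_):
        raise ValueError("chip and input tracks are on different bin grids")
    chip_total = chip.total()
    input_total = input_.total()
    if chip_total <= 0 or input_total <= 0:
        raise ValueError("cannot scale a track with zero total")
    values: dict[str, np.ndarray] = {}
    mask: dict[str, np.ndarray] = {}
    for chrom in chip.values:
        sc = chip.values[chrom] * (CHIP_SCALE * nf / chip_total)
        si = input_.values[chrom] * (CHIP_SCALE / input_total)
        if smooth_bins > 1:
            sc = ndimage.uniform_filter1d(sc, smooth_bins, mode="nearest")
            si = ndimage.uniform_filter1d(si, smooth_bins, mode="nearest")
        m = (
            chip.mask[chrom]
            | input_.mask[chrom]
            | (input_.values[chrom] < min_input_reads)
            | (si <= 0)
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            v = np.where(m, 0.0, sc / np.where(si > 0, si, 1.0))
        values[chrom] = v
        mask[chrom] = m
    return BinnedTrack(bin_size=chip.bin_size, values=values, mask=mask, semantics="nFE")


@dataclass(frozen=True)
class Peak:
    """A thresholded enrichment region with its summit."""

    interval: GenomicInterval
    summit: int
    max_nfe: float
    mean_nfe: float

    def __post_init__(self) -> None:
        if not self.interval.start <= self.summit < self.interval.end:
            raise ValueError("summit outside peak interval")


def call_peaks(
    track: BinnedTrack,
    threshold: float = 2.0,
    min_width_bins: int = 1,
    merge_gap_bins: int = 0,
) -> list[Peak]:
    """Threshold peak calling on an nFE track.

    Peaks are maximal runs of unmasked bins with nFE >= ``threshold``; runs
    separated by at most ``merge_gap_bins`` bins are merged; merged runs
    shorter than ``min_width_bins`` are dropped.  The summit is the center
    of the maximum-nFE bin, leftmost on ties.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    bs = track.bin_size
    peaks: list[Peak] = []
    for chrom in track.values:
        v = track.values[chrom]
        m = track.mask[chrom]
        above = (~m) & (v >= threshold)
        if not above.any():
            continue
        padded = np.concatenate([[False], above, [False]]).astype(int)
        d = np.diff(padded)
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)  # half-open bin runs
        merged: list[list[int]] = [[int(starts[0]), int(ends[0])]]
        for s, e in zip(starts[1:], ends[1:]):
            if s - merged[-1][1] <= merge_gap_bins:
                merged[-1][1] = int(e)
            else:
                merged.append([int(s), int(e)])
        for s, e in merged:
            if e - s < min_width_bins:
                continue
            run_vals = np.where(m[s:e], -np.inf, v[s:e])
            best = int(np.argmax(run_vals))  # argmax is leftmost on ties
            unmasked = v[s:e][~m[s:e]]
            start_bp = s * bs
            end_bp = e * bs
            summit = (s + best) * bs + bs // 2
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, start_bp, end_bp),
                    summit=min(summit, end_bp - 1),
                    max_nfe=float(run_vals[best]),
                    mean_nfe=float(unmasked.mean()),
                )
            )
    return peaks


def peak_overlap_fraction(peaks_a: list[Peak], peaks_b: list[Peak]) -> float:
    """Fraction of peaks in A intersecting >= 1 bp of any peak in B.

    Asymmetric by design.  NaN if A is empty.
    """
    if not peaks_a:
        return float("nan")
    trees: dict[str, IntervalTree] = {}
    for p in peaks_b:
        trees.setdefault(p.interval.chrom, IntervalTree()).addi(
            p.interval.start, p.interval.end
        )
    hit = 0
    for p in peaks_a:
        tree = trees.get(p.interval.chrom)
        if tree is not None and tree.overlap(p.interval.start, p.interval.end):
            hit += 1
    return hit / len(peaks_a)


def track_correlation(
    track_a: BinnedTrack,
    track_b: BinnedTrack,
    at: list[GenomicInterval] | None = None,
    window: int = 400,
) -> float:
    """Spearman rank correlation of two tracks.

    Over jointly unmasked bins, or over per-site window-mean nFE values when
    a site list is given.  Average ranks on ties.
    """
    if at is not None:
        from .sites import quantify_at_sites

        a = quantify_at_sites(track_a, at, window=window)
        b = quantify_at_sites(track_b, at, window=window)
        ok = ~(np.isnan(a) | np.isnan(b))
        a, b = a[ok], b[ok]
    else:
        if not track_a.same_grid(track_b):
            raise ValueError("tracks are on different bin grids")
        chunks_a, chunks_b = [], []
        for chrom in track_a.values:
            ok = ~(track_a.mask[chrom] | track_b.mask[chrom])
            chunks_a.append(track_a.values[chrom][ok])
            chunks_b.append(track_b.values[chrom][ok])
        a = np.concatenate(chunks_a)
        b = np.concatenate(chunks_b)
    if len(a) < 3:
        raise ValueError("fewer than 3 paired unmasked values")
    rho, _ = stats.spearmanr(a, b)
    return float(rho)
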