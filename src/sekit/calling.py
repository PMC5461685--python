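"""Superenhancer calling: stitch, score, rank, threshold.

The procedure follows the classic ROSE recipe with an automatic cutoff:

1. *Stitch* — within each chromosome, consecutive peaks whose gap
   (next start minus previous end) is strictly less than the stitch
   distance (12.5 kb by default) are merged transitively into one region.
2. *Score* — each stitched region receives the cumulative read-base
   signal over its support: with raw reads, the summed overlap length in
   bp of every read with the region; with a pileup track, the area under
   the track inside the region.
3. *Rank* — regions are sorted by descending count; rank 1 is the
   strongest region. Ties fall back to genomic order.
4. *Threshold* — both count and rank are scaled to [0, 1]; on the
   ascending curve the discrete slope closest to 1 (the 45-degree
   tangent of the hockey stick) marks the SE/TE boundary. Regions
   ranked at or above the boundary are superenhancers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .algebra import SignalTrack
from .errors import DegenerateInputError, UsageError
from .intervals import GenomicInterval, Peak, Read, StitchedEnhancer

DEFAULT_STITCH_DISTANCE = 12_500


@dataclass
class RankCurve:
    """The scaled count-vs-rank curve and the chosen SE cutoff.

    ``scaled_rank``/``scaled_count`` are in descending-rank order (rank 1
    first); ``theta`` is the number of regions flagged SE.
    """

    scaled_rank: np.ndarray
    scaled_count: np.ndarray
    theta: int


def stitch_peaks(peaks: list[Peak], distance: int = DEFAULT_STITCH_DISTANCE) -> list[StitchedEnhancer]:
    """Merge peaks closer than ``distance`` bp into stitched regions.

    Input order is irrelevant (a stable internal sort is applied);
    stitching never crosses chromosomes, and a gap exactly equal to the
    threshold does *not* stitch.
    """
    if distance < 0:
        raise UsageError(f"stitch distance must be >= 0, got {distance}")
    ordered = sorted(peaks, key=lambda p: p.interval)
    out: list[StitchedEnhancer] = []
    group: list[Peak] = []
    for peak in ordered:
        if group and (
            peak.interval.chrom == group[-1].interval.chrom
            and peak.interval.start - group[-1].interval.end < distance
        ):
            group.append(peak)
        else:
            if group:
                out.append(_finish_group(group))
            group = [peak]
    if group:
        out.append(_finish_group(group))
    return out


def _finish_group(group: list[Peak]) -> StitchedEnhancer:
    interval = GenomicInterval(
        group[0].interval.chrom, group[0].interval.start, max(p.interval.end for p in group)
    )
    return StitchedEnhancer(interval=interval, subpeaks=list(group))


def score_stitched(
    region: StitchedEnhancer,
    reads: list[Read] | None = None,
    track: SignalTrack | None = None,
) -> float:
    """Cumulative signal over the stitched support.

    Exactly one of ``reads``/``track`` must be given. With reads the
    score counts, over all reads, every read base that falls inside the
    region; with a track it is the area under the pileup in the region.
    """
    if (reads is None) == (track is None):
        raise UsageError("supply exactly one of reads or track")
    if track is not None:
        return track.area(region.interval)
    return float(sum(read.interval.overlap_length(region.interval) for read in reads))


def rank_stitched(regions: list[StitchedEnhancer]) -> list[StitchedEnhancer]:
    """Sort by descending count and assign ranks 1..n.

    Equal counts are ordered genomically (chrom, start ascending) so the
    ranking is deterministic.
    """
    ordered = sorted(regions, key=lambda r: (-r.count, r.interval))
    for i, region in enumerate(ordered, start=1):
        region.rank = i
    return ordered


def find_threshold(counts: np.ndarray, smooth_window: int = 1) -> int:
    """SE cutoff from the 45-degree tangent of the scaled score curve.

    ``counts`` must be in descending-rank order. Both axes are scaled to
    [0, 1]; on the ascending curve the forward-difference slope
    ``s_i = (y[i+1] - y[i]) / (x[i+1] - x[i])`` is scanned and the
    segment whose slope is nearest 1 fixes the boundary. The returned
    theta is the count of regions (by descending rank) flagged SE; ties
    in ``|s - 1|`` resolve toward fewer SEs.

    ``smooth_window`` (odd) optionally applies a moving average to the
    slopes before the scan; the default of 1 means no smoothing.

    Fewer than 3 regions cannot support a tangent: a warning is issued
    and 0 is returned (everything TE). A constant curve has no
    inflection and raises :class:`DegenerateInputError`.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.size
    if n < 3:
        warnings.warn(f"only {n} stitched regions; flagging all as typical enhancers")
        return 0
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise UsageError(f"smooth_window must be a positive odd integer, got {smooth_window}")
    ascending = counts[::-1]
    lo, hi = ascending[0], ascending[-1]
    if hi == lo:
        raise DegenerateInputError("constant counts: no inflection point exists")
    y = (ascending - lo) / (hi - lo)
    x = np.arange(n) / (n - 1)
    slopes = np.diff(y) / np.diff(x)
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        slopes = np.convolve(slopes, kernel, mode="same")
    deviation = np.abs(slopes - 1.0)
    # ties toward fewer SEs = larger ascending index; scan from the top
    best = deviation.size - 1 - int(np.argmin(deviation[::-1]))
    # slope segment `best` spans ascending indices [best, best+1]; the
    # upper point is the weakest SE, at descending rank n - (best + 1) + 1
    return n - best - 1


def apply_threshold(ranked: list[StitchedEnhancer], theta: int) -> None:
    """Flag the top ``theta`` ranks as SE (in place)."""
    for region in ranked:
        region.is_se = region.rank <= theta


def rank_curve(ranked: list[StitchedEnhancer], theta: int) -> RankCurve:
    counts = np.array([r.count for r in ranked], dtype=float)
    n = counts.size
    ranks = np.arange(1, n + 1, dtype=float)
    scaled_rank = (ranks - 1) / (n - 1) if n > 1 else np.zeros(n)
    span = counts.max() - counts.min()
    scaled_count = (counts - counts.min()) / span if span > 0 else np.zeros(n)
    return RankCurve(scaled_rank=scaled_rank, scaled_count=scaled_count, theta=theta)


def call_superenhancers(
    peaks: list[Peak],
    reads: list[Read] | None = None,
    track: SignalTrack | None = None,
    distance: int = DEFAULT_STITCH_DISTANCE,
    smooth_window: int = 1,
) -> tuple[list[StitchedEnhancer], RankCurve | None]:
    """Full deterministic pipeline: stitch, score, rank, threshold, flag.

    When both reads and a combined-signal track are supplied the track
    wins (it is the refined signal) and the reads are ignored with a
    warning. Returns the ranked regions and the rank curve (None when
    the peak set is empty).
    """
    if track is not None and reads is not None:
        warnings.warn("both reads and track supplied; scoring from the track")
        reads = None
    regions = stitch_peaks(peaks, distance=distance)
    if not regions:
        return [], None
    for region in regions:
        region.count = score_stitched(region, reads=reads, track=track)
    ranked = rank_stitched(regions)
    counts = np.array([r.count for r in ranked])
    try:
        theta = find_threshold(counts, smooth_window=smooth_window)
    except DegenerateInputError:
        warnings.warn("constant scores: no SE/TE boundary; flagging all as TE")
        theta = 0
    apply_threshold(ranked, theta)
    return ranked, rank_curve(ranked, theta)
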