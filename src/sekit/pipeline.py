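"""End-to-end composition: peaks + signal -> ranked, annotated SE table.

Stitching and scoring are embarrassingly parallel per chromosome, so
they run through the generic scheduler (cyclic chunks of chromosomes);
ranking, thresholding and annotation are global and always serial. The
output table is identical for any worker count.
"""

from __future__ import annotations

import pandas as pd

from . import annotation as ann
from .algebra import SignalTrack
from .calling import (
    DEFAULT_STITCH_DISTANCE,
    RankCurve,
    apply_threshold,
    find_threshold,
    rank_curve,
    rank_stitched,
    score_stitched,
    stitch_peaks,
)
from .chromstats import closeness_all
from .errors import DegenerateInputError
from .intervals import GeneModel, Peak, Read, StitchedEnhancer
from .io import SE_TABLE_COLUMNS
from .scheduler import ResourceSpec, cyclic_partition, n_processes, parallel_map

import numpy as np
import warnings


def _stitch_score_chrom(chunk: list[tuple[list[Peak], list[Read] | None, list | None, int]]):
    """Per-chromosome stitch + score; the parallel task body."""
    out = []
    for peaks, reads, track_rows, distance in chunk:
        regions = stitch_peaks(peaks, distance=distance)
        track = SignalTrack(track_rows) if track_rows is not None else None
        for region in regions:
            region.count = score_stitched(region, reads=reads, track=track)
        out.append(regions)
    return out


def call_pipeline(
    peaks: list[Peak],
    reads: list[Read] | None = None,
    track: SignalTrack | None = None,
    genes: list[GeneModel] | None = None,
    distance: int = DEFAULT_STITCH_DISTANCE,
    tss_window: int = ann.DEFAULT_TSS_WINDOW,
    proximal_window: int = ann.DEFAULT_PROXIMAL_WINDOW,
    smooth_window: int = 1,
    resources: ResourceSpec | None = None,
) -> tuple[pd.DataFrame, list[StitchedEnhancer], RankCurve | None]:
    """Run stitch -> score -> rank -> threshold -> annotate.

    With ``resources`` given, per-chromosome work is dealt cyclically
    across ``n_processes`` workers; otherwise it runs serially. Both
    paths produce the same table.
    """
    if track is not None and reads is not None:
        warnings.warn("both reads and track supplied; scoring from the track")
        reads = None
    if not peaks:
        return pd.DataFrame(columns=SE_TABLE_COLUMNS), [], None

    by_chrom: dict[str, list[Peak]] = {}
    for peak in sorted(peaks, key=lambda p: p.interval):
        by_chrom.setdefault(peak.interval.chrom, []).append(peak)
    reads_by_chrom: dict[str, list[Read]] = {}
    for read in reads or []:
        reads_by_chrom.setdefault(read.interval.chrom, []).append(read)

    elements = []
    for chrom in sorted(by_chrom):
        track_rows = (
            [(chrom, s, e, v) for s, e, v in track.segments(chrom)] if track is not None else None
        )
        elements.append(
            (by_chrom[chrom], reads_by_chrom.get(chrom, []) if track is None else None,
             track_rows, distance)
        )

    k = n_processes(resources, len(elements)) if resources is not None else 1
    chunks = cyclic_partition(elements, k)
    per_chrom_regions = parallel_map(_stitch_score_chrom, chunks)
    regions = [r for group in per_chrom_regions for r in group]

    ranked = rank_stitched(regions)
    counts = np.array([r.count for r in ranked])
    try:
        theta = find_threshold(counts, smooth_window=smooth_window)
    except DegenerateInputError:
        warnings.warn("constant scores: no SE/TE boundary; flagging all as TE")
        theta = 0
    apply_threshold(ranked, theta)
    curve = rank_curve(ranked, theta)

    closeness_by_rank = {
        rec.se_id: rec.closeness for rec in closeness_all([r for r in ranked if r.is_se])
    }
    rows = []
    for region in ranked:
        a = ann.annotate(region, genes or [], tss_window=tss_window,
                         proximal_window=proximal_window)
        rows.append(
            {
                "rank": region.rank,
                "chrom": region.chrom,
                "start": region.interval.start,
                "end": region.interval.end,
                "n_subpeaks": region.n_subpeaks,
                "count": region.count,
                "is_SE": region.is_se,
                "closest_gene": a.closest_gene,
                "tss_distance": a.tss_distance if a.tss_distance is not None else "NA",
                "enhancer_type": a.enhancer_type,
                "percentage_outs": round(a.percentage_outs, 2),
                "closeness": closeness_by_rank.get(region.rank, "NA")
                if region.is_se
                else "NA",
            }
        )
    table = pd.DataFrame(rows, columns=SE_TABLE_COLUMNS)
    return table, ranked, curve


def subpeak_table(regions: list[StitchedEnhancer]) -> pd.DataFrame:
    """Tidy frame of all subpeaks (rank, is_SE, chrom, start, end, pileup)."""
    rows = []
    for region in regions:
        for peak in region.subpeaks:
            rows.append(
                {
                    "rank": region.rank,
                    "is_SE": region.is_se,
                    "chrom": peak.interval.chrom,
                    "start": peak.interval.start,
                    "end": peak.interval.end,
                    "pileup": peak.pileup,
                }
            )
    return pd.DataFrame(rows, columns=["rank", "is_SE", "chrom", "start", "end", "pileup"])
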