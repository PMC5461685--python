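"""Static SVG rendering: chromosomal ideograms and per-SE profile shots.

All output is plain hand-assembled SVG so a rerun on identical inputs
yields identical bytes. Each SE marker on a chromosomal plot is an
anchor linking to its row in the SE table page.
"""

from __future__ import annotations

import math

import numpy as np

from .algebra import SignalTrack
from .chromstats import ClosenessRecord, rank_percentile_bins
from .errors import UsageError
from .intervals import GenomicInterval, StitchedEnhancer

NEAR_PAD_FRACTION = 0.5  # each side, of the SE width
FAR_WIDTH_FACTOR = 10  # total window width, in SE widths


def snapshot_windows(
    se: GenomicInterval, chrom_size: int | None = None
) -> tuple[GenomicInterval, GenomicInterval]:
    """(near, far) windows for profile snapshots of one SE.

    Near: the SE padded by half its width on each side (morphology).
    Far: the SE centered in a window ten times its width (context).
    Both are clipped to [0, chrom_size).
    """
    width = len(se)
    near_lo = se.start - int(NEAR_PAD_FRACTION * width)
    near_hi = se.end + int(NEAR_PAD_FRACTION * width)
    center = (se.start + se.end) // 2
    far_lo = center - (FAR_WIDTH_FACTOR * width) // 2
    far_hi = far_lo + FAR_WIDTH_FACTOR * width

    def clip(lo: int, hi: int) -> GenomicInterval:
        lo = max(0, lo)
        if chrom_size is not None:
            hi = min(hi, chrom_size)
        hi = max(hi, lo + 1)
        return GenomicInterval(se.chrom, lo, hi)

    return clip(near_lo, near_hi), clip(far_lo, far_hi)


def _hue_color(fraction: float, hue_lo: float = 0.0, hue_hi: float = 270.0) -> str:
    """Linear hue ramp; 0 -> red, 1 -> violet by default."""
    hue = hue_lo + (hue_hi - hue_lo) * min(max(fraction, 0.0), 1.0)
    return f"hsl({hue:.0f},85%,45%)"


def closeness_color(value: int | None, lo: int, hi: int) -> str:
    """Log-scaled red (close) to violet (far); NA is grey."""
    if value is None:
        return "#999999"
    lo, hi = max(lo, 1), max(hi, 2)
    f = (math.log10(max(value, 1)) - math.log10(lo)) / (math.log10(hi) - math.log10(lo) or 1.0)
    return _hue_color(f)


def profile_svg(
    se: StitchedEnhancer,
    track: SignalTrack,
    window: GenomicInterval,
    width: int = 640,
    height: int = 160,
) -> str:
    """Pileup profile over a window, with SE and subpeak support bars.

    The pileup is drawn as a filled step curve; a black bar marks the SE
    support and alternating-colour bars below it mark each subpeak.
    """
    span = len(window)
    segs = [
        (max(s, window.start), min(e, window.end), v)
        for s, e, v in track.segments(window.chrom)
        if e > window.start and s < window.end
    ]
    vmax = max((v for _, _, v in segs), default=1.0)
    plot_h = height - 40

    def x(pos: int) -> float:
        return (pos - window.start) / span * width

    def y(value: float) -> float:
        return plot_h - value / vmax * (plot_h - 10)

    pts = [f"{x(window.start):.1f},{plot_h:.1f}"]
    for s, e, v in segs:
        pts.append(f"{x(s):.1f},{plot_h:.1f}")
        pts.append(f"{x(s):.1f},{y(v):.1f}")
        pts.append(f"{x(e):.1f},{y(v):.1f}")
        pts.append(f"{x(e):.1f},{plot_h:.1f}")
    pts.append(f"{x(window.end):.1f},{plot_h:.1f}")
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}" '
        f'viewBox="0 0 {width} {height}">',
        f'<rect width="{width}" height="{height}" fill="white"/>',
        f'<polygon points="{" ".join(pts)}" fill="#4878b0" stroke="#2a5080" stroke-width="0.5"/>',
        f'<rect x="{x(se.interval.start):.1f}" y="{plot_h + 6}" '
        f'width="{max(x(se.interval.end) - x(se.interval.start), 1):.1f}" height="6" fill="black"/>',
    ]
    for i, peak in enumerate(se.subpeaks):
        color = "#d95f02" if i % 2 == 0 else "#1b9e77"
        x0, x1 = x(max(peak.interval.start, window.start)), x(min(peak.interval.end, window.end))
        if x1 > x0:
            parts.append(
                f'<rect x="{x0:.1f}" y="{plot_h + 16}" width="{max(x1 - x0, 1):.1f}" '
                f'height="6" fill="{color}"/>'
            )
    parts.append(
        f'<text x="4" y="{height - 4}" font-size="10" font-family="sans-serif">'
        f"{window.chrom}:{window.start + 1}-{window.end}</text>"
    )
    parts.append("</svg>")
    return "\n".join(parts)


def render_chromosomal_plot(
    ses: list[StitchedEnhancer],
    mode: str,
    chrom_sizes: dict[str, int],
    enrichment_marks: dict[str, str] | None = None,
    closeness_records: list[ClosenessRecord] | None = None,
    bins: int = 10,
    width: int = 900,
) -> str:
    """Karyotype-style SVG: one lane per chromosome, one marker per SE.

    ``mode`` selects the colouring: ``enrichment`` (per-chromosome
    significance glyphs beside the label), ``rank`` (percentile bins) or
    ``closeness`` (log red-to-violet distance scale, grey for NA). Every
    marker links to its SE-table row anchor.
    """
    if mode not in ("enrichment", "rank", "closeness"):
        raise UsageError(f"unknown chromosomal plot mode {mode!r}")
    se_only = sorted((s for s in ses if s.is_se), key=lambda s: s.interval)
    lane_h, pad_left = 34, 90
    chroms = sorted(chrom_sizes)
    height = lane_h * len(chroms) + 20
    max_size = max(chrom_sizes.values()) or 1
    scale = (width - pad_left - 20) / max_size

    n_total = len(ses)
    closeness_by_rank: dict[int, int | None] = {}
    if closeness_records:
        closeness_by_rank = {r.se_id: r.closeness for r in closeness_records}
    finite = [v for v in closeness_by_rank.values() if v is not None]
    c_lo, c_hi = (min(finite), max(finite)) if finite else (1, 2)

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}" '
        f'viewBox="0 0 {width} {height}">',
        f'<rect width="{width}" height="{height}" fill="white"/>',
    ]
    for i, chrom in enumerate(chroms):
        cy = 20 + i * lane_h
        mark = (enrichment_marks or {}).get(chrom, "") if mode == "enrichment" else ""
        label = f"{chrom} {mark}".rstrip()
        parts.append(
            f'<text x="6" y="{cy + 5}" font-size="12" font-family="sans-serif">{label}</text>'
        )
        parts.append(
            f'<rect x="{pad_left}" y="{cy - 5}" width="{chrom_sizes[chrom] * scale:.1f}" '
            f'height="10" rx="5" fill="#e8e8e8" stroke="#888"/>'
        )
        for se in (s for s in se_only if s.chrom == chrom):
            if mode == "rank":
                bin_idx = int(rank_percentile_bins(np.array([se.rank]), n_total, bins)[0])
                color = _hue_color((bin_idx - 1) / max(bins - 1, 1))
            elif mode == "closeness":
                color = closeness_color(closeness_by_rank.get(se.rank), c_lo, c_hi)
            else:
                color = "#c0392b"
            cx = pad_left + (se.interval.start + se.interval.end) / 2 * scale
            parts.append(
                f'<a href="se_table.html#se-{se.rank}">'
                f'<circle cx="{cx:.1f}" cy="{cy}" r="4" fill="{color}">'
                f"<title>rank {se.rank}: {se.chrom}:{se.interval.start}-{se.interval.end}</title>"
                f"</circle></a>"
            )
    parts.append("</svg>")
    return "\n".join(parts)
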