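"""Deterministic synthetic epigenomic landscapes.

Everything the pipeline consumes can be generated here: an enhancer
landscape with planted superenhancer clusters and isolated typical
enhancers, reads sampled over the peaks in proportion to their pileup,
gene models with marker genes planted inside the SE clusters, and an
analytic hockey-stick score curve with a known 45-degree-tangent index.

The defaults emulate an embryonic-stem-cell-like landscape: SE clusters
of 5-7 subpeaks (the subpeak count range typical of ESC
superenhancers), intra-cluster gaps safely below the 12.5 kb stitch
distance, isolated enhancers separated by more than it, and roughly a
tenfold pileup contrast between SE subpeaks and typical enhancers.

Every generator takes an explicit integer seed; there is no global
randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import GenerationError, UsageError
from .intervals import GeneModel, GenomicInterval, Peak, Read

DEFAULT_CHROM_SIZES = {"chr1": 3_000_000, "chr2": 3_000_000, "chr3": 3_000_000}


@dataclass
class LandscapeSpec:
    """Parameters of a planted enhancer landscape."""

    chrom_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CHROM_SIZES))
    n_se_clusters: int = 20
    subpeaks_min: int = 5
    subpeaks_max: int = 7
    intra_cluster_gap: int = 6_000  # < stitch distance, keeps clusters whole
    n_te: int = 200
    te_min_separation: int = 20_000  # > stitch distance, keeps TEs isolated
    se_pileup_mean: float = 60.0
    te_pileup_mean: float = 6.0
    se_grading: float = 1.12  # geometric spacing of cluster strengths
    te_log_sd: float = 0.5  # right-skewed TE strength spread
    peak_width_min: int = 600
    peak_width_max: int = 2_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.intra_cluster_gap >= 12_500:
            raise UsageError("intra_cluster_gap must stay below the 12.5 kb stitch distance")
        if self.te_min_separation <= 12_500:
            raise UsageError("te_min_separation must exceed the 12.5 kb stitch distance")
        if self.se_pileup_mean <= self.te_pileup_mean:
            raise UsageError("SE pileup must exceed TE pileup")


def make_landscape(spec: LandscapeSpec | None = None) -> tuple[list[Peak], pd.DataFrame]:
    """Plant SE clusters and isolated TEs; return peaks and a truth table.

    Cluster strengths form a geometric ladder (``se_grading`` apart), so
    the sorted score spectrum is a smooth continuum rather than a pile
    of near-ties — the shape real SE rankings show. Each cluster's total
    pileup budget is the strength times six, split evenly over its
    subpeaks. TE strengths are lognormal around ``te_pileup_mean``, i.e.
    right-skewed like real enhancer signal.

    The truth table has one row per planted cluster with its stitched
    extent (chrom, start, end, n_subpeaks), which stitching at the
    default distance reproduces exactly by construction. Raises
    :class:`GenerationError` when the genome cannot hold the request.
    """
    spec = spec or LandscapeSpec()
    rng = np.random.default_rng(spec.seed)
    strengths = [spec.se_pileup_mean * spec.se_grading**i for i in range(spec.n_se_clusters)]
    rng.shuffle(strengths)
    items = ["SE"] * spec.n_se_clusters + ["TE"] * spec.n_te
    rng.shuffle(items)
    chroms = sorted(spec.chrom_sizes)
    peaks: list[Peak] = []
    truth_rows = []
    chrom_idx = 0
    cursor = int(rng.integers(1_000, 5_000))
    cluster_id = 0
    te_id = 0
    for kind in items:
        placed = False
        while chrom_idx < len(chroms):
            chrom = chroms[chrom_idx]
            size = spec.chrom_sizes[chrom]
            if kind == "SE":
                n_sub = int(rng.integers(spec.subpeaks_min, spec.subpeaks_max + 1))
                widths = rng.integers(spec.peak_width_min, spec.peak_width_max + 1, n_sub)
                gaps = rng.integers(200, min(spec.intra_cluster_gap, 12_499) + 1, n_sub - 1)
                extent = int(widths.sum() + gaps.sum())
                if cursor + extent >= size:
                    chrom_idx += 1
                    cursor = int(rng.integers(1_000, 5_000))
                    continue
                start = cursor
                pos = start
                sub = []
                per_peak = strengths[cluster_id] * 6.0 / n_sub
                for i in range(n_sub):
                    iv = GenomicInterval(chrom, pos, pos + int(widths[i]))
                    pileup = float(per_peak * rng.uniform(0.98, 1.02))
                    sub.append(Peak(iv, pileup, f"SE{cluster_id:03d}_{i}"))
                    pos = iv.end + (int(gaps[i]) if i < n_sub - 1 else 0)
                peaks.extend(sub)
                truth_rows.append(
                    {
                        "cluster": f"SE{cluster_id:03d}",
                        "chrom": chrom,
                        "start": start,
                        "end": sub[-1].interval.end,
                        "n_subpeaks": n_sub,
                    }
                )
                cluster_id += 1
                cursor = sub[-1].interval.end
            else:
                width = int(rng.integers(spec.peak_width_min, spec.peak_width_max + 1))
                if cursor + width >= size:
                    chrom_idx += 1
                    cursor = int(rng.integers(1_000, 5_000))
                    continue
                iv = GenomicInterval(chrom, cursor, cursor + width)
                pileup = float(
                    spec.te_pileup_mean
                    * np.exp(rng.normal(-spec.te_log_sd**2 / 2, spec.te_log_sd))
                )
                peaks.append(Peak(iv, pileup, f"TE{te_id:04d}"))
                te_id += 1
                cursor = iv.end
            cursor += int(rng.integers(spec.te_min_separation, 2 * spec.te_min_separation))
            placed = True
            break
        if not placed:
            raise GenerationError(
                f"genome too small: placed {cluster_id} clusters and {te_id} TEs "
                f"of {spec.n_se_clusters}/{spec.n_te} requested"
            )
    peaks.sort(key=lambda p: p.interval)
    truth = pd.DataFrame(truth_rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    return peaks, truth


def make_reads(
    peaks: list[Peak],
    depth_per_pileup_unit: float = 3.0,
    read_length: int = 100,
    seed: int = 0,
) -> list[Read]:
    """Sample reads over peaks, count proportional to pileup.

    Each peak receives ``round(pileup * depth_per_pileup_unit)`` reads
    with uniform start positions inside the peak; reads may run past the
    peak end, as sequencing reads do past a narrow summit.
    """
    if read_length < 1:
        raise UsageError("read_length must be >= 1")
    rng = np.random.default_rng(seed)
    reads = []
    for peak in peaks:
        n = int(round(peak.pileup * depth_per_pileup_unit))
        if n <= 0:
            continue
        starts = rng.integers(peak.interval.start, peak.interval.end, n)
        for s in sorted(int(x) for x in starts):
            reads.append(Read(GenomicInterval(peak.interval.chrom, s, s + read_length)))
    reads.sort(key=lambda r: r.interval)
    return reads


def make_genes(
    truth: pd.DataFrame,
    chrom_sizes: dict[str, int] | None = None,
    n_markers: int | None = None,
    n_background: int = 200,
    fraction_marker_in_se: float = 1.0,
    gene_length: int = 2_000,
    seed: int = 0,
) -> tuple[list[GeneModel], list[str]]:
    """Gene models with marker genes planted inside SE clusters.

    A fraction ``fraction_marker_in_se`` of the markers get their TSS
    inside a planted cluster (cycling through clusters); the rest, and
    all background genes, are placed uniformly outside every cluster.
    Returns (genes, marker symbols).
    """
    if not 0.0 <= fraction_marker_in_se <= 1.0:
        raise UsageError("fraction_marker_in_se must be in [0, 1]")
    chrom_sizes = chrom_sizes or dict(DEFAULT_CHROM_SIZES)
    rng = np.random.default_rng(seed)
    clusters = truth.reset_index(drop=True)
    if n_markers is None:
        n_markers = len(clusters)
    genes: list[GeneModel] = []
    markers: list[str] = []
    n_inside = int(round(fraction_marker_in_se * n_markers))

    def _outside_position() -> tuple[str, int]:
        for _ in range(1000):
            chrom = sorted(chrom_sizes)[rng.integers(0, len(chrom_sizes))]
            pos = int(rng.integers(0, chrom_sizes[chrom] - gene_length))
            hit = clusters[
                (clusters["chrom"] == chrom)
                & (clusters["start"] - gene_length < pos)
                & (pos < clusters["end"])
            ]
            if hit.empty:
                return chrom, pos
        raise GenerationError("could not place a gene outside the planted clusters")

    for i in range(n_markers):
        name = f"MARKER{i:03d}"
        markers.append(name)
        if i < n_inside and len(clusters):
            row = clusters.iloc[i % len(clusters)]
            tss = int(rng.integers(row["start"], row["end"]))
            chrom = row["chrom"]
        else:
            chrom, tss = _outside_position()
        genes.append(
            GeneModel(name, "+", tss, GenomicInterval(chrom, tss, tss + gene_length))
        )
    for i in range(n_background):
        chrom, tss = _outside_position()
        genes.append(
            GeneModel(f"GENE{i:04d}", "+", tss, GenomicInterval(chrom, tss, tss + gene_length))
        )
    genes.sort(key=lambda g: (g.chrom, g.span.start, g.name))
    return genes, markers


def _solve_growth(n_segments: int, tangent_segment: int) -> float:
    """Growth rate g of geometric slope increments ``exp(g*(i - i0))``
    whose mean-slope crossing sits exactly at segment ``i0`` after the
    [0,1] rescaling applied by the threshold finder."""
    m = n_segments

    def crossing(g: float) -> float:
        # log of sum_{i=0}^{m-1} exp(g*i), computed without overflow
        log_t = g * m + np.log1p(-np.exp(-g * m)) - (g + np.log1p(-np.exp(-g)))
        return (log_t - np.log(m)) / g - tangent_segment

    # convex increments place the mean-slope crossing in ((m-1)/2, m-1)
    if not (m - 1) / 2 < tangent_segment < m - 1:
        raise UsageError(
            f"tangent segment {tangent_segment} unreachable with a convex curve of "
            f"{m} segments; needs ({(m - 1) / 2:.0f}, {m - 1})"
        )
    g_hi = 1.0 / m
    while crossing(g_hi) < 0:
        g_hi *= 2.0
        if g_hi > 1e4:
            raise UsageError(f"tangent segment {tangent_segment} numerically unreachable")
    return float(brentq(crossing, 1e-9, g_hi, maxiter=200))


def make_hockey_curve(
    n: int,
    inflection_index: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    count_min: float = 10.0,
    count_max: float = 10_000.0,
) -> np.ndarray:
    """Descending score curve whose 45-degree tangent sits at a known rank.

    The ascending [0,1]-scaled curve is built from geometrically growing
    per-rank increments; the growth rate is solved so the increment
    equal to the mean (slope 1 after rescaling) falls exactly at the
    segment whose upper point is descending rank ``inflection_index``.
    ``noise_sd`` perturbs the increments (in units of the slope-1
    increment) before integration; counts are then mapped linearly onto
    [count_min, count_max] and returned in descending-rank order.
    """
    if not 1 < inflection_index < n:
        raise UsageError("inflection_index must satisfy 1 < index < n")
    m = n - 1
    i0 = n - inflection_index - 1  # 0-based ascending segment of the tangent
    g = _solve_growth(m, i0)
    slopes = np.exp(g * (np.arange(m) - i0))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        slopes = np.maximum(slopes + rng.normal(0.0, noise_sd, m), 1e-9)
    y = np.concatenate([[0.0], np.cumsum(slopes)])
    y = y / y[-1]
    counts = count_min + y * (count_max - count_min)
    return counts[::-1].copy()
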