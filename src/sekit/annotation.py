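"""Gene assignment and TSS-relative subpeak annotation.

Each stitched enhancer is assigned the gene with the closest TSS (edge
distance in bp; 0 when the TSS falls inside the region). Genes
overlapping the region and genes with a TSS within a proximal window are
reported alongside. Subpeak structure is summarized by the percentage of
subpeaks lying outside a TSS window ("Percentage OUTS") and the derived
enhancer type: *Pure* (all subpeaks outside any TSS window), *Only TSS*
(all inside), *Mixed* otherwise. A region sitting entirely inside a TSS
window likely reflects promoter signal rather than a distal enhancer,
which is what this classification is meant to expose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .intervals import GeneModel, GenomicInterval, StitchedEnhancer

DEFAULT_TSS_WINDOW = 2_500
DEFAULT_PROXIMAL_WINDOW = 50_000

PURE = "Pure"
ONLY_TSS = "Only TSS"
MIXED = "Mixed"


@dataclass
class SEAnnotation:
    closest_gene: str = "NA"
    tss_distance: int | None = None
    overlapping_genes: list[str] = field(default_factory=list)
    proximal_genes: list[str] = field(default_factory=list)
    n_subpeaks: int = 0
    percentage_outs: float = 0.0
    enhancer_type: str = PURE


def tss_distance(se: GenomicInterval, tss: int) -> int:
    """Edge distance in bp from the region to a TSS; 0 if the TSS is inside.

    Outside the region the distance is measured to the nearest covered
    base (``start`` on the left, ``end - 1`` on the right).
    """
    if se.start <= tss < se.end:
        return 0
    if tss < se.start:
        return se.start - tss
    return tss - (se.end - 1)


def assign_closest_gene(
    se: StitchedEnhancer, genes: list[GeneModel]
) -> tuple[str, int | None]:
    """Gene with the nearest TSS on the SE's chromosome.

    Ties break lexicographically by gene symbol; with no gene on the
    chromosome the annotation is ("NA", None).
    """
    candidates = [g for g in genes if g.chrom == se.chrom]
    if not candidates:
        return "NA", None
    best = min(candidates, key=lambda g: (tss_distance(se.interval, g.tss), g.name))
    return best.name, tss_distance(se.interval, best.tss)


def find_overlapping_and_proximal(
    se: StitchedEnhancer,
    genes: list[GeneModel],
    window: int = DEFAULT_PROXIMAL_WINDOW,
) -> tuple[list[str], list[str]]:
    """Genes whose body intersects the SE, and genes with a TSS within
    ``window`` bp of either SE edge (excluding the overlapping ones)."""
    overlapping, proximal = [], []
    for gene in genes:
        if gene.chrom != se.chrom:
            continue
        if gene.span.intersects(se.interval):
            overlapping.append(gene.name)
        elif tss_distance(se.interval, gene.tss) <= window:
            proximal.append(gene.name)
    return sorted(overlapping), sorted(proximal)


def _subpeak_in_tss(peak_iv: GenomicInterval, genes: list[GeneModel], tss_window: int) -> bool:
    # closed TSS window [tss - w, tss + w] intersected with a half-open peak
    for gene in genes:
        if gene.chrom != peak_iv.chrom:
            continue
        if peak_iv.start <= gene.tss + tss_window and gene.tss - tss_window < peak_iv.end:
            return True
    return False


def annotate_subpeaks(
    se: StitchedEnhancer,
    genes: list[GeneModel],
    tss_window: int = DEFAULT_TSS_WINDOW,
) -> tuple[int, float, str]:
    """(n_subpeaks, percentage_outs, enhancer_type) for one region.

    A subpeak is "inside" when it intersects the closed window
    ``[tss - tss_window, tss + tss_window]`` of *any* gene.
    """
    n = len(se.subpeaks)
    outside = sum(
        0 if _subpeak_in_tss(p.interval, genes, tss_window) else 1 for p in se.subpeaks
    )
    pct = 100.0 * outside / n if n else 0.0
    if outside == n and n > 0:
        etype = PURE
    elif outside == 0:
        etype = ONLY_TSS
    else:
        etype = MIXED
    return n, pct, etype


def annotate(
    se: StitchedEnhancer,
    genes: list[GeneModel],
    tss_window: int = DEFAULT_TSS_WINDOW,
    proximal_window: int = DEFAULT_PROXIMAL_WINDOW,
) -> SEAnnotation:
    """Full annotation bundle for one stitched region."""
    closest, dist = assign_closest_gene(se, genes)
    overlapping, proximal = find_overlapping_and_proximal(se, genes, window=proximal_window)
    n, pct, etype = annotate_subpeaks(se, genes, tss_window=tss_window)
    return SEAnnotation(
        closest_gene=closest,
        tss_distance=dist,
        overlapping_genes=overlapping,
        proximal_genes=proximal,
        n_subpeaks=n,
        percentage_outs=pct,
        enhancer_type=etype,
    )


def genecards_url(symbol: str) -> str:
    return f"https://www.genecards.org/cgi-bin/carddisp.pl?gene={symbol}"


def ucsc_url(interval: GenomicInterval) -> str:
    # UCSC display is 1-based inclusive
    return (
        "https://genome.ucsc.edu/cgi-bin/hgTracks?position="
        f"{interval.chrom}:{interval.start + 1}-{interval.end}"
    )
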