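"""Chromosome-level SE statistics.

*Closeness* of a superenhancer is the gap in bp to its nearest
neighbouring SE on the same chromosome (for interior SEs, the smaller of
the two adjacent gaps; undefined when the chromosome holds a single SE).

Chromosome *enrichment* asks whether a chromosome carries more (or
fewer) SEs than its share of genes predicts. With N genes genome-wide,
n on the chromosome, K SEs genome-wide and k on the chromosome, the
hypergeometric h(k; K, n, N) is approximated by the binomial
b(k; K, z) with z = n/N, and the two one-sided exact tail sums
P(X >= k) / P(X <= k) are marked at 0.05 and 0.01.

The SE-vs-TE summaries (TSS overlap percentages, length/pileup
histograms in log10 bins, subpeak-count histograms) are computed as tidy
tables, ready for plotting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SekitError, UsageError
from .intervals import StitchedEnhancer

MARK_ENRICH_01 = "⋏⋏"
MARK_ENRICH_05 = "⋏"
MARK_NONE = "none"
MARK_DEPLETE_05 = "⋎"
MARK_DEPLETE_01 = "⋎⋎"


@dataclass
class ClosenessRecord:
    se_id: int  # rank of the SE in the call
    chrom: str
    closeness: int | None  # bp to nearest SE on the chromosome, None if alone


@dataclass
class EnrichmentResult:
    chrom: str
    N: int
    K: int
    n: int
    k: int
    z: float
    p_enrich: float
    p_deplete: float
    mark: str


def closeness(ses_on_chrom: list[StitchedEnhancer]) -> list[ClosenessRecord]:
    """Nearest-SE gap for each SE of one chromosome.

    Input must be sorted by start and disjoint (stitching guarantees
    both). A lone SE gets closeness None.
    """
    ses = ses_on_chrom
    for a, b in zip(ses, ses[1:]):
        if a.chrom != b.chrom:
            raise UsageError("closeness operates on a single chromosome")
        if b.interval.start < a.interval.end:
            raise SekitError(f"overlapping SEs at {a.interval} / {b.interval}")
    c = len(ses)
    out = []
    for idx, se in enumerate(ses):
        if c == 1:
            value = None
        elif idx == 0:
            value = ses[1].interval.start - se.interval.end
        elif idx == c - 1:
            value = se.interval.start - ses[idx - 1].interval.end
        else:
            value = min(
                ses[idx + 1].interval.start - se.interval.end,
                se.interval.start - ses[idx - 1].interval.end,
            )
        out.append(ClosenessRecord(se_id=se.rank, chrom=se.chrom, closeness=value))
    return out


def closeness_all(ses: list[StitchedEnhancer]) -> list[ClosenessRecord]:
    """Closeness across every chromosome, SEs grouped internally."""
    by_chrom: dict[str, list[StitchedEnhancer]] = {}
    for se in sorted(ses, key=lambda s: s.interval):
        by_chrom.setdefault(se.chrom, []).append(se)
    out = []
    for chrom in sorted(by_chrom):
        out.extend(closeness(by_chrom[chrom]))
    return out


def chromosome_enrichment(
    chrom: str,
    N: int,
    K: int,
    n: int,
    k: int,
    alpha1: float = 0.05,
    alpha2: float = 0.01,
) -> EnrichmentResult:
    """Exact binomial tail test of SE enrichment/depletion on a chromosome.

    The gene share z = n/N is the success probability; enrichment is
    P(X >= k) and depletion P(X <= k) for X ~ Binomial(K, z). Marks:
    double glyph below 0.01, single below 0.05, ``none`` otherwise, with
    enrichment taking precedence should both fire.
    """
    if not (0 < n <= N):
        raise UsageError(f"need 0 < n <= N, got n={n}, N={N}")
    if not (0 <= k <= K):
        raise UsageError(f"need 0 <= k <= K, got k={k}, K={K}")
    z = n / N
    dist = stats.binom(K, z)
    p_enrich = float(dist.sf(k - 1))  # P(X >= k)
    p_deplete = float(dist.cdf(k))  # P(X <= k)
    if p_enrich < alpha2:
        mark = MARK_ENRICH_01
    elif p_enrich < alpha1:
        mark = MARK_ENRICH_05
    elif p_deplete < alpha2:
        mark = MARK_DEPLETE_01
    elif p_deplete < alpha1:
        mark = MARK_DEPLETE_05
    else:
        mark = MARK_NONE
    return EnrichmentResult(
        chrom=chrom, N=N, K=K, n=n, k=k, z=z, p_enrich=p_enrich, p_deplete=p_deplete, mark=mark
    )


def enrichment_table(
    ses: list[StitchedEnhancer], genes_per_chrom: dict[str, int]
) -> pd.DataFrame:
    """Per-chromosome enrichment over every chromosome carrying genes."""
    N = sum(genes_per_chrom.values())
    se_only = [s for s in ses if s.is_se]
    K = len(se_only)
    k_per_chrom: dict[str, int] = {}
    for se in se_only:
        k_per_chrom[se.chrom] = k_per_chrom.get(se.chrom, 0) + 1
    rows = []
    for chrom in sorted(genes_per_chrom):
        res = chromosome_enrichment(
            chrom, N=N, K=K, n=genes_per_chrom[chrom], k=k_per_chrom.get(chrom, 0)
        )
        rows.append(vars(res))
    return pd.DataFrame(rows)


def rank_percentile_bins(ranks: np.ndarray, n_total: int, bins: int = 10) -> np.ndarray:
    """Percentile bin (1..bins) per rank: ``ceil(rank * bins / n)`` clipped."""
    ranks = np.asarray(ranks)
    if n_total < 1:
        raise UsageError("empty rank set")
    raw = np.ceil(ranks * bins / n_total).astype(int)
    return np.clip(raw, 1, bins)


def _log_hist(values: np.ndarray, n_bins: int = 30) -> pd.DataFrame:
    values = np.asarray(values, dtype=float)
    values = values[values > 0]
    if values.size == 0:
        return pd.DataFrame(columns=["bin_left", "bin_right", "count"])
    lo, hi = values.min(), values.max()
    if lo == hi:
        hi = lo * 1.0001 + 1e-9
    edges = np.logspace(math.log10(lo), math.log10(hi), n_bins + 1)
    counts, edges = np.histogram(values, bins=edges)
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})


def summary_statistics(se_table: pd.DataFrame, subpeaks: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """SE-vs-TE summary bundle computed from an annotated SE table.

    ``subpeaks`` is a tidy frame (rank, is_SE, start, end, pileup) of all
    subpeaks. Returns tidy frames keyed by artifact name:

    - ``ins_outs``: percentage of SE/TE regions intersecting a TSS
      window (regions with percentage_outs < 100).
    - ``length_hist_se`` / ``length_hist_te``: region length histograms
      on log10-spaced bins; ``subpeak_length_hist_*`` likewise.
    - ``subpeak_count_hist_10`` / ``_20``: subpeak-count histograms at
      10 and 20 linear bins, columns bin_left/bin_right/count split by
      class.
    """
    out: dict[str, pd.DataFrame] = {}
    is_se = se_table["is_SE"].astype(bool)
    ins_rows = []
    for label, mask in (("SE", is_se), ("TE", ~is_se)):
        sub = se_table[mask]
        n = len(sub)
        pct_ins = 100.0 * (sub["percentage_outs"] < 100.0).sum() / n if n else float("nan")
        ins_rows.append({"class": label, "n": n, "pct_with_tss": pct_ins})
    out["ins_outs"] = pd.DataFrame(ins_rows)

    lengths = se_table["end"] - se_table["start"]
    out["length_hist_se"] = _log_hist(lengths[is_se].to_numpy())
    out["length_hist_te"] = _log_hist(lengths[~is_se].to_numpy())

    sp_se = subpeaks[subpeaks["is_SE"].astype(bool)]
    sp_te = subpeaks[~subpeaks["is_SE"].astype(bool)]
    out["subpeak_length_hist_se"] = _log_hist((sp_se["end"] - sp_se["start"]).to_numpy())
    out["subpeak_length_hist_te"] = _log_hist((sp_te["end"] - sp_te["start"]).to_numpy())
    out["pileup_hist_se"] = _log_hist(sp_se["pileup"].to_numpy())
    out["pileup_hist_te"] = _log_hist(sp_te["pileup"].to_numpy())

    n_sub = se_table["n_subpeaks"].to_numpy()
    for n_bins in (10, 20):
        hi = max(int(n_sub.max()), n_bins) if n_sub.size else n_bins
        edges = np.linspace(0.5, hi + 0.5, n_bins + 1)
        rows = []
        for label, mask in (("SE", is_se.to_numpy()), ("TE", (~is_se).to_numpy())):
            counts, _ = np.histogram(n_sub[mask], bins=edges)
            for left, right, cnt in zip(edges[:-1], edges[1:], counts):
                rows.append(
                    {"class": label, "bin_left": left, "bin_right": right, "count": int(cnt)}
                )
        out[f"subpeak_count_hist_{n_bins}"] = pd.DataFrame(rows)
    return out
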