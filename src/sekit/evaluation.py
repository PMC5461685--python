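"""Scaled-rank evaluation of SE predictors against marker genes.

Different predictors (different signals or signal-algebra combinations)
produce SE lists of different lengths, so raw ranks are not comparable.
The scaled rank

    s(r) = 100 * r / n_se

where ``n_se`` is the predictor's SE count, lands in [0, 100] when the
region is called SE and above 100 when it is a TE. A marker gene absent
from the prediction altogether receives the sentinel
``s = 100 * (n_stitched + 1) / n_se`` — one step worse than the worst
TE — which keeps the average finite and order-consistent.

The goodness of a predictor is the mean s over a marker gene list
(lower is better); across predictors the means are normalised to the
worst one, so the weakest predictor scores 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import EvaluationError

SENTINEL_STATUS = "unpredicted"


@dataclass
class MarkerScore:
    gene: str
    rank: int | None
    s: float
    status: str  # "SE", "TE" or "unpredicted"


@dataclass
class GoodnessResult:
    label: str
    n_se: int
    n_stitched: int
    s_mean: float
    s_norm: float | None = None
    per_marker: list[MarkerScore] | None = None


def scaled_rank(r: int, n_se: int) -> float:
    """s(r) = 100 r / n_se; r and n_se must be positive."""
    if n_se < 1:
        raise EvaluationError("no SEs predicted: scaled rank undefined")
    if r < 1:
        raise EvaluationError(f"rank must be >= 1, got {r}")
    return 100.0 * r / n_se


def marker_goodness(
    marker_genes: list[str], se_table: pd.DataFrame, label: str = "predictor"
) -> GoodnessResult:
    """Mean scaled rank of a marker list under one prediction.

    Each marker is matched (case-insensitively) against the table's
    ``closest_gene`` column; the best-ranked match wins. Unmatched
    markers take the sentinel value.
    """
    if not marker_genes:
        raise EvaluationError("marker list is empty")
    if se_table.empty:
        raise EvaluationError("SE table is empty")
    n_stitched = len(se_table)
    n_se = int(se_table["is_SE"].astype(bool).sum())
    if n_se < 1:
        raise EvaluationError("no SEs predicted: goodness undefined")
    by_gene: dict[str, int] = {}
    for _, row in se_table.iterrows():
        gene = str(row["closest_gene"]).upper()
        rank = int(row["rank"])
        if gene not in by_gene or rank < by_gene[gene]:
            by_gene[gene] = rank
    sentinel = scaled_rank(n_stitched + 1, n_se)
    scores = []
    for marker in marker_genes:
        rank = by_gene.get(marker.upper())
        if rank is None:
            scores.append(MarkerScore(marker, None, sentinel, SENTINEL_STATUS))
        else:
            s = scaled_rank(rank, n_se)
            scores.append(MarkerScore(marker, rank, s, "SE" if s <= 100.0 else "TE"))
    mean = sum(m.s for m in scores) / len(scores)
    return GoodnessResult(
        label=label, n_se=n_se, n_stitched=n_stitched, s_mean=mean, per_marker=scores
    )


def normalize_goodness(results: list[GoodnessResult]) -> list[GoodnessResult]:
    """Divide every mean by the largest one; the worst predictor gets 1.0."""
    if not results:
        raise EvaluationError("no goodness results to normalise")
    worst = max(r.s_mean for r in results)
    if worst <= 0:
        raise EvaluationError("all goodness means are zero")
    for r in results:
        r.s_norm = r.s_mean / worst
    return results


def goodness_table(results: list[GoodnessResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "predictor": r.label,
                "n_se": r.n_se,
                "n_stitched": r.n_stitched,
                "s_mean": r.s_mean,
                "s_norm": r.s_norm,
            }
            for r in results
        ]
    )


def marker_matrix(results: list[GoodnessResult]) -> pd.DataFrame:
    """Markers x predictors matrix of s(r) values (heatmap data)."""
    data: dict[str, dict[str, float]] = {}
    for r in results:
        for m in r.per_marker or []:
            data.setdefault(m.gene, {})[r.label] = m.s
    return pd.DataFrame(data).T.sort_index()
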