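"""Gene-set statistics: over-representation and single-sample enrichment.

Over-representation analysis (ORA) scores a query gene set against each
set of a GMT collection with the hypergeometric upper tail, inside a
declared universe, with Benjamini–Hochberg correction across sets.

Single-sample GSEA (ssGSEA) scores every sample of an expression matrix
against each gene set by a rank-weighted running sum: genes are ranked by
expression within the sample, and the score accumulates the difference
between the weighted in-set ECDF (weights rank^alpha) and the unweighted
out-of-set ECDF over the whole ranking. Being rank-based, the raw score
is invariant to any per-sample monotone transform of the values.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import EnrichmentResult, ExpressionMatrix


def ora(
    query: Iterable[str],
    sets: Mapping[str, Mapping],
    universe: Iterable[str],
) -> EnrichmentResult:
    """Hypergeometric over-representation of a query set in each gene set.

    Sets are intersected with the universe first; the query must be a
    subset of the universe. p-values are the upper tail
    P(X ≥ overlap | universe, set size, query size); BH-adjusted values
    are computed across all sets in the collection.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("the universe is empty")
    query = set(query)
    if not query <= universe:
        extra = sorted(query - universe)[:5]
        raise ValueError(f"query contains features outside the universe, e.g. {extra}")
    m = len(universe)
    n_query = len(query)
    rows = []
    for name, entry in sets.items():
        members = set(entry["members"]) & universe
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, m, len(members), n_query)) if members else 1.0
        rows.append(
            {
                "set_name": name,
                "overlap": k,
                "set_size": len(members),
                "universe_size": m,
                "p_value": min(p, 1.0),
                "enrichment_direction": "over",
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adjusted"] = multipletests(table["p_value"], method="fdr_bh")[1]
        table = table.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    else:
        table["p_adjusted"] = pd.Series(dtype=float)
    return EnrichmentResult(table=table, universe_size=m, query_size=n_query)


def _ssgsea_sample(
    ranks: np.ndarray, order: np.ndarray, in_set: np.ndarray, alpha: float
) -> float:
    """Running-sum enrichment of one gene set in one ranked sample.

    ranks: average-tie ranks of expression (highest expression = highest
    rank); order: gene indices sorted by decreasing rank; in_set: boolean
    per gene.
    """
    n = len(ranks)
    n_in = int(in_set.sum())
    n_out = n - n_in
    if n_out == 0:
        # with no out-of-set genes the two ECDFs degenerate together
        return 0.0
    ordered_in = in_set[order]
    w = np.where(ordered_in, np.abs(ranks[order]) ** alpha, 0.0)
    denom = w.sum()
    if denom <= 0:
        return 0.0
    p_in = np.cumsum(w) / denom
    p_out = np.cumsum(~ordered_in) / n_out
    return float((p_in - p_out).sum())


def ssgsea(
    matrix: ExpressionMatrix | pd.DataFrame,
    sets: Mapping[str, Mapping],
    alpha: float = 0.25,
    normalize: bool = True,
    min_members: int = 2,
) -> tuple[pd.DataFrame, int]:
    """Single-sample gene-set scores for every sample × set.

    Returns a samples×sets DataFrame and the number of sets skipped for
    having fewer than ``min_members`` members present in the matrix. When
    ``normalize`` is on, all scores are divided by the global score range
    (max − min across the whole table), the usual cross-sample
    normalization for this statistic.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    genes = values.index.to_numpy()
    gene_pos = {g: i for i, g in enumerate(genes)}

    usable: dict[str, np.ndarray] = {}
    skipped = 0
    for name, entry in sets.items():
        idx = [gene_pos[g] for g in entry["members"] if g in gene_pos]
        if len(idx) < min_members:
            skipped += 1
            continue
        mask = np.zeros(len(genes), dtype=bool)
        mask[idx] = True
        usable[name] = mask

    scores = pd.DataFrame(
        index=values.columns, columns=list(usable), dtype=float
    )
    for sample in values.columns:
        v = values[sample].to_numpy(dtype=float)
        ranks = stats.rankdata(v, method="average")
        # decreasing rank; stable so equal ranks break by gene position
        order = np.argsort(-ranks, kind="mergesort")
        for name, mask in usable.items():
            scores.loc[sample, name] = _ssgsea_sample(ranks, order, mask, alpha)

    if normalize and scores.size:
        rng = np.nanmax(scores.to_numpy()) - np.nanmin(scores.to_numpy())
        if rng > 0:
            scores = scores / rng
    return scores, skipped


def network_table(
    enrichment: EnrichmentResult,
    sets: Mapping[str, Mapping],
    query: Iterable[str],
    cutoff: float = 0.05,
) -> pd.DataFrame:
    """Feature–set edge list for sets passing the adjusted-p cutoff.

    One edge per (query feature, passing set) membership pair; intended
    for external network visualization tools.
    """
    query = set(query)
    passing = enrichment.table.loc[
        enrichment.table["p_adjusted"] <= cutoff, "set_name"
    ]
    edges = []
    for name in passing:
        for g in sorted(set(sets[name]["members"]) & query):
            edges.append({"feature": g, "set_name": name})
    return pd.DataFrame(edges, columns=["feature", "set_name"])
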