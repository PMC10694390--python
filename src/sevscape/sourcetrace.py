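"""Cell-of-origin attribution of bulk sEV cargo.

Two complementary strategies against a single-cell reference:

A. *Deconvolution + cell-weighted fold change.* Nonnegative least squares
   on marker genes estimates cell-type proportions in the bulk profile;
   each differential gene's log2 fold change is then apportioned across
   cell types by specificity × proportion, and cell types are ranked by
   the mean |cwFC| they receive. The top-ranked cluster is the cell type
   most likely responsible for the differential cargo.

B. *Abundance attribution.* Each gene's bulk mass is split across
   clusters by the specificity share S[g,k]; summing over genes gives
   each cluster's share of total sEV cargo (Tissue-sEV%). Dividing by the
   cluster's share of cells (Cell%) — on a log10 scale, the release index
   — asks whether a cell type over- or under-contributes cargo per cell.

The attribution is a soft (specificity-share) assignment: it conserves
mass exactly, so Tissue-sEV% sums to 1 and each gene's cwFC row sums to
its log2 fold change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .containers import CellTypeReference, DifferentialResult, SourceAttribution


@dataclass
class SignatureMatrix:
    """Genes×clusters mean expression (CPM) with specificity shares.

    specificity row-normalizes the cluster means: S[g,k] is the share of
    gene g's total cluster-mean expression carried by cluster k; rows of
    expressed genes sum to 1. marker_genes holds the per-cluster top-m
    markers by specificity × expression.
    """

    means: pd.DataFrame
    specificity: pd.DataFrame
    marker_genes: dict[str, list[str]]

    @property
    def clusters(self) -> list[str]:
        return self.means.columns.tolist()

    @property
    def all_markers(self) -> list[str]:
        seen: dict[str, None] = {}
        for genes in self.marker_genes.values():
            for g in genes:
                seen.setdefault(g, None)
        return list(seen)


def _specificity(means: pd.DataFrame) -> pd.DataFrame:
    totals = means.sum(axis=1)
    spec = means.div(totals.replace(0.0, np.nan), axis=0).fillna(0.0)
    return spec


def build_signature(
    sc_counts: pd.DataFrame,
    labels: pd.Series,
    m: int = 50,
) -> SignatureMatrix:
    """Distill a labeled single-cell count matrix into a signature.

    Per-cell CPM is averaged within each cluster; markers are the top-m
    genes per cluster by specificity × log1p(mean expression), with
    deterministic lexicographic tie-breaking on gene id.
    """
    labels = labels.reindex(sc_counts.index)
    if labels.isna().any():
        raise ValueError("every cell needs a cluster label")
    counts = labels.value_counts()
    small = counts[counts < 3]
    if len(small):
        raise ValueError(
            f"cluster(s) with fewer than 3 cells: {sorted(small.index.tolist())}"
        )
    lib = sc_counts.sum(axis=1)
    if (lib <= 0).any():
        raise ValueError("cells with zero total counts present")
    cpm = sc_counts.div(lib, axis=0) * 1e6
    means = cpm.groupby(labels, observed=True).mean().T  # genes × clusters
    means = means[sorted(means.columns, key=str)]
    spec = _specificity(means)
    score = spec * np.log1p(means)
    marker_genes: dict[str, list[str]] = {}
    for c in means.columns:
        # stable sort over a lexicographically pre-ordered index makes the
        # tie-break deterministic by gene id
        ranked = score[c].loc[sorted(score.index)].sort_values(
            ascending=False, kind="mergesort"
        )
        marker_genes[c] = ranked.index[:m].tolist()
    return SignatureMatrix(means=means, specificity=spec, marker_genes=marker_genes)


def signature_from_reference(
    reference: CellTypeReference, m: int = 50
) -> SignatureMatrix:
    """Signature straight from a reference's mean profiles (no cells)."""
    means = reference.profiles.copy()
    spec = _specificity(means)
    score = spec * np.log1p(means)
    marker_genes = {}
    for c in means.columns:
        ranked = score[c].loc[sorted(score.index)].sort_values(
            ascending=False, kind="mergesort"
        )
        marker_genes[c] = ranked.index[:m].tolist()
    return SignatureMatrix(means=means, specificity=spec, marker_genes=marker_genes)


def deconvolve(bulk: pd.Series, sig: SignatureMatrix) -> pd.Series:
    """Cell-type proportions by nonnegative least squares on marker genes.

    The bulk vector is CPM-scaled, restricted to the signature's marker
    genes, and regressed on the CPM signature columns with p ≥ 0; the
    solution is renormalized to sum to 1.
    """
    if len(sig.clusters) < 2:
        raise ValueError("need at least 2 clusters to deconvolve")
    total = float(bulk.sum())
    if total <= 0:
        raise ValueError("bulk vector is all zeros")
    markers = [g for g in sig.all_markers if g in bulk.index]
    if not markers:
        raise ValueError("no signature marker genes present in the bulk vector")
    b = (bulk / total * 1e6).loc[markers].to_numpy(dtype=float)
    a = sig.means.loc[markers].to_numpy(dtype=float)
    coef, _ = nnls(a, b)
    s = coef.sum()
    if s <= 0:
        raise ValueError("deconvolution returned an all-zero solution")
    return pd.Series(coef / s, index=sig.clusters, name="proportion")


def cw_fold_change(
    deg: DifferentialResult,
    sig: SignatureMatrix,
    proportions: pd.Series,
    directions: tuple[str, ...] = ("up",),
) -> tuple[pd.DataFrame, list[str], int]:
    """Apportion each differential gene's log2FC across cell types.

    cwFC[g,k] = log2FC(g) · S[g,k]·p̂_k / Σ_k' S[g,k']·p̂_k', so each
    gene's row sums to its log2 fold change. Clusters are ranked by the
    mean |cwFC| over the differential genes. Genes absent from the
    signature are dropped; the count of dropped genes is returned.
    """
    t = deg.table
    use = t[t["direction"].isin(directions)] if directions else t
    genes = [g for g in use["feature"] if g in sig.specificity.index]
    dropped = len(use) - len(genes)
    if not genes:
        raise ValueError("no differential genes overlap the signature")
    log2fc = use.set_index("feature").loc[genes, "log2_fc"].astype(float)
    s = sig.specificity.loc[genes].to_numpy(dtype=float)
    p = proportions.reindex(sig.clusters).to_numpy(dtype=float)
    weights = s * p[None, :]
    denom = weights.sum(axis=1, keepdims=True)
    # genes expressed nowhere get a uniform share (cannot localize them)
    flat = denom[:, 0] <= 0
    if flat.any():
        weights[flat] = 1.0 / len(sig.clusters)
        denom[flat] = 1.0
    share = weights / denom
    cw = pd.DataFrame(
        share * log2fc.to_numpy()[:, None], index=genes, columns=sig.clusters
    )
    ranking = (
        cw.abs().mean(axis=0).sort_values(ascending=False, kind="mergesort").index.tolist()
    )
    return cw, ranking, dropped


def attribute_abundance(
    bulk: pd.Series,
    sig: SignatureMatrix,
    cell_counts: Mapping[str, int],
    immune: Mapping[str, bool] | None = None,
) -> SourceAttribution:
    """Strategy B: split bulk cargo mass across clusters by specificity.

    Attributed mass A_k = Σ_g b_g·S[g,k]; Tissue-sEV%_k = A_k / Σ A;
    Cell%_k = n_k / Σ n; per-cell share = Tissue-sEV%_k / n_k;
    release index = log10(Tissue-sEV%_k / Cell%_k). When immune flags are
    given, the abundance-weighted mean release index per flag is reported.
    """
    if set(cell_counts) != set(sig.clusters):
        raise KeyError("cell_counts keys do not match signature clusters")
    if (bulk < 0).any():
        raise ValueError("bulk vector must be nonnegative")
    common = [g for g in sig.specificity.index if g in bulk.index]
    b = bulk.loc[common].to_numpy(dtype=float)
    s = sig.specificity.loc[common].to_numpy(dtype=float)
    mass = b @ s
    total = mass.sum()
    if total <= 0:
        raise ValueError("zero total attributed mass: bulk and signature do not overlap")
    sev_pct = mass / total
    n = np.array([cell_counts[c] for c in sig.clusters], dtype=float)
    cell_pct = n / n.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        per_cell = np.where(n > 0, sev_pct / n, np.nan)
        release = np.where(
            (sev_pct > 0) & (cell_pct > 0), np.log10(sev_pct / cell_pct), -np.inf
        )
    per_cluster = pd.DataFrame(
        {
            "cell_pct": cell_pct,
            "sev_pct": sev_pct,
            "per_cell_share": per_cell,
            "release_index": release,
        },
        index=pd.Index(sig.clusters, name="cluster"),
    )
    immune_summary: dict[str, float] = {}
    if immune is not None:
        per_cluster["immune"] = [bool(immune.get(c, False)) for c in sig.clusters]
        for flag, label in ((True, "immune"), (False, "nonimmune")):
            sel = per_cluster["immune"] == flag
            if sel.any():
                w = per_cluster.loc[sel, "sev_pct"]
                ri = per_cluster.loc[sel, "release_index"]
                ok = np.isfinite(ri)
                if ok.any() and w[ok].sum() > 0:
                    immune_summary[label] = float(
                        np.average(ri[ok], weights=w[ok])
                    )
    return SourceAttribution(
        per_cluster=per_cluster, immune_summary=immune_summary
    )


def trace(
    bulk: pd.Series,
    sig: SignatureMatrix,
    cell_counts: Mapping[str, int],
    deg: DifferentialResult | None = None,
    immune: Mapping[str, bool] | None = None,
) -> SourceAttribution:
    """Run both strategies and assemble a full SourceAttribution."""
    attribution = attribute_abundance(bulk, sig, cell_counts, immune=immune)
    attribution.proportions = deconvolve(bulk, sig)
    if deg is not None:
        cw, ranking, dropped = cw_fold_change(deg, sig, attribution.proportions)
        attribution.cw_fc = cw
        attribution.cluster_ranking = ranking
    return attribution
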