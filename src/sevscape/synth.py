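"""Synthetic cohorts with planted, machine-readable ground truth.

The generators emulate the study design this package analyzes: a
single-cell reference of a tumor microenvironment (epithelial cells,
cancer-associated fibroblasts, endothelial cells, immune cells), paired
per-patient sEV count profiles from tumor tissue (T), normal tissue (N),
tumor organoids (O) and plasma (B), pure CAF-culture sEV profiles, and a
case/control plasma cohort for diagnostics.

Counts are negative-binomial around cluster-mixture means. Organoid
profiles are drawn from the tumor-epithelial cluster alone (in-vitro
purity): that is the generative analogue of organoid sEVs lacking stromal
and immune cargo, and it is what makes the "lost in vitro" signature
recoverable. Every generator is deterministic given its seed, and the
planted truth is returned as a :class:`~sevscape.containers.GroundTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    CellTypeReference,
    ExpressionMatrix,
    GroundTruth,
    SampleMetadata,
)

_SEMANTIC_CLUSTERS = ("Epithelial", "CAF", "Endothelial", "Immune")


class ConfigurationError(ValueError):
    """A simulation configuration violates one of its invariants."""


@dataclass
class SimulationConfig:
    """Knobs of all synthetic generators.

    Defaults are the study conditions used throughout the test-suite:
    7 patients, 2000 genes, 4 clusters with 50 markers each, sequencing
    depth 2×10⁶ per sample, planted tumor effect log2FC = 2 on 300 genes
    of which 50 are withheld from organoid profiles, and a 140-case /
    118-control plasma cohort with marker effect log2FC = 1.5.
    """

    n_genes: int = 2000
    n_clusters: int = 4
    markers_per_cluster: int = 50
    n_patients: int = 7
    library_size: int = 2_000_000
    nb_dispersion: float = 50.0
    tumor_effect_log2fc: float = 2.0
    n_tumor_up: int = 300
    n_lost: int = 50
    frac_caf_expressed: float = 0.6
    release_rates: Sequence[float] | None = None
    n_cases: int = 140
    n_controls: int = 118
    marker_effect_log2fc: float = 1.5
    seed: int = 0
    # generator internals, all config-exposed
    cells_per_cluster: int = 150
    cell_library_size: int = 5_000
    marker_fold: float = 16.0
    n_immune_clusters: int = 1
    blood_dilution: float = 0.1
    n_caf_samples: int = 4
    n_diagnostic_markers: int = 15
    base_log_sigma: float = 1.0
    patient_log_sigma: float = 0.1
    diag_biological_sigma: float = 1.0

    def validate(self) -> None:
        checks = [
            (self.n_genes > 0, "n_genes must be positive"),
            (self.n_clusters > 0, "n_clusters must be positive"),
            (self.markers_per_cluster > 0, "markers_per_cluster must be positive"),
            (self.n_patients > 0, "n_patients must be positive"),
            (self.library_size > 0, "library_size must be positive"),
            (self.nb_dispersion > 0, "nb_dispersion must be positive"),
            (self.tumor_effect_log2fc >= 0, "tumor_effect_log2fc must be nonnegative"),
            (self.n_tumor_up >= 0, "n_tumor_up must be nonnegative"),
            (self.n_lost >= 0, "n_lost must be nonnegative"),
            (self.n_lost <= self.n_tumor_up, "n_lost must not exceed n_tumor_up"),
            (0.0 <= self.frac_caf_expressed <= 1.0, "frac_caf_expressed must be in [0,1]"),
            (
                self.markers_per_cluster * self.n_clusters <= self.n_genes,
                "markers_per_cluster × n_clusters must not exceed n_genes",
            ),
            (self.n_cases >= 2, "n_cases must be ≥ 2"),
            (self.n_controls >= 2, "n_controls must be ≥ 2"),
            (self.cells_per_cluster >= 3, "cells_per_cluster must be ≥ 3"),
            (self.marker_fold >= 8, "marker_fold must be ≥ 8"),
            (0 <= self.n_immune_clusters <= self.n_clusters, "n_immune_clusters out of range"),
            (0.0 <= self.blood_dilution <= 1.0, "blood_dilution must be in [0,1]"),
            (self.n_caf_samples >= 1, "n_caf_samples must be ≥ 1"),
        ]
        if self.release_rates is not None:
            checks.append(
                (len(self.release_rates) == self.n_clusters, "release_rates length must equal n_clusters")
            )
            checks.append(
                (all(r > 0 for r in self.release_rates), "all release rates must be > 0")
            )
        for ok, msg in checks:
            if not ok:
                raise ConfigurationError(msg)

    def resolved_release_rates(self) -> np.ndarray:
        if self.release_rates is not None:
            return np.asarray(self.release_rates, dtype=float)
        if self.n_clusters == 1:
            return np.array([1.0])
        # distinct per-cluster rates spanning a 10× range, highest for the
        # CAF-like cluster-index-0... clusters are ordered Epithelial, CAF,
        # Endothelial, Immune; CAFs get the top rate, immune the lowest.
        rates = np.geomspace(5.0, 0.5, self.n_clusters)
        if self.n_clusters >= 2:
            # swap so CAF (index 1) is the strongest releaser, as observed
            # for per-cell sEV output in tumor tissue
            rates[[0, 1]] = rates[[1, 0]]
        return rates


def _cluster_names(k: int) -> list[str]:
    if k == len(_SEMANTIC_CLUSTERS):
        return list(_SEMANTIC_CLUSTERS)
    return [f"cluster{i}" for i in range(k)]


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, size_param: float) -> np.ndarray:
    """Negative binomial draws with mean mu and size (dispersion) size_param."""
    mu = np.maximum(mu, 0.0)
    p = size_param / (size_param + mu)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if pos.any():
        out[pos] = rng.negative_binomial(size_param, p[pos])
    return out


def _base_weights(rng: np.random.Generator, n_genes: int, sigma: float) -> np.ndarray:
    return rng.lognormal(mean=0.0, sigma=sigma, size=n_genes)


def simulate_reference(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.Series, CellTypeReference, GroundTruth]:
    """Generate a single-cell count matrix and its distilled reference.

    Returns
    -------
    (cells×genes counts, cluster labels per cell, CellTypeReference, GroundTruth)
        The CellTypeReference carries the *generative* cluster mean
        profiles (CPM scale), cell counts and immune flags; GroundTruth
        records per-cluster release rates and cell counts.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    genes = _gene_ids(config.n_genes)
    clusters = _cluster_names(config.n_clusters)

    base = _base_weights(rng, config.n_genes, config.base_log_sigma)
    order = rng.permutation(config.n_genes)
    marker_idx = {
        clusters[k]: order[
            k * config.markers_per_cluster : (k + 1) * config.markers_per_cluster
        ]
        for k in range(config.n_clusters)
    }

    profiles = np.tile(base[:, None], (1, config.n_clusters)).astype(float)
    for k, c in enumerate(clusters):
        profiles[marker_idx[c], k] *= config.marker_fold
    profiles /= profiles.sum(axis=0, keepdims=True)
    profiles_cpm = pd.DataFrame(profiles * 1e6, index=genes, columns=clusters)

    n_cells = config.cells_per_cluster
    labels = np.repeat(clusters, n_cells)
    counts = np.zeros((len(labels), config.n_genes), dtype=np.int64)
    for k, c in enumerate(clusters):
        mu = profiles[:, k] * config.cell_library_size
        block = _nb_sample(
            rng, np.tile(mu, (n_cells, 1)), config.nb_dispersion
        )
        counts[k * n_cells : (k + 1) * n_cells, :] = block

    cell_ids = [f"cell{i:05d}" for i in range(len(labels))]
    sc_counts = pd.DataFrame(counts, index=cell_ids, columns=genes)
    label_series = pd.Series(labels, index=cell_ids, name="cluster")

    immune = {c: False for c in clusters}
    if config.n_immune_clusters:
        for c in clusters[-config.n_immune_clusters :]:
            immune[c] = True

    cell_counts = {c: n_cells for c in clusters}
    reference = CellTypeReference(
        profiles=profiles_cpm, cell_counts=cell_counts, immune=immune
    )
    rates = config.resolved_release_rates()
    truth = GroundTruth(
        cluster_release_rates={c: float(r) for c, r in zip(clusters, rates)},
        cluster_cell_counts=dict(cell_counts),
    )
    return sc_counts, label_series, reference, truth


def expected_sev_shares(
    reference: CellTypeReference, truth: GroundTruth
) -> dict[str, float]:
    """Closed-form expected per-cluster share of bulk sEV cargo.

    share_k ∝ n_k · r_k · m̄_k where m̄_k is the total mean expression of
    cluster k's profile.
    """
    clusters = reference.clusters
    if set(truth.cluster_release_rates) != set(clusters) or set(
        truth.cluster_cell_counts
    ) != set(clusters):
        raise KeyError("truth cluster keys do not match the reference clusters")
    w = np.array(
        [
            truth.cluster_cell_counts[c]
            * truth.cluster_release_rates[c]
            * reference.profiles[c].sum()
            for c in clusters
        ],
        dtype=float,
    )
    if w.sum() <= 0:
        raise ValueError("all cluster contributions are zero")
    w /= w.sum()
    return {c: float(x) for c, x in zip(clusters, w)}


def simulate_tissue_bulk(
    reference: CellTypeReference,
    truth: GroundTruth,
    depth: int,
    seed: int,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """One bulk tissue sEV profile: cell-count- and release-weighted mixture.

    The bulk mean is ∝ Σ_k n_k·r_k·(cluster mean profile); counts are
    negative-binomial at the requested depth. The closed-form expected
    cluster shares are recorded in the returned truth's metadata.
    """
    shares = expected_sev_shares(reference, truth)
    clusters = reference.clusters
    w = np.array(
        [truth.cluster_cell_counts[c] * truth.cluster_release_rates[c] for c in clusters]
    )
    mix = reference.profiles.to_numpy() @ w
    mix = mix / mix.sum()
    rng = np.random.default_rng([seed, 1])
    counts = _nb_sample(rng, mix * depth, 50.0)
    values = pd.DataFrame({"bulk": counts}, index=reference.profiles.index)
    matrix = ExpressionMatrix(
        values,
        metadata=[SampleMetadata("bulk", "pool", "T")],
        kind="count",
    )
    new_truth = replace(truth, expected_sev_shares=shares)
    return matrix, new_truth


def _profile_with_effect(
    base_profile: np.ndarray, idx: np.ndarray, log2fc: float
) -> np.ndarray:
    prof = base_profile.copy()
    prof[idx] *= 2.0**log2fc
    return prof / prof.sum()


def simulate_paired_cohort(
    config: SimulationConfig,
    reference: CellTypeReference | None = None,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Paired multi-source cohort: T/N/O/B per patient plus CAF cultures.

    Planted structure (all recorded in the returned GroundTruth):

    * ``n_tumor_up`` genes get a log2 mean shift of ``tumor_effect_log2fc``
      in every patient's T profile relative to N;
    * ``n_lost`` of those carry the shift in T but *not* in O — the
      organoid-lost set;
    * O profiles are drawn from the tumor-epithelial cluster only;
    * a ``frac_caf_expressed`` fraction of the lost genes is expressed in
      CAF-culture profiles; the remaining lost genes are silenced there;
    * B (plasma) profiles are a ``blood_dilution`` convex mixture of the
      patient's T profile with the N background.

    Planted genes are drawn from non-marker genes so that the epithelial
    purity of O profiles does not confound the planted lost-set truth.
    """
    config.validate()
    if reference is None:
        _, _, reference, ref_truth = simulate_reference(config)
    else:
        ref_truth = GroundTruth(
            cluster_release_rates={
                c: float(r)
                for c, r in zip(reference.clusters, config.resolved_release_rates())
            },
            cluster_cell_counts=dict(reference.cell_counts),
        )
    rng = np.random.default_rng([config.seed, 2])
    genes = reference.profiles.index.to_numpy()
    clusters = reference.clusters
    profiles = reference.profiles.to_numpy() / 1e6  # back to relative scale

    # non-marker gene pool: markers are the top-specificity genes of each
    # cluster in the generative profiles
    marker_mask = np.zeros(len(genes), dtype=bool)
    for k in range(len(clusters)):
        ratio = profiles[:, k] / np.maximum(profiles.mean(axis=1), 1e-300)
        marker_mask |= ratio > 2.0
    pool = np.flatnonzero(~marker_mask)
    if len(pool) < config.n_tumor_up:
        raise ConfigurationError("not enough non-marker genes to plant tumor_up set")
    chosen = rng.choice(pool, size=config.n_tumor_up, replace=False)
    tumor_up_idx = np.sort(chosen)
    lost_idx = np.sort(rng.choice(tumor_up_idx, size=config.n_lost, replace=False))
    n_caf_expr = int(round(config.frac_caf_expressed * config.n_lost))
    caf_expr_idx = np.sort(rng.choice(lost_idx, size=n_caf_expr, replace=False))

    rates = np.array(
        [ref_truth.cluster_release_rates[c] for c in clusters], dtype=float
    )
    n_k = np.array([ref_truth.cluster_cell_counts[c] for c in clusters], dtype=float)
    w = n_k * rates
    tissue_mix = profiles @ w
    tissue_mix /= tissue_mix.sum()

    epi_idx = 0  # tumor-epithelial cluster is the first by construction
    epi_profile = profiles[:, epi_idx] / profiles[:, epi_idx].sum()

    caf_idx = 1 if len(clusters) > 1 else 0
    caf_profile = profiles[:, caf_idx].copy()
    silent = np.setdiff1d(lost_idx, caf_expr_idx)
    caf_profile[silent] = 0.0
    # guarantee the planted CAF-expressed genes are solidly detectable
    floor = np.median(caf_profile[caf_profile > 0])
    caf_profile[caf_expr_idx] = np.maximum(caf_profile[caf_expr_idx], floor)
    caf_profile /= caf_profile.sum()

    up_not_lost = np.setdiff1d(tumor_up_idx, lost_idx)

    columns: dict[str, np.ndarray] = {}
    metadata: list[SampleMetadata] = []
    for i in range(config.n_patients):
        pid = f"P{i + 1}"
        pat_effect = rng.lognormal(0.0, config.patient_log_sigma, size=len(genes))
        n_prof = tissue_mix * pat_effect
        n_prof /= n_prof.sum()
        t_prof = _profile_with_effect(n_prof, tumor_up_idx, config.tumor_effect_log2fc)
        o_base = epi_profile * pat_effect
        o_base /= o_base.sum()
        o_prof = _profile_with_effect(o_base, up_not_lost, config.tumor_effect_log2fc)
        b_prof = config.blood_dilution * t_prof + (1 - config.blood_dilution) * n_prof
        b_prof /= b_prof.sum()
        for src, prof in (("T", t_prof), ("N", n_prof), ("O", o_prof), ("B", b_prof)):
            sid = f"{pid}_{src}"
            columns[sid] = _nb_sample(
                rng, prof * config.library_size, config.nb_dispersion
            )
            metadata.append(SampleMetadata(sid, pid, src))

    for j in range(config.n_caf_samples):
        sid = f"CAF{j + 1}"
        columns[sid] = _nb_sample(
            rng, caf_profile * config.library_size, config.nb_dispersion
        )
        metadata.append(SampleMetadata(sid, f"CAFdonor{j + 1}", "CAF"))

    matrix = ExpressionMatrix(
        pd.DataFrame(columns, index=genes), metadata=metadata, kind="count"
    )
    truth = GroundTruth(
        tumor_up_genes=set(genes[tumor_up_idx]),
        lost_genes=set(genes[lost_idx]),
        caf_expressed_genes=set(genes[caf_expr_idx]),
        cluster_release_rates=dict(ref_truth.cluster_release_rates),
        cluster_cell_counts=dict(ref_truth.cluster_cell_counts),
    )
    return matrix, truth


def simulate_diagnostic_cohort(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Case/control plasma sEV cohort with planted marker effects.

    ``n_diagnostic_markers`` genes are shifted by ``marker_effect_log2fc``
    in cases; every other gene is exchangeable between groups. Library
    sizes vary log-normally around ``library_size`` so that analyses must
    normalize, and every gene carries per-person biological variability
    (log2-normal with sd ``diag_biological_sigma``) — without it, marker
    separation would be limited only by sequencing noise and per-gene
    AUCs would be unrealistically perfect.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 3])
    genes = np.array(_gene_ids(config.n_genes))
    base = _base_weights(rng, config.n_genes, config.base_log_sigma)
    base /= base.sum()
    marker_idx = np.sort(
        rng.choice(config.n_genes, size=config.n_diagnostic_markers, replace=False)
    )
    case_prof = _profile_with_effect(base, marker_idx, config.marker_effect_log2fc)

    columns: dict[str, np.ndarray] = {}
    metadata: list[SampleMetadata] = []
    for group, n, prof in (
        ("case", config.n_cases, case_prof),
        ("control", config.n_controls, base),
    ):
        for i in range(n):
            sid = f"{group}{i + 1:03d}"
            lib = config.library_size * rng.lognormal(0.0, 0.2)
            bio = np.exp2(
                rng.normal(0.0, config.diag_biological_sigma, size=config.n_genes)
            )
            columns[sid] = _nb_sample(rng, prof * bio * lib, config.nb_dispersion)
            metadata.append(SampleMetadata(sid, sid, "B", group=group))

    matrix = ExpressionMatrix(
        pd.DataFrame(columns, index=genes), metadata=metadata, kind="count"
    )
    truth = GroundTruth(diagnostic_markers=set(genes[marker_idx]))
    return matrix, truth


def simulate_intensity_groups(
    n_features: int = 2000,
    n_per_group: int = 5,
    n_up: int = 50,
    effect_log2fc: float = 2.0,
    sigma: float = 0.5,
    seed: int = 0,
) -> tuple[ExpressionMatrix, set[str]]:
    """Proteome-like log-normal intensity matrix with a planted up set.

    Two groups ("T" and "N" sources) of ``n_per_group`` samples each; the
    first ``n_up`` features get a log2 mean shift of ``effect_log2fc`` in
    the T group. Returns the intensity matrix and the planted up set.
    """
    if n_up > n_features:
        raise ConfigurationError("n_up must not exceed n_features")
    rng = np.random.default_rng([seed, 4])
    features = [f"prot{i:05d}" for i in range(n_features)]
    base_log = rng.normal(10.0, 2.0, size=n_features)
    up_idx = np.arange(n_up)
    cols: dict[str, np.ndarray] = {}
    metadata = []
    for g, src in (("T", "T"), ("N", "N")):
        for j in range(n_per_group):
            mu = base_log.copy()
            if src == "T":
                mu[up_idx] += effect_log2fc
            vals = np.exp2(mu + rng.normal(0.0, sigma, size=n_features))
            sid = f"{src}{j + 1}"
            cols[sid] = vals
            metadata.append(SampleMetadata(sid, f"Q{j + 1}", src))
    matrix = ExpressionMatrix(
        pd.DataFrame(cols, index=features), metadata=metadata, kind="intensity"
    )
    return matrix, {features[i] for i in up_idx}


def subset_by_source(matrix: ExpressionMatrix, source: str) -> ExpressionMatrix:
    """Restrict a cohort matrix to samples of one source code."""
    if matrix.metadata is None:
        raise ValueError("matrix has no sample metadata")
    ids = [s for s, m in matrix.metadata.items() if m.source == source]
    if not ids:
        raise ValueError(f"no samples of source {source!r}")
    return ExpressionMatrix(
        matrix.values[ids],
        metadata=[matrix.metadata[s] for s in ids],
        kind=matrix.kind,
    )
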