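"""Core in-memory containers shared across the pipeline.

The pipeline moves feature×sample matrices (RNA counts or protein
intensities), per-sample metadata, a cell-type reference distilled from a
single-cell experiment, and a handful of structured results between stages.
Everything here is a thin, validated wrapper over pandas/numpy objects so
that each stage can be used from Python without touching the CLI.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

SCHEMA_VERSION = "1.0"

SOURCE_CODES = ("T", "N", "O", "B", "CAF", "other")


class Direction(str, Enum):
    UP = "up"
    DOWN = "down"
    NS = "ns"


@dataclass(frozen=True)
class SampleMetadata:
    """Identity of one sample: who it came from and what it is.

    source uses the study's shorthand: T = tumor tissue, N = paired normal
    tissue, O = tumor organoid culture, B = plasma (blood), CAF =
    cancer-associated-fibroblast culture.
    """

    sample_id: str
    patient_id: str
    source: str
    group: str | None = None

    def __post_init__(self) -> None:
        if self.source not in SOURCE_CODES:
            raise ValueError(
                f"source {self.source!r} is not one of {SOURCE_CODES}"
            )


class ExpressionMatrix:
    """A features×samples numeric matrix with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with one column per sample id.
    metadata
        Per-sample :class:`SampleMetadata`, one per column of ``values``.
        Optional: matrices used as bare numeric tables (e.g. a CAF-culture
        matrix) may omit it.
    kind
        ``"count"`` for integer sequencing counts, ``"intensity"`` for
        continuous (e.g. proteomic) values.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        metadata: Iterable[SampleMetadata] | None = None,
        kind: str = "count",
    ) -> None:
        if kind not in ("count", "intensity"):
            raise ValueError(f"kind must be 'count' or 'intensity', got {kind!r}")
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        arr = values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("matrix contains non-finite values")
        if kind == "count":
            if (arr < 0).any():
                raise ValueError("negative values in a count matrix")
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("non-integer values in a count matrix")
        self.values = values
        self.kind = kind
        if metadata is not None:
            meta = list(metadata)
            ids = [m.sample_id for m in meta]
            if sorted(ids) != sorted(values.columns.tolist()):
                raise ValueError("metadata sample ids do not match matrix columns")
            if len(set(ids)) != len(ids):
                raise ValueError("duplicate sample ids in metadata")
            self.metadata = {m.sample_id: m for m in meta}
        else:
            self.metadata = None

    @property
    def feature_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    def library_sizes(self) -> pd.Series:
        return self.values.sum(axis=0)

    def cpm(self) -> pd.DataFrame:
        """Counts-per-million normalization (column-wise)."""
        lib = self.values.sum(axis=0)
        return self.values / lib * 1e6

    def samples_for(self, patient_id: str, source: str) -> list[str]:
        if self.metadata is None:
            raise ValueError("matrix has no sample metadata")
        return [
            s
            for s, m in self.metadata.items()
            if m.patient_id == patient_id and m.source == source
        ]

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ExpressionMatrix({len(self.values)} features × "
            f"{len(self.values.columns)} samples, kind={self.kind!r})"
        )


@dataclass
class CellTypeReference:
    """Per-cluster mean expression plus cluster-level annotation.

    profiles is genes×clusters mean expression on a counts-per-million
    scale; cell_counts is cells per cluster in the reference; immune flags
    which clusters are immune lineages.
    """

    profiles: pd.DataFrame
    cell_counts: dict[str, int]
    immune: dict[str, bool]

    def __post_init__(self) -> None:
        clusters = set(self.profiles.columns)
        if set(self.cell_counts) != clusters or set(self.immune) != clusters:
            raise ValueError("cluster annotation keys do not match profile columns")
        if any(n <= 0 for n in self.cell_counts.values()):
            raise ValueError("cluster cell counts must be positive")

    @property
    def clusters(self) -> list[str]:
        return self.profiles.columns.tolist()


@dataclass
class GroundTruth:
    """Planted truth emitted by the synthetic generators.

    The recovery oracle for every downstream stage: which genes were made
    tumor-up, which of those were withheld from organoid profiles (lost),
    which are expressed by CAFs, per-cluster sEV release rates and cell
    counts, and the diagnostic marker genes.
    """

    tumor_up_genes: set[str] = field(default_factory=set)
    lost_genes: set[str] = field(default_factory=set)
    caf_expressed_genes: set[str] = field(default_factory=set)
    cluster_release_rates: dict[str, float] = field(default_factory=dict)
    cluster_cell_counts: dict[str, int] = field(default_factory=dict)
    diagnostic_markers: set[str] = field(default_factory=set)
    expected_sev_shares: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.lost_genes <= self.tumor_up_genes:
            raise ValueError("lost_genes must be a subset of tumor_up_genes")
        if any(r < 0 for r in self.cluster_release_rates.values()):
            raise ValueError("release rates must be nonnegative")

    def to_dict(self) -> dict[str, Any]:
        return {
            "schema_version": SCHEMA_VERSION,
            "tumor_up_genes": sorted(self.tumor_up_genes),
            "lost_genes": sorted(self.lost_genes),
            "caf_expressed_genes": sorted(self.caf_expressed_genes),
            "cluster_release_rates": dict(self.cluster_release_rates),
            "cluster_cell_counts": dict(self.cluster_cell_counts),
            "diagnostic_markers": sorted(self.diagnostic_markers),
            "expected_sev_shares": dict(self.expected_sev_shares),
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "GroundTruth":
        return cls(
            tumor_up_genes=set(d.get("tumor_up_genes", ())),
            lost_genes=set(d.get("lost_genes", ())),
            caf_expressed_genes=set(d.get("caf_expressed_genes", ())),
            cluster_release_rates=dict(d.get("cluster_release_rates", {})),
            cluster_cell_counts={
                k: int(v) for k, v in d.get("cluster_cell_counts", {}).items()
            },
            diagnostic_markers=set(d.get("diagnostic_markers", ())),
            expected_sev_shares=dict(d.get("expected_sev_shares", {})),
        )


@dataclass
class DifferentialResult:
    """Per-feature differential outcome for one contrast.

    table has columns feature, fold_change, log2_fc, p_value, p_adjusted,
    direction; contrast records which samples and method produced it.
    """

    table: pd.DataFrame
    contrast: dict[str, Any]

    REQUIRED = ("feature", "fold_change", "log2_fc", "p_value", "p_adjusted", "direction")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"DifferentialResult table missing columns {missing}")

    @property
    def up_set(self) -> set[str]:
        t = self.table
        return set(t.loc[t["direction"] == Direction.UP.value, "feature"])

    @property
    def down_set(self) -> set[str]:
        t = self.table
        return set(t.loc[t["direction"] == Direction.DOWN.value, "feature"])

    @property
    def features(self) -> set[str]:
        return set(self.table["feature"])

    def to_dict(self) -> dict[str, Any]:
        return {
            "schema_version": SCHEMA_VERSION,
            "contrast": self.contrast,
            "records": self.table.to_dict(orient="records"),
        }


@dataclass
class SignatureSet:
    """A named feature set with per-patient support counts."""

    name: str
    members: set[str]
    support: dict[str, int]
    n_patients: int
    min_support: int
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.min_support < 1:
            raise ValueError("min_support must be ≥ 1")
        for f in self.members:
            s = self.support.get(f, 0)
            if s < self.min_support:
                raise ValueError(f"member {f} has support {s} < min_support")
            if s > self.n_patients:
                raise ValueError(f"support of {f} exceeds n_patients")

    def to_dict(self) -> dict[str, Any]:
        return {
            "schema_version": SCHEMA_VERSION,
            "name": self.name,
            "members": sorted(self.members),
            "support": {k: int(v) for k, v in sorted(self.support.items())},
            "n_patients": self.n_patients,
            "min_support": self.min_support,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SignatureSet":
        return cls(
            name=d["name"],
            members=set(d["members"]),
            support={k: int(v) for k, v in d["support"].items()},
            n_patients=int(d["n_patients"]),
            min_support=int(d["min_support"]),
            provenance=dict(d.get("provenance", {})),
        )


@dataclass
class SourceAttribution:
    """Cell-of-origin attribution of a bulk sEV profile.

    per_cluster has one row per cluster with cell_pct (share of reference
    cells), sev_pct (attributed share of bulk sEV cargo), per_cell_share
    (sev_pct / n_k) and release_index = log10(sev_pct / cell_pct).
    cw_fc is the per-gene per-cluster cell-weighted fold-change table
    (genes×clusters); proportions are the deconvolution estimates.
    """

    per_cluster: pd.DataFrame
    proportions: pd.Series | None = None
    cw_fc: pd.DataFrame | None = None
    cluster_ranking: list[str] | None = None
    immune_summary: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "schema_version": SCHEMA_VERSION,
            "per_cluster": self.per_cluster.reset_index()
            .rename(columns={"index": "cluster"})
            .to_dict(orient="records"),
            "immune_summary": dict(self.immune_summary),
        }
        if self.proportions is not None:
            d["proportions"] = {k: float(v) for k, v in self.proportions.items()}
        if self.cluster_ranking is not None:
            d["cluster_ranking"] = list(self.cluster_ranking)
        if self.cw_fc is not None:
            d["cw_fc"] = {
                "genes": self.cw_fc.index.tolist(),
                "clusters": self.cw_fc.columns.tolist(),
                "values": self.cw_fc.to_numpy().tolist(),
            }
        return d


@dataclass
class EnrichmentResult:
    """Over-representation outcome: one row per gene set."""

    table: pd.DataFrame
    universe_size: int
    query_size: int

    def to_dict(self) -> dict[str, Any]:
        return {
            "schema_version": SCHEMA_VERSION,
            "universe_size": self.universe_size,
            "query_size": self.query_size,
            "records": self.table.to_dict(orient="records"),
        }


@dataclass
class DiagnosticReport:
    """Biomarker funnel plus per-gene and model-level ROC performance."""

    funnel_stages: list[dict[str, Any]] = field(default_factory=list)
    per_gene_auc: dict[str, dict[str, float]] = field(default_factory=dict)
    model: dict[str, Any] = field(default_factory=dict)
    split: dict[str, Any] = field(default_factory=dict)
    train_auc: dict[str, float] = field(default_factory=dict)
    validation_auc: dict[str, float] = field(default_factory=dict)
    seed: int | None = None

    def to_dict(self) -> dict[str, Any]:
        return {
            "schema_version": SCHEMA_VERSION,
            "funnel_stages": self.funnel_stages,
            "per_gene_auc": self.per_gene_auc,
            "model": self.model,
            "split": self.split,
            "train_auc": self.train_auc,
            "validation_auc": self.validation_auc,
            "seed": self.seed,
        }


@dataclass
class LostSignature:
    """Per-patient lost sets, their consensus, and the CAF overlay."""

    per_patient_lost: dict[str, set[str]]
    consensus: SignatureSet
    caf_overlap: set[str] = field(default_factory=set)
    caf_detection_rule: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        union: set[str] = set()
        for s in self.per_patient_lost.values():
            union |= s
        if not self.consensus.members <= union:
            raise ValueError("consensus members must come from per-patient lost sets")
        if not self.caf_overlap <= self.consensus.members:
            raise ValueError("caf_overlap must be a subset of the consensus")

    def to_dict(self) -> dict[str, Any]:
        return {
            "schema_version": SCHEMA_VERSION,
            "per_patient_lost": {k: sorted(v) for k, v in self.per_patient_lost.items()},
            "consensus": self.consensus.to_dict(),
            "caf_overlap": sorted(self.caf_overlap),
            "caf_detection_rule": self.caf_detection_rule,
        }
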