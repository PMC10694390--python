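"""The "lost in vitro" signature: three-source set algebra plus CAF overlay.

For each patient with complete T/N/O samples, the genes called up in the
tumor-vs-normal contrast but *not* up in the organoid-vs-normal contrast
form that patient's lost set — cargo present in the tissue sEV pool that
the in-vitro model fails to reproduce. The consensus keeps genes lost in
at least ``min_support`` patients. The CAF overlay then asks what fraction
of the consensus is expressed by pure CAF-culture sEVs, the study's route
to attributing the lost cargo to stromal cells.
"""

from __future__ import annotations

from typing import Mapping

from .containers import (
    DifferentialResult,
    ExpressionMatrix,
    LostSignature,
    SignatureSet,
)


def lost_per_patient(
    up_t_vs_n: DifferentialResult, up_o_vs_n: DifferentialResult
) -> set[str]:
    """Genes up in T-vs-N but not up in O-vs-N for one patient.

    "Not upregulated" means failing the joint fold-change/p-value up-call
    under the same thresholds used for the T contrast.
    """
    if up_t_vs_n.features != up_o_vs_n.features:
        raise ValueError("the two contrasts cover different feature universes")
    return up_t_vs_n.up_set - up_o_vs_n.up_set


def lost_consensus(
    per_patient: Mapping[str, set[str]], min_support: int = 4
) -> SignatureSet:
    """Features lost in at least ``min_support`` patients."""
    if min_support < 1:
        raise ValueError("min_support must be ≥ 1")
    if min_support > len(per_patient):
        raise ValueError(
            f"min_support={min_support} exceeds the {len(per_patient)} patients present"
        )
    support: dict[str, int] = {}
    for genes in per_patient.values():
        for g in genes:
            support[g] = support.get(g, 0) + 1
    members = {g for g, s in support.items() if s >= min_support}
    return SignatureSet(
        name="lost_consensus",
        members=members,
        support={g: support[g] for g in members},
        n_patients=len(per_patient),
        min_support=min_support,
        provenance={"rule": "up in T:N and not up in O:N, per patient"},
    )


def caf_overlay(
    consensus: SignatureSet,
    caf_matrix: ExpressionMatrix,
    min_samples: int | None = None,
    floor_cpm: float = 1.0,
) -> tuple[set[str], float]:
    """Overlap of the lost consensus with CAF-expressed features.

    A feature counts as CAF-expressed when its CPM is at least
    ``floor_cpm`` in at least ``min_samples`` CAF samples (default: all of
    them). Returns the overlap set and the overlap fraction of the
    consensus (0.0 for an empty consensus).
    """
    if floor_cpm < 0:
        raise ValueError("floor_cpm must be nonnegative")
    n_samples = len(caf_matrix.sample_ids)
    if min_samples is None:
        min_samples = n_samples
    if min_samples < 1 or min_samples > n_samples:
        raise ValueError(
            f"min_samples={min_samples} out of range for {n_samples} CAF samples"
        )
    cpm = caf_matrix.cpm()
    expressed = set(cpm.index[(cpm >= floor_cpm).sum(axis=1) >= min_samples])
    overlap = consensus.members & expressed
    fraction = len(overlap) / len(consensus.members) if consensus.members else 0.0
    return overlap, fraction


def build_lost_signature(
    t_contrasts: Mapping[str, DifferentialResult],
    o_contrasts: Mapping[str, DifferentialResult],
    caf_matrix: ExpressionMatrix | None = None,
    min_support: int = 4,
    caf_min_samples: int | None = None,
    caf_floor_cpm: float = 1.0,
) -> LostSignature:
    """End-to-end lost-signature construction over a patient mapping."""
    if set(t_contrasts) != set(o_contrasts):
        raise ValueError("T and O contrasts must cover the same patients")
    per_patient = {
        pid: lost_per_patient(t_contrasts[pid], o_contrasts[pid])
        for pid in t_contrasts
    }
    consensus = lost_consensus(per_patient, min_support=min_support)
    overlap: set[str] = set()
    rule: dict = {}
    if caf_matrix is not None:
        overlap, _ = caf_overlay(
            consensus, caf_matrix, min_samples=caf_min_samples, floor_cpm=caf_floor_cpm
        )
        rule = {
            "min_samples": caf_min_samples
            if caf_min_samples is not None
            else len(caf_matrix.sample_ids),
            "floor": caf_floor_cpm,
        }
    return LostSignature(
        per_patient_lost=per_patient,
        consensus=consensus,
        caf_overlap=overlap,
        caf_detection_rule=rule,
    )
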