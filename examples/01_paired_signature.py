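"""Paired tumor/normal sEV contrasts and the majority-vote signature.

Simulates a 7-patient cohort with 300 planted tumor-up genes, runs the
exact no-replicate test per patient, and votes the per-patient up-calls
into a cancer-specific signature (kept if up in ≥4 of 7 patients).
"""

from sevscape import pairdiff
from sevscape.synth import SimulationConfig, simulate_paired_cohort

cfg = SimulationConfig(seed=1)
cohort, truth = simulate_paired_cohort(cfg)

results = [
    pairdiff.per_patient_contrast(cohort, f"P{i+1}", "T", "N",
                                  fc_threshold=1.5, alpha=0.05)
    for i in range(cfg.n_patients)
]
signature = pairdiff.majority_vote(results, min_support=4, name="cancer_specific")

recovered = len(signature.members & truth.tumor_up_genes)
print(f"signature size: {len(signature.members)}")
print(f"planted tumor-up genes recovered: {recovered}/{cfg.n_tumor_up}")
# The signature is the set of genes consistently enriched in tumor-tissue
# sEVs; with the planted effect (log2FC=2) nearly all 300 should be found
# and few noise genes should sneak in.

stat, p = pairdiff.sharing_test(27, 5354, 418, 36173)
print(f"mRNA vs microRNA sharing chi-square: {stat:.2f}, p = {p:.2e}")
# A small p means the two cargo classes differ in how much of their
# repertoire is tumor-enriched (microRNAs are more shared between tumor
# and normal tissue than mRNAs).
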