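import numpy as np
import pandas as pd
import pytest

from sevscape import pairdiff
from sevscape.synth import (
    SimulationConfig,
    simulate_paired_cohort,
    simulate_reference,
)


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def reference_bundle(default_config):
    """(single-cell counts, labels, CellTypeReference, GroundTruth) at defaults."""
    return simulate_reference(default_config)


@pytest.fixture(scope="session")
def cohort_bundle(default_config, reference_bundle):
    """(cohort ExpressionMatrix, GroundTruth) for the default paired design."""
    _, _, reference, _ = reference_bundle
    return simulate_paired_cohort(default_config, reference)


@pytest.fixture(scope="session")
def patient_contrasts(cohort_bundle):
    """T-vs-N and O-vs-N exact contrasts for every patient."""
    cohort, _ = cohort_bundle
    patients = sorted({m.patient_id for m in cohort.metadata.values() if m.source == "T"})
    t = {p: pairdiff.per_patient_contrast(cohort, p, "T", "N") for p in patients}
    o = {p: pairdiff.per_patient_contrast(cohort, p, "O", "N") for p in patients}
    return t, o


def exact_binomial_oracle(x: int, n: int, pr: float) -> float:
    """Independent enumeration oracle for the two-sided exact test.

    Sums Binomial(n, pr) point probabilities over every outcome whose pmf
    does not exceed that of the observed count (method of small p-values,
    with the same 1+1e-7 tie tolerance the implementation documents).
    """
    from scipy.stats import binom

    if n == 0:
        return 1.0
    pmf = binom.pmf(np.arange(n + 1), n, pr)
    return float(min(1.0, pmf[pmf <= pmf[x] * (1 + 1e-7)].sum()))


def pair_counting_auc(values, labels) -> float:
    """Exhaustive case-control pair counting: ties count one half."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    pos = values[labels == 1]
    neg = values[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))
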