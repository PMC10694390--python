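"""Differential testing for sEV profiles.

Two regimes are covered:

* no-replicate pairs (one tumor-tissue sEV library against its paired
  normal-tissue library from the same patient) — handled by an exact
  conditioned-binomial test on the two library counts, the standard exact
  choice for comparing two sequencing libraries without replicates;
* replicated groups (e.g. proteomic intensities, tumor vs normal sources)
  — handled by Welch's t-test on the log scale with Benjamini–Hochberg
  adjustment.

On top of these sit the per-patient contrast driver, the majority-vote
signature across patients, and the chi-square test for whether two feature
classes (mRNA vs microRNA) share cargo between tumor and normal at
different rates.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import (
    DifferentialResult,
    Direction,
    ExpressionMatrix,
    SignatureSet,
)

# Relative tolerance used when comparing point-probabilities while summing
# the two-sided rejection region; guards against ties lost to rounding
# (same convention as R's binom.test).
_REL_TOL = 1.0 + 1e-7

DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_DETECTION_FLOOR = 5


def _ac_pvalues(x: np.ndarray, n: np.ndarray, pr: float) -> np.ndarray:
    """Two-sided exact binomial p-values by the method of small p-values.

    For each feature, conditional on the total count n = x + y, x follows
    Binomial(n, pr) under the null of equal relative abundance, where
    pr = N_A / (N_A + N_B) is set by the two library sizes. The two-sided
    p-value sums Pr(k) over every outcome k whose point-probability does
    not exceed that of the observed x. The binomial pmf is unimodal, so
    the rejection region is a pair of tails whose inner boundaries are
    located by vectorized bisection rather than full enumeration.
    """
    x = np.asarray(x, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    p = np.ones(x.shape, dtype=float)

    live = n > 0
    if not live.any():
        return p

    px = stats.binom.pmf(x, n, pr) * _REL_TOL
    mode = np.floor((n + 1) * pr).astype(np.int64)
    mode = np.minimum(mode, n)
    pmode = stats.binom.pmf(mode, n, pr)

    # If the modal probability itself is within tolerance of px, every
    # outcome is in the rejection region: p = 1.
    active = live & (pmode > px)
    if not active.any():
        return p

    lower = active & (x < mode)   # observed in the left tail
    upper = active & (x > mode)   # observed in the right tail

    out = np.zeros(x.shape, dtype=float)

    if lower.any():
        xl, nl, pxl = x[lower], n[lower], px[lower]
        left = stats.binom.cdf(xl, nl, pr)
        # smallest k in (mode, n] with pmf(k) <= px
        lo = mode[lower].copy()
        hi = nl + 1
        while (hi - lo > 1).any():
            mid = (lo + hi) // 2
            ok = stats.binom.pmf(mid, nl, pr) <= pxl
            hi = np.where(ok, mid, hi)
            lo = np.where(ok, lo, mid)
        right = np.where(hi <= nl, stats.binom.sf(hi - 1, nl, pr), 0.0)
        out[lower] = left + right

    if upper.any():
        xu, nu, pxu = x[upper], n[upper], px[upper]
        right = stats.binom.sf(xu - 1, nu, pr)
        # largest k in [0, mode) with pmf(k) <= px
        lo = np.full(xu.shape, -1, dtype=np.int64)
        hi = mode[upper].copy()
        while (hi - lo > 1).any():
            mid = (lo + hi) // 2
            ok = stats.binom.pmf(mid, nu, pr) <= pxu
            lo = np.where(ok, mid, lo)
            hi = np.where(ok, hi, mid)
        left = np.where(lo >= 0, stats.binom.cdf(np.maximum(lo, 0), nu, pr), 0.0)
        left = np.where(lo >= 0, left, 0.0)
        out[upper] = left + right

    p[active] = np.minimum(out[active], 1.0)
    return p


def single_sample_test(
    x: int,
    y: int,
    n_a: float,
    n_b: float,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[float, float]:
    """Exact two-library test for one feature, no replicates.

    Parameters
    ----------
    x, y
        Raw counts of the feature in library A and library B.
    n_a, n_b
        Total library sizes (total counts) of A and B.
    pseudocount
        Added to both counts before forming the fold change so zeros do
        not yield infinite ratios.

    Returns
    -------
    (fold_change, p_value)
        Linear-scale library-size-normalized fold change A/B, and the
        two-sided exact conditioned-binomial p-value.
    """
    if x < 0 or y < 0 or x != int(x) or y != int(y):
        raise ValueError("counts must be nonnegative integers")
    if n_a <= 0 or n_b <= 0:
        raise ValueError("library sizes must be positive")
    fc = ((x + pseudocount) / n_a) / ((y + pseudocount) / n_b)
    pr = n_a / (n_a + n_b)
    p = float(_ac_pvalues(np.array([x]), np.array([x + y]), pr)[0])
    return fc, p


def _directions(
    fc: np.ndarray, p: np.ndarray, tested: np.ndarray, fc_threshold: float, alpha: float
) -> np.ndarray:
    direction = np.full(fc.shape, Direction.NS.value, dtype=object)
    sig = tested & (p < alpha)
    direction[sig & (fc > fc_threshold)] = Direction.UP.value
    with np.errstate(divide="ignore"):
        down_cut = 1.0 / fc_threshold if fc_threshold > 0 else np.inf
    direction[sig & (fc < down_cut)] = Direction.DOWN.value
    return direction


def pairwise_exact_table(
    counts_a: pd.Series,
    counts_b: pd.Series,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    detection_floor: int = DEFAULT_DETECTION_FLOOR,
    contrast: Mapping | None = None,
) -> DifferentialResult:
    """Exact test applied feature-wise to two aligned count vectors.

    Features with raw count below ``detection_floor`` in both samples are
    reported but marked ``ns`` (the exact test makes trivial calls at tiny
    counts). BH-adjusted p-values are always computed alongside raw ones;
    the up/down thresholds are applied to raw p, mirroring common practice
    for per-patient screens, and the adjusted values are reported for the
    caller to use instead if desired.
    """
    if not counts_a.index.equals(counts_b.index):
        raise ValueError("count vectors must share an identical feature index")
    x = counts_a.to_numpy()
    y = counts_b.to_numpy()
    if (x < 0).any() or (y < 0).any():
        raise ValueError("counts must be nonnegative")
    n_a = float(x.sum())
    n_b = float(y.sum())
    if n_a <= 0 or n_b <= 0:
        raise ValueError("each sample must have positive total counts")

    xi = np.round(x).astype(np.int64)
    yi = np.round(y).astype(np.int64)
    tested = (xi >= detection_floor) | (yi >= detection_floor)

    fc = ((x + pseudocount) / n_a) / ((y + pseudocount) / n_b)
    pr = n_a / (n_a + n_b)
    p = np.ones(len(x))
    if tested.any():
        p[tested] = _ac_pvalues(xi[tested], xi[tested] + yi[tested], pr)

    p_adj = np.ones(len(x))
    if tested.any():
        p_adj[tested] = multipletests(p[tested], method="fdr_bh")[1]

    direction = _directions(fc, p, tested, fc_threshold, alpha)
    table = pd.DataFrame(
        {
            "feature": counts_a.index,
            "fold_change": fc,
            "log2_fc": np.log2(fc),
            "p_value": p,
            "p_adjusted": p_adj,
            "direction": direction,
            "tested": tested,
        }
    )
    meta = dict(contrast or {})
    meta.setdefault("method", "exact-conditioned-binomial")
    meta.setdefault("fc_threshold", fc_threshold)
    meta.setdefault("alpha", alpha)
    return DifferentialResult(table=table, contrast=meta)


def per_patient_contrast(
    cohort: ExpressionMatrix,
    patient: str,
    source_a: str,
    source_b: str,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    detection_floor: int = DEFAULT_DETECTION_FLOOR,
) -> DifferentialResult:
    """Exact A-vs-B contrast for one patient's paired samples."""
    ids_a = cohort.samples_for(patient, source_a)
    ids_b = cohort.samples_for(patient, source_b)
    if len(ids_a) != 1:
        raise ValueError(
            f"patient {patient!r} has {len(ids_a)} samples of source {source_a!r}; need exactly 1"
        )
    if len(ids_b) != 1:
        raise ValueError(
            f"patient {patient!r} has {len(ids_b)} samples of source {source_b!r}; need exactly 1"
        )
    return pairwise_exact_table(
        cohort.values[ids_a[0]],
        cohort.values[ids_b[0]],
        fc_threshold=fc_threshold,
        alpha=alpha,
        pseudocount=pseudocount,
        detection_floor=detection_floor,
        contrast={
            "patient": patient,
            "numerator": ids_a[0],
            "denominator": ids_b[0],
            "sources": f"{source_a}:{source_b}",
        },
    )


def majority_vote(
    per_patient: Sequence[DifferentialResult],
    min_support: int,
    name: str = "signature",
) -> SignatureSet:
    """Features called up in at least ``min_support`` patients.

    The study's rule "upregulated in more than half (4 of 7)" corresponds
    to min_support=4 with 7 patients.
    """
    if min_support < 1:
        raise ValueError("min_support must be ≥ 1")
    if len(per_patient) == 0:
        raise ValueError("need at least one per-patient result")
    if min_support > len(per_patient):
        raise ValueError("min_support exceeds the number of patients")
    support: dict[str, int] = {}
    for res in per_patient:
        for f in res.up_set:
            support[f] = support.get(f, 0) + 1
    members = {f for f, s in support.items() if s >= min_support}
    return SignatureSet(
        name=name,
        members=members,
        support={f: support[f] for f in members},
        n_patients=len(per_patient),
        min_support=min_support,
        provenance={"rule": "direction==up per patient", "vote": f">={min_support}"},
    )


def sharing_test(
    up_a: int, total_a: int, up_b: int, total_b: int
) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) on a 2×2 table.

    Compares the fraction of upregulated features between two feature
    classes, e.g. 27/5354 microRNAs vs 418/36173 mRNAs: a small p-value
    means the two classes share tumor/normal cargo at different rates.
    """
    for up, tot in ((up_a, total_a), (up_b, total_b)):
        if tot <= 0 or up < 0 or up > tot:
            raise ValueError("need 0 ≤ up ≤ total and total > 0")
    obs = np.array(
        [[up_a, total_a - up_a], [up_b, total_b - up_b]], dtype=float
    )
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    exp = row @ col / obs.sum()
    if (exp == 0).any():
        raise ValueError("degenerate 2×2 table: an expected cell is zero")
    stat = float(((obs - exp) ** 2 / exp).sum())
    p = float(stats.chi2.sf(stat, df=1))
    return stat, p


def group_test(
    matrix: ExpressionMatrix,
    groups: Mapping[str, str] | pd.Series,
    numerator: str,
    denominator: str,
    fc_threshold: float = 4.0,
    alpha: float = 0.05,
    scale: str = "log_intensity",
    use_adjusted: bool = False,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> DifferentialResult:
    """Welch two-sided t-test between two sample groups.

    For ``scale="log_intensity"`` the matrix holds positive intensities
    that are log2-transformed before testing; for ``scale="count"`` counts
    are converted to log2-CPM with a pseudocount first. The fold change is
    the ratio of group geometric means. Benjamini–Hochberg adjusted
    p-values are always reported; direction thresholds use raw p by
    default and adjusted p when ``use_adjusted`` is set.
    """
    if scale not in ("log_intensity", "count"):
        raise ValueError("scale must be 'log_intensity' or 'count'")
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    ids_a = [s for s in matrix.sample_ids if groups.get(s) == numerator]
    ids_b = [s for s in matrix.sample_ids if groups.get(s) == denominator]
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError("each group needs at least 2 samples")

    if scale == "count":
        logm = np.log2(matrix.cpm() + pseudocount)
    else:
        vals = matrix.values
        if (vals.to_numpy() < 0).any():
            raise ValueError("intensities must be nonnegative")
        logm = np.log2(vals + pseudocount)

    a = logm[ids_a].to_numpy()
    b = logm[ids_b].to_numpy()
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    # Zero-variance-in-both-groups features have an undefined statistic;
    # report them as maximally null.
    p = np.where(np.isfinite(p), p, 1.0)
    log2_fc = a.mean(axis=1) - b.mean(axis=1)
    fc = np.exp2(log2_fc)
    p_adj = multipletests(p, method="fdr_bh")[1]
    p_for_calls = p_adj if use_adjusted else p
    tested = np.ones(len(fc), dtype=bool)
    direction = _directions(fc, p_for_calls, tested, fc_threshold, alpha)
    table = pd.DataFrame(
        {
            "feature": matrix.feature_ids,
            "fold_change": fc,
            "log2_fc": log2_fc,
            "p_value": p,
            "p_adjusted": p_adj,
            "direction": direction,
            "tested": tested,
        }
    )
    return DifferentialResult(
        table=table,
        contrast={
            "numerator": ids_a,
            "denominator": ids_b,
            "method": "welch-t",
            "scale": scale,
            "fc_threshold": fc_threshold,
            "alpha": alpha,
            "use_adjusted": use_adjusted,
        },
    )
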