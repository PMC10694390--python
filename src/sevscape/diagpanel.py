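"""Circulating-biomarker funnel and diagnostic classifier.

The funnel narrows a tissue-derived cancer signature to candidates usable
in blood: genes detected in enough plasma (B) sEV samples, then
intersected with an externally supplied list of plasma-exosome-up genes
and with a tissue-expression-up list (stand-ins for database contrasts).
Each candidate is scored by ROC AUC with a DeLong confidence interval;
the panel is then combined in a maximum-margin (SVM) classifier whose
hyperparameters are chosen by internal cross-validation on a stratified
training split, and evaluated on the held-out validation split with
stratified-bootstrap confidence intervals.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .containers import DiagnosticReport, ExpressionMatrix, SignatureSet

DEFAULT_COST_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)
DEFAULT_GAMMA_GRID = ("scale", 0.01, 0.1, 1.0)


def funnel(
    cancer_sig: SignatureSet | Iterable[str],
    b_matrix: ExpressionMatrix,
    detect_min_samples: int,
    external_up: Iterable[str],
    tissue_up: Iterable[str],
    detect_floor: float = 1.0,
) -> DiagnosticReport:
    """Three-stage candidate funnel.

    Stage 1 keeps signature genes with raw count ≥ ``detect_floor`` in at
    least ``detect_min_samples`` plasma samples; stages 2 and 3 intersect
    with the external plasma-up and tissue-up lists. Final membership is
    a plain triple intersection — stage order only affects the logged
    stage-by-stage counts.
    """
    members = set(cancer_sig.members if isinstance(cancer_sig, SignatureSet) else cancer_sig)
    external_up = set(external_up)
    tissue_up = set(tissue_up)
    if not external_up or not tissue_up:
        raise ValueError("external_up and tissue_up lists must be nonempty")
    n_samples = len(b_matrix.sample_ids)
    if detect_min_samples > n_samples:
        raise ValueError(
            f"detect_min_samples={detect_min_samples} exceeds the {n_samples} plasma samples"
        )
    detected_counts = (b_matrix.values >= detect_floor).sum(axis=1)
    detected = set(detected_counts.index[detected_counts >= detect_min_samples])

    stages = []
    current = members
    for stage_name, rule, keep in (
        (
            "detected_in_plasma",
            f"count ≥ {detect_floor} in ≥ {detect_min_samples}/{n_samples} B samples",
            detected,
        ),
        ("external_plasma_up", "∩ external plasma-up list", external_up),
        ("tissue_up", "∩ tissue-up list", tissue_up),
    ):
        nxt = current & keep
        stages.append(
            {
                "stage_name": stage_name,
                "rule": rule,
                "n_in": len(current),
                "n_out": len(nxt),
                "members": sorted(nxt),
            }
        )
        current = nxt
    return DiagnosticReport(funnel_stages=stages)


def roc_auc(
    values: Sequence[float], labels: Sequence[int]
) -> tuple[float, float, float]:
    """AUC by the rank (Mann–Whitney) statistic with a DeLong 95% CI.

    Ties between a case and a control count one half. Labels are binary
    with 1 = case; both classes must be present.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    if set(np.unique(y)) - {0, 1, True, False}:
        raise ValueError("labels must be binary 0/1")
    pos = v[y == 1]
    neg = v[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    auc = float(psi.mean())
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    s10 = v10.var(ddof=1) if len(pos) > 1 else 0.0
    s01 = v01.var(ddof=1) if len(neg) > 1 else 0.0
    se = float(np.sqrt(s10 / len(pos) + s01 / len(neg)))
    z = stats.norm.ppf(0.975)
    return auc, max(0.0, auc - z * se), min(1.0, auc + z * se)


def per_gene_auc(
    matrix: ExpressionMatrix,
    labels: Mapping[str, int] | pd.Series,
    genes: Iterable[str] | None = None,
    use_cpm: bool = True,
) -> dict[str, dict[str, float]]:
    """ROC AUC (+DeLong CI) of each gene's normalized abundance."""
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    y = labels.reindex(matrix.sample_ids).to_numpy()
    data = matrix.cpm() if use_cpm else matrix.values
    genes = list(genes) if genes is not None else matrix.feature_ids
    out = {}
    for g in genes:
        auc, lo, hi = roc_auc(data.loc[g].to_numpy(), y)
        out[g] = {"auc": auc, "ci_low": lo, "ci_high": hi}
    return out


def _bootstrap_auc_ci(
    values: np.ndarray, y: np.ndarray, rng: np.random.Generator, n_boot: int = 2000
) -> tuple[float, float]:
    """Stratified bootstrap percentile CI for the AUC of a score vector."""
    pos = values[y == 1]
    neg = values[y == 0]
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        ps = rng.choice(pos, size=len(pos), replace=True)
        ns = rng.choice(neg, size=len(neg), replace=True)
        gt = (ps[:, None] > ns[None, :]).mean()
        eq = (ps[:, None] == ns[None, :]).mean()
        aucs[b] = gt + 0.5 * eq
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


def train_signature(
    matrix: ExpressionMatrix,
    labels: Mapping[str, int] | pd.Series,
    panel: Sequence[str],
    ratio: float = 0.7,
    cv_folds: int = 5,
    seed: int = 0,
    cost_grid: Sequence[float] = DEFAULT_COST_GRID,
    gamma_grid: Sequence = DEFAULT_GAMMA_GRID,
    n_boot: int = 2000,
    split_ids: tuple[Sequence[str], Sequence[str]] | None = None,
) -> DiagnosticReport:
    """Maximum-margin diagnostic signature with internal cross-validation.

    The cohort is split into stratified training/validation sets at
    ``ratio``; features (log2 CPM of panel genes) are standardized on
    training statistics only; linear and RBF kernels over the cost (and
    RBF width) grids compete by cross-validated AUC on the training set
    alone; the winner's decision values give the train and validation
    AUCs with stratified-bootstrap 95% CIs. Validation samples never
    touch model selection.
    """
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    y = labels.reindex(matrix.sample_ids).astype(int)
    if y.isna().any():
        raise ValueError("every sample needs a binary label")
    counts = y.value_counts()
    if counts.min() < 10:
        raise ValueError("need ≥ 10 samples per class")
    missing = [g for g in panel if g not in matrix.values.index]
    if missing:
        raise ValueError(f"panel genes absent from the matrix: {missing[:5]}")
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0,1)")

    x = np.log2(matrix.cpm().loc[list(panel)].T.to_numpy() + 0.5)
    yv = y.to_numpy()
    sample_ids = np.array(matrix.sample_ids)

    idx = np.arange(len(yv))
    if split_ids is not None:
        # a predetermined split (e.g. to hold the partition fixed across
        # label perturbations); must cover all samples disjointly
        pos = {s: i for i, s in enumerate(sample_ids)}
        train_idx = np.array([pos[s] for s in split_ids[0]])
        val_idx = np.array([pos[s] for s in split_ids[1]])
        if set(train_idx) & set(val_idx) or len(train_idx) + len(val_idx) != len(yv):
            raise ValueError("split_ids must partition the samples")
    else:
        train_idx, val_idx = train_test_split(
            idx, train_size=ratio, stratify=yv, random_state=seed
        )
    min_class_train = min(np.bincount(yv[train_idx]))
    if min_class_train < cv_folds:
        raise ValueError(
            f"smallest training class ({min_class_train}) is below cv_folds={cv_folds}"
        )

    param_grid = [
        {"svc__kernel": ["linear"], "svc__C": list(cost_grid)},
        {
            "svc__kernel": ["rbf"],
            "svc__C": list(cost_grid),
            "svc__gamma": list(gamma_grid),
        },
    ]
    pipe = Pipeline([("scale", StandardScaler()), ("svc", SVC())])
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(pipe, param_grid, scoring="roc_auc", cv=cv, refit=True)
    search.fit(x[train_idx], yv[train_idx])
    model = search.best_estimator_

    scores_train = model.decision_function(x[train_idx])
    scores_val = model.decision_function(x[val_idx])
    auc_train, _, _ = roc_auc(scores_train, yv[train_idx])
    auc_val, _, _ = roc_auc(scores_val, yv[val_idx])
    rng = np.random.default_rng([seed, 5])
    tr_lo, tr_hi = _bootstrap_auc_ci(scores_train, yv[train_idx], rng, n_boot)
    va_lo, va_hi = _bootstrap_auc_ci(scores_val, yv[val_idx], rng, n_boot)

    best = {k.replace("svc__", ""): v for k, v in search.best_params_.items()}
    return DiagnosticReport(
        per_gene_auc={},
        model={
            "kernel": best.get("kernel"),
            "hyperparameters": best,
            "cv_folds": cv_folds,
            "cv_grid": {
                "cost": list(cost_grid),
                "gamma": [str(g) for g in gamma_grid],
            },
            "cv_auc": float(search.best_score_),
            "panel": list(panel),
        },
        split={
            "train_ids": sample_ids[train_idx].tolist(),
            "validation_ids": sample_ids[val_idx].tolist(),
            "ratio": ratio,
        },
        train_auc={"auc": auc_train, "ci_low": tr_lo, "ci_high": tr_hi},
        validation_auc={"auc": auc_val, "ci_low": va_lo, "ci_high": va_hi},
        seed=seed,
    )


def roc_points(values: Sequence[float], labels: Sequence[int]) -> pd.DataFrame:
    """ROC curve points (fpr, tpr, threshold) for export."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(np.asarray(labels), np.asarray(values, dtype=float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
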