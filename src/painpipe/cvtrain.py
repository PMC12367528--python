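"""Repeated nested cross-validated ridge (L2) logistic classification.

The estimator mirrors the standard biobank-scale biomarker recipe: stratified
outer folds provide unbiased validation scores, an inner stratified CV selects
the L2 penalty from random log-uniform draws by AUC, and the confound
residualizer is fit on the outer-training rows only and applied to both
partitions, so no validation statistics leak into preprocessing. Balanced
class weights w_c = n / (2 n_c) keep rare diagnoses from being swamped by
controls. Each repeat reshuffles the folds under its own derived seed; the
whole bundle is bit-for-bit reproducible from the configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .errors import ConfigError, DataError, NumericalError
from .preprocess import Residualizer, apply_residualizer, fit_residualizer


@dataclass
class CVConfig:
    outer_folds: int = 5
    inner_folds: int = 5
    repeats: int = 5
    n_hyperparameter_draws: int = 25
    penalty_range: tuple[float, float] = (1e-4, 1e4)  # L2 strength lambda
    base_seed: int = 0
    class_weighting: str = "balanced"  # balanced | none
    max_iter: int = 2000
    tol: float = 1e-8

    def validate(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ConfigError("outer and inner folds must both be >= 2")
        if self.repeats < 1:
            raise ConfigError("repeats must be >= 1")
        lo, hi = self.penalty_range
        if not (0 < lo <= hi):
            raise ConfigError("penalty_range endpoints must be positive and ordered")
        if self.class_weighting not in ("balanced", "none"):
            raise ConfigError("class_weighting must be 'balanced' or 'none'")


@dataclass
class FoldModel:
    repeat: int
    fold: int
    coef: np.ndarray
    intercept: float
    lam: float
    residualizer: Residualizer
    val_idx: np.ndarray
    val_scores: np.ndarray  # linear decision values
    val_probs: np.ndarray
    train_idx: np.ndarray
    auc: float


@dataclass
class ModelBundle:
    name: str
    feature_names: list[str]
    config: CVConfig
    folds: list[FoldModel] = field(default_factory=list)

    @property
    def auc_list(self) -> list[float]:
        return [f.auc for f in self.folds]

    def out_of_fold_probabilities(self, n_subjects: int) -> np.ndarray:
        """Per-subject probability, averaged over the repeats' single
        out-of-fold predictions."""
        acc = np.zeros(n_subjects)
        cnt = np.zeros(n_subjects)
        for f in self.folds:
            acc[f.val_idx] += f.val_probs
            cnt[f.val_idx] += 1
        if (cnt == 0).any():
            raise DataError("some subjects never appear in a validation fold")
        return acc / cnt


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC-AUC: probability that a random case outscores a random control,
    ties counted one half."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise DataError("AUC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, float)))


@dataclass
class MetricSummary:
    mean: float
    ci_lower: float
    ci_upper: float
    values: list[float]
    n_bootstrap: int


def bootstrap_summary(
    values, n_bootstrap: int = 1000, seed: int = 0
) -> MetricSummary:
    """Percentile 95% CI over seeded resamples of a metric list."""
    values = np.asarray(values, float)
    if values.size < 2:
        raise DataError("bootstrap_summary needs at least two values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_bootstrap, values.size))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return MetricSummary(float(values.mean()), float(lo), float(hi),
                         values.tolist(), n_bootstrap)


def zscore_auc_matrix(auc_matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Z-score AUCs within each diagnosis (row) across subcategories (columns).

    Returns the z matrix and a boolean suppression mask marking entries with
    z <= 0, the convention used to display only above-average performance.
    """
    vals = auc_matrix.to_numpy(float)
    if vals.shape[1] < 2:
        raise DataError("need >= 2 subcategories per diagnosis to z-score")
    sd = vals.std(axis=1, ddof=1)
    sd[sd <= 1e-12 * np.maximum(1.0, np.abs(vals).max(axis=1))] = 0.0
    if (sd <= 0).any():
        bad = list(auc_matrix.index[sd <= 0])
        raise DataError(f"zero-variance rows cannot be z-scored: {bad}")
    z = (vals - vals.mean(axis=1, keepdims=True)) / sd[:, None]
    zdf = pd.DataFrame(z, index=auc_matrix.index, columns=auc_matrix.columns)
    return zdf, zdf <= 0


def _fit_logistic(Xt, yv, lam, config, sample_weight=None):
    cw = "balanced" if config.class_weighting == "balanced" else None
    # default penalty is ridge (L2); strength lambda enters as C = 1/lambda
    clf = LogisticRegression(
        C=1.0 / lam, solver="lbfgs", tol=config.tol,
        max_iter=config.max_iter, class_weight=cw,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            clf.fit(Xt, yv)
        except ConvergenceWarning as exc:  # pragma: no cover - rare
            raise NumericalError(f"logistic solver failed to converge: {exc}") from exc
    return clf


def nested_cv_train(
    X: pd.DataFrame,
    y: np.ndarray,
    C: pd.DataFrame,
    config: CVConfig | None = None,
    name: str = "model",
) -> ModelBundle:
    """Train the repeated nested-CV deconfounded ridge logistic classifier.

    Within each outer fold the residualizer is fit on the outer-training rows
    and applied to both partitions; the inner CV then selects the L2 strength
    lambda from ``n_hyperparameter_draws`` log-uniform samples by mean inner
    AUC, and the final model is refit on the full outer-training partition at
    the selected lambda. Out-of-fold decision scores, probabilities and AUCs
    are recorded per (repeat, fold).
    """
    config = config or CVConfig()
    config.validate()
    y = np.asarray(y).astype(int)
    if len(X) != len(y) or len(C) != len(y):
        raise DataError("feature, label and confounder row counts differ")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise DataError("both classes must be present")
    if counts.min() < config.outer_folds:
        raise DataError(
            f"minority class ({counts.min()} subjects) cannot stratify "
            f"{config.outer_folds} outer folds; use a larger cohort"
        )

    bundle = ModelBundle(name=name, feature_names=list(X.columns), config=config)
    lo, hi = config.penalty_range
    for r in range(config.repeats):
        repeat_seed = (config.base_seed + r) % (2**31 - 1)
        rng = np.random.default_rng([config.base_seed, r])
        lambdas = lo * (hi / lo) ** rng.random(config.n_hyperparameter_draws)
        outer = StratifiedKFold(config.outer_folds, shuffle=True, random_state=repeat_seed)
        for k, (tr, va) in enumerate(outer.split(np.zeros(len(y)), y)):
            resid = fit_residualizer(X.iloc[tr], C.iloc[tr], fitted_on=f"r{r}f{k}")
            Xtr = apply_residualizer(resid, X.iloc[tr], C.iloc[tr]).to_numpy()
            Xva = apply_residualizer(resid, X.iloc[va], C.iloc[va]).to_numpy()
            ytr, yva = y[tr], y[va]
            if np.unique(yva).size < 2:
                raise DataError(f"outer fold {k} has a single class in validation")
            inner = StratifiedKFold(
                config.inner_folds, shuffle=True,
                random_state=(repeat_seed * 100003 + k) % (2**31 - 1))
            splits = list(inner.split(np.zeros(len(ytr)), ytr))
            inner_auc = np.zeros(len(lambdas))
            for j, lam in enumerate(lambdas):
                scores = []
                for itr, iva in splits:
                    clf = _fit_logistic(Xtr[itr], ytr[itr], lam, config)
                    s = Xtr[iva] @ clf.coef_[0] + clf.intercept_[0]
                    scores.append(auc(s, ytr[iva]))
                inner_auc[j] = np.mean(scores)
            lam = float(lambdas[int(np.argmax(inner_auc))])
            clf = _fit_logistic(Xtr, ytr, lam, config)
            val_scores = Xva @ clf.coef_[0] + clf.intercept_[0]
            val_probs = 1.0 / (1.0 + np.exp(-val_scores))
            bundle.folds.append(FoldModel(
                repeat=r, fold=k, coef=clf.coef_[0].copy(),
                intercept=float(clf.intercept_[0]), lam=lam, residualizer=resid,
                val_idx=va.copy(), val_scores=val_scores, val_probs=val_probs,
                train_idx=tr.copy(), auc=auc(val_scores, yva),
            ))
    return bundle


def cross_predict(
    bundle: ModelBundle, X_B: pd.DataFrame, y_B: np.ndarray, C_B: pd.DataFrame
) -> dict:
    """Apply a trained bundle to another cohort/diagnosis.

    Each fold's residualizer and weight vector produce probabilities on cohort
    B; the report averages ROC-AUC across folds and, at probability threshold
    0.5, sensitivity and specificity.
    """
    if list(X_B.columns) != bundle.feature_names:
        raise DataError("cohort B feature columns do not match the training modality")
    y_B = np.asarray(y_B).astype(int)
    aucs, sens, spec = [], [], []
    for f in bundle.folds:
        Xt = apply_residualizer(f.residualizer, X_B, C_B).to_numpy()
        s = Xt @ f.coef + f.intercept
        p = 1.0 / (1.0 + np.exp(-s))
        aucs.append(auc(s, y_B))
        pred = p >= 0.5
        sens.append(float(pred[y_B == 1].mean()))
        spec.append(float((~pred[y_B == 0]).mean()))
    return {
        "auc": float(np.mean(aucs)),
        "sensitivity": float(np.mean(sens)),
        "specificity": float(np.mean(spec)),
        "fold_aucs": aucs,
    }
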