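"""Confound mitigation: OLS residualization fit on training data only.

A :class:`Residualizer` regresses every feature on the confounders (with
intercept) using ordinary least squares on the training partition, and
standardizes the resulting residuals by their training mean and SD. The same
coefficients and statistics are then applied to held-out data, so validation
folds never influence the fit. Zero-variance features are flagged and mapped to
zero rather than dropped, preserving signature dimensionality across folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError


@dataclass
class Residualizer:
    feature_names: list[str]
    confounder_names: list[str]
    coef: np.ndarray          # (n_confounders + 1) x n_features, row 0 = intercept
    mean: np.ndarray          # training residual mean per feature
    sd: np.ndarray            # training residual SD per feature (1.0 where flagged)
    zero_variance: np.ndarray  # bool per feature
    fitted_on: str = "all"

    def to_frame(self) -> pd.DataFrame:
        """Serialize coefficients and statistics as a delimited-friendly table."""
        rows = ["intercept", *self.confounder_names, "resid_mean", "resid_sd",
                "zero_variance"]
        data = np.vstack([self.coef, self.mean, self.sd,
                          self.zero_variance.astype(float)])
        out = pd.DataFrame(data, columns=self.feature_names)
        out.insert(0, "term", rows)
        return out


def _design(C: np.ndarray) -> np.ndarray:
    return np.hstack([np.ones((C.shape[0], 1)), C])


def fit_residualizer(
    X_train: pd.DataFrame, C_train: pd.DataFrame, fitted_on: str = "all"
) -> Residualizer:
    """OLS fit of each feature on the confounders, over the training rows.

    Raises :class:`DataError` if rows are misaligned, the training set is too
    small, or the confounder matrix is rank deficient (the offending collinear
    columns are named).
    """
    if len(X_train) != len(C_train):
        raise DataError("feature and confounder row counts differ")
    n, q = len(X_train), C_train.shape[1]
    if n <= q + 1:
        raise DataError(f"need n_train > n_confounders + 1 (got {n} rows, {q} confounders)")
    D = _design(C_train.to_numpy(float))
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        # name collinear columns: those whose removal restores full column rank
        collinear = [
            name for j, name in enumerate(C_train.columns)
            if np.linalg.matrix_rank(np.delete(D, j + 1, axis=1)) == rank
        ]
        raise DataError(f"rank-deficient confounder matrix; collinear columns: {collinear}")
    Xv = X_train.to_numpy(float)
    coef, *_ = np.linalg.lstsq(D, Xv, rcond=None)
    resid = Xv - D @ coef
    mean = resid.mean(axis=0)
    sd = resid.std(axis=0, ddof=1)
    zero_var = sd <= 1e-12
    sd = np.where(zero_var, 1.0, sd)
    return Residualizer(
        feature_names=list(X_train.columns),
        confounder_names=list(C_train.columns),
        coef=coef, mean=mean, sd=sd, zero_variance=zero_var, fitted_on=fitted_on,
    )


def apply_residualizer(
    model: Residualizer, X: pd.DataFrame, C: pd.DataFrame
) -> pd.DataFrame:
    """Deconfound and standardize ``X`` using training-fold statistics only."""
    if list(X.columns) != model.feature_names:
        raise DataError("feature columns do not match the fitted residualizer")
    if list(C.columns) != model.confounder_names:
        unseen = [c for c in C.columns if c not in model.confounder_names]
        raise DataError(f"confounder columns do not match the fit (unseen: {unseen})")
    D = _design(C.to_numpy(float))
    resid = X.to_numpy(float) - D @ model.coef
    out = (resid - model.mean) / model.sd
    out[:, model.zero_variance] = 0.0
    return pd.DataFrame(out, columns=model.feature_names, index=X.index)
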