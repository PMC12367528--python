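"""Encoding maps, composite signatures and their validation.

A linear classifier's weight vector is not directly interpretable feature by
feature; the encoding map (structure coefficients) is. For each (repeat, fold)
model we correlate every deconfounded, standardized feature with the model's
linear decision score over the training partition, then average across folds
and repeats. Averaging the maps of several disease models yields a composite
signature; a subject is scored by the dot product of the signature with their
deconfounded standardized profile. Density thresholding, map similarity with
permutation p-values and a permutation-null AUC test complete the toolkit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cvtrain import ModelBundle, auc
from .errors import ConfigError, DataError
from .preprocess import Residualizer, apply_residualizer


@dataclass
class EncodingMap:
    feature_names: list[str]
    coefficients: np.ndarray  # in [-1, 1]
    source_model: str
    n_models_averaged: int = 1
    flagged_zero_variance: np.ndarray | None = None


@dataclass
class CompositeSignature:
    feature_names: list[str]
    coefficients: np.ndarray
    contributing_models: list[str]
    coefficient_sd: np.ndarray | None = None
    density: float = 1.0

    def nonzero_features(self) -> list[str]:
        return [f for f, c in zip(self.feature_names, self.coefficients) if c != 0.0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"feature": self.feature_names,
                             "coefficient": self.coefficients})


def _pearson_columns(Xt: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of each column of Xt with s; zero-variance columns get 0."""
    Xc = Xt - Xt.mean(axis=0)
    sc = s - s.mean()
    sx = np.sqrt((Xc ** 2).sum(axis=0))
    ss = np.sqrt((sc ** 2).sum())
    zero = (sx <= 1e-12) | (ss <= 1e-12)
    denom = np.where(zero, 1.0, sx * ss)
    r = (Xc * sc[:, None]).sum(axis=0) / denom
    r[zero] = 0.0
    return r, zero


def structure_coefficients(
    bundle: ModelBundle, X: pd.DataFrame, C: pd.DataFrame
) -> EncodingMap:
    """Average per-fold feature-vs-decision-score Pearson correlations."""
    if list(X.columns) != bundle.feature_names:
        raise DataError("features do not match the trained bundle")
    maps, zeros = [], []
    for f in bundle.folds:
        Xt = apply_residualizer(f.residualizer, X.iloc[f.train_idx],
                                C.iloc[f.train_idx]).to_numpy()
        s = Xt @ f.coef + f.intercept
        r, zero = _pearson_columns(Xt, s)
        maps.append(r)
        zeros.append(zero)
    coef = np.mean(maps, axis=0)
    return EncodingMap(
        feature_names=bundle.feature_names, coefficients=coef,
        source_model=bundle.name, n_models_averaged=len(bundle.folds),
        flagged_zero_variance=np.any(zeros, axis=0),
    )


def composite_signature(maps: list[EncodingMap]) -> CompositeSignature:
    """Element-wise unweighted mean across disease models, with per-feature SD."""
    if not maps:
        raise DataError("composite_signature requires at least one encoding map")
    names = maps[0].feature_names
    for m in maps[1:]:
        if m.feature_names != names:
            raise DataError("encoding maps have mismatched feature names/order")
    mat = np.vstack([m.coefficients for m in maps])
    return CompositeSignature(
        feature_names=list(names),
        coefficients=mat.mean(axis=0),
        contributing_models=[m.source_model for m in maps],
        coefficient_sd=mat.std(axis=0, ddof=0),
    )


def _top_k_mask(coefficients: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask of the k largest-|coefficient| entries; ties broken by
    feature order (earlier feature kept)."""
    order = np.lexsort((np.arange(len(coefficients)), -np.abs(coefficients)))
    mask = np.zeros(len(coefficients), bool)
    mask[order[:k]] = True
    return mask


def simplify_signature(sig: CompositeSignature, k: int) -> CompositeSignature:
    """Retain the k features of largest |coefficient|, zeroing the rest."""
    if k <= 0:
        raise ConfigError("k must be positive")
    if k > len(sig.feature_names):
        raise ConfigError("k exceeds the number of features")
    mask = _top_k_mask(sig.coefficients, k)
    return CompositeSignature(
        feature_names=list(sig.feature_names),
        coefficients=np.where(mask, sig.coefficients, 0.0),
        contributing_models=list(sig.contributing_models),
        coefficient_sd=sig.coefficient_sd,
        density=k / len(sig.feature_names),
    )


def threshold_signature(sig: CompositeSignature, density: float) -> CompositeSignature:
    """Keep the top ceil(density * n_features) features by |coefficient|."""
    if not (0.0 < density <= 1.0):
        raise ConfigError("density must be in (0, 1]")
    k = int(np.ceil(density * len(sig.feature_names)))
    out = simplify_signature(sig, k)
    out.density = density
    return out


def score_subjects(
    sig: CompositeSignature,
    X: pd.DataFrame,
    C: pd.DataFrame,
    residualizer: Residualizer,
) -> np.ndarray:
    """score_i = sum_j sig_j * x~_ij on the deconfounded standardized profile."""
    if list(X.columns) != sig.feature_names:
        raise DataError("features do not match the signature")
    Xt = apply_residualizer(residualizer, X, C).to_numpy()
    return Xt @ sig.coefficients


def encoding_similarity(
    map_a, map_b, n_permutations: int = 1000, seed: int = 0
) -> dict:
    """Pearson r between two coefficient vectors with a two-sided
    feature-index permutation p-value, (count+1)/(n+1) convention."""
    a = np.asarray(getattr(map_a, "coefficients", map_a), float)
    b = np.asarray(getattr(map_b, "coefficients", map_b), float)
    if a.shape != b.shape or a.size < 3:
        raise DataError("aligned vectors of >= 3 features required")
    if a.std() <= 1e-15 or b.std() <= 1e-15:
        raise DataError("zero-variance coefficient vector")
    r_obs = float(np.corrcoef(a, b)[0, 1])
    rng = np.random.default_rng(seed)
    ac = a - a.mean()
    bc = b - b.mean()
    denom = np.sqrt((ac ** 2).sum() * (bc ** 2).sum())
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(a))
        r_perm = float(ac[perm] @ bc) / denom
        if abs(r_perm) >= abs(r_obs) - 1e-15:
            count += 1
    return {"r": r_obs, "p": (count + 1) / (n_permutations + 1),
            "n_permutations": n_permutations}


def permutation_null_auc(
    sig: CompositeSignature,
    X: pd.DataFrame,
    y: np.ndarray,
    C: pd.DataFrame,
    residualizer: Residualizer,
    n_permutations: int = 1000,
    seed: int = 0,
) -> dict:
    """Observed signature AUC against a label-permutation null distribution."""
    y = np.asarray(y).astype(int)
    if np.unique(y).size < 2:
        raise DataError("both classes must be present")
    scores = score_subjects(sig, X, C, residualizer)
    observed = auc(scores, y)
    rng = np.random.default_rng(seed)
    null = np.array([auc(scores, y[rng.permutation(len(y))])
                     for _ in range(n_permutations)])
    count = int((null >= observed - 1e-15).sum())
    return {
        "observed_auc": observed,
        "null_aucs": null,
        "null_mean": float(null.mean()),
        "null_sd": float(null.std(ddof=1)),
        "z": float((observed - null.mean()) / null.std(ddof=1)),
        "p": (count + 1) / (n_permutations + 1),
    }
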