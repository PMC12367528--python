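"""Deviance-explained (D2) computation and unique/shared partitioning.

D2 = 1 - deviance(model) / deviance(intercept-only) of a logistic regression
of the outcome on one or two prediction sources. Predictors enter on the logit
scale (probabilities clipped to [1e-6, 1 - 1e-6] first) so the refit is stable
near 0/1. The partition between a biological and a psychosocial source is

    unique_bio = D2_combined - D2_psy
    unique_psy = D2_combined - D2_bio
    shared     = D2_bio + D2_psy - D2_combined

which satisfies unique_bio + unique_psy + shared = D2_combined exactly by
construction. Shared deviance may be negative (suppression) and is reported
as computed rather than truncated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .errors import DataError, NumericalError

CLIP = 1e-6


@dataclass
class DeviancePartition:
    d2_bio: float
    d2_psy: float
    d2_combined: float
    unique_bio: float
    unique_psy: float
    shared: float


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(np.asarray(p, float), CLIP, 1.0 - CLIP)
    return np.log(p / (1.0 - p))


def d2(y: np.ndarray, *predictors: np.ndarray) -> float:
    """Fraction of deviance explained by logistic regression of ``y`` on the
    logit-transformed probability predictor(s).

    Perfectly collinear duplicate predictors are dropped with a warning;
    complete separation raises :class:`NumericalError`.
    """
    y = np.asarray(y).astype(int)
    if np.unique(y).size < 2:
        raise DataError("both classes must be present")
    if not predictors:
        raise DataError("at least one predictor required")
    cols = [_logit(p) for p in predictors]
    kept: list[np.ndarray] = []
    for j, col in enumerate(cols, start=1):
        if col.std() <= 1e-12:
            continue  # constant predictor: nothing beyond the intercept
        dup = any(abs(np.corrcoef(col, k)[0, 1]) > 1 - 1e-10 for k in kept)
        if dup:
            warnings.warn(f"predictor {j} is collinear with an earlier one; dropped")
        else:
            kept.append(col)
    if not kept:
        return 0.0  # intercept-only model explains no deviance
    design = sm.add_constant(np.column_stack(kept), has_constant="add")
    model = sm.GLM(y, design, family=sm.families.Binomial())
    try:
        with warnings.catch_warnings():
            # clipped logits keep the design bounded, so a saturated fit is a
            # legitimate D2 -> 1 outcome rather than a failure
            warnings.simplefilter("ignore")
            fit = model.fit(maxiter=200, tol=1e-10)
    except Exception as exc:  # statsmodels raises on unsalvageable fits
        raise NumericalError(f"logistic refit failed: {exc}") from exc
    out = float(1.0 - fit.deviance / fit.null_deviance)
    if not np.isfinite(out) or not np.all(np.isfinite(fit.params)):
        raise NumericalError("deviance refit did not produce finite estimates")
    return out


def partition_deviance(y: np.ndarray, p_bio: np.ndarray, p_psy: np.ndarray) -> DeviancePartition:
    """Partition D2 into unique and shared biological/psychosocial parts."""
    p_bio = np.asarray(p_bio, float)
    p_psy = np.asarray(p_psy, float)
    if len(p_bio) != len(y) or len(p_psy) != len(y):
        raise DataError("predictor vectors must align with the labels")
    d2_bio = d2(y, p_bio)
    d2_psy = d2(y, p_psy)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duplicate-predictor warning is expected
        d2_comb = d2(y, p_bio, p_psy)
    return DeviancePartition(
        d2_bio=d2_bio, d2_psy=d2_psy, d2_combined=d2_comb,
        unique_bio=d2_comb - d2_psy,
        unique_psy=d2_comb - d2_bio,
        shared=d2_bio + d2_psy - d2_comb,
    )
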