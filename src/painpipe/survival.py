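"""Longitudinal synergy: Kaplan-Meier incidence, log-rank tests and Cox HRs.

Risk groups (for example high-high, high-low, low-high, low-low combinations
of baseline biological and psychosocial quintiles) are compared on time to
diagnosis onset. Estimation is delegated to lifelines; event times in the
synthetic cohorts are continuous, so tie handling is immaterial. Hazard
ratios default to the each-group-versus-rest parameterization; a
reference-group parameterization is also available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .cvtrain import auc
from .errors import DataError
from .synergy import cohens_d


@dataclass
class SurvivalRecords:
    """Per-subject time (years, > 0), event indicator and optional group."""

    time: np.ndarray
    event: np.ndarray
    group: np.ndarray | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        self.event = np.asarray(self.event).astype(int)
        if self.time.size == 0:
            raise DataError("at least one record required")
        if (self.time <= 0).any():
            raise DataError("event/censoring times must be positive")
        if self.group is not None:
            self.group = np.asarray(self.group)


def km_curve(records: SurvivalRecords) -> pd.DataFrame:
    """Product-limit estimate; returns a step table with survival and
    cumulative incidence (1 - S) at each event time."""
    km = KaplanMeierFitter()
    km.fit(records.time, records.event)
    surv = km.survival_function_
    out = surv.reset_index()
    out.columns = ["time", "survival"]
    out["cumulative_incidence"] = 1.0 - out["survival"]
    return out


def logrank_test(records: SurvivalRecords) -> dict:
    """Two-sided log-rank test across the record groups."""
    if records.group is None:
        raise DataError("records carry no group labels")
    groups, counts = np.unique(records.group, return_counts=True)
    if len(groups) < 2:
        raise DataError("need >= 2 non-empty groups")
    res = multivariate_logrank_test(records.time, records.group, records.event)
    return {"chi_square": float(res.test_statistic), "p": float(res.p_value),
            "df": int(len(groups) - 1)}


def _fit_cox(df: pd.DataFrame, covariates: list[str]) -> CoxPHFitter:
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:
        raise DataError(f"Cox fit failed (separation or no events?): {exc}") from exc
    return cph


def cox_hr(
    records: SurvivalRecords,
    covariates: pd.DataFrame | None = None,
    mode: str = "vs_rest",
    reference: str | None = None,
) -> pd.DataFrame:
    """Cox proportional-hazards ratios with Wald 95% CIs.

    With ``covariates`` given, a single model on those columns is fit. With
    group labels instead, ``mode='vs_rest'`` fits one model per group against
    the complement (the framing used for the four risk-group curves) and
    ``mode='reference'`` fits one model with dummies against ``reference``.
    """
    if records.event.sum() == 0:
        raise DataError("no events observed")
    base = pd.DataFrame({"time": records.time, "event": records.event})
    rows = []
    if covariates is not None:
        df = pd.concat([base, covariates.reset_index(drop=True)], axis=1)
        cph = _fit_cox(df, list(covariates.columns))
        for name in covariates.columns:
            s = cph.summary.loc[name]
            rows.append({"term": name, "hr": float(np.exp(s["coef"])),
                         "ci_lower": float(np.exp(s["coef lower 95%"])),
                         "ci_upper": float(np.exp(s["coef upper 95%"])),
                         "p": float(s["p"])})
        return pd.DataFrame(rows)
    if records.group is None:
        raise DataError("either covariates or group labels are required")
    groups = list(dict.fromkeys(records.group.tolist()))
    if mode == "vs_rest":
        for g in groups:
            df = base.copy()
            df[f"group_{g}"] = (records.group == g).astype(float)
            cph = _fit_cox(df, [f"group_{g}"])
            s = cph.summary.loc[f"group_{g}"]
            rows.append({"term": str(g), "hr": float(np.exp(s["coef"])),
                         "ci_lower": float(np.exp(s["coef lower 95%"])),
                         "ci_upper": float(np.exp(s["coef upper 95%"])),
                         "p": float(s["p"])})
    elif mode == "reference":
        ref = reference if reference is not None else groups[0]
        df = base.copy()
        others = [g for g in groups if g != ref]
        for g in others:
            df[f"group_{g}"] = (records.group == g).astype(float)
        cph = _fit_cox(df, [f"group_{g}" for g in others])
        for g in others:
            s = cph.summary.loc[f"group_{g}"]
            rows.append({"term": f"{g}_vs_{ref}", "hr": float(np.exp(s["coef"])),
                         "ci_lower": float(np.exp(s["coef lower 95%"])),
                         "ci_upper": float(np.exp(s["coef upper 95%"])),
                         "p": float(s["p"])})
    else:
        raise DataError("mode must be 'vs_rest' or 'reference'")
    return pd.DataFrame(rows)


def prognostic_contrast(
    baseline_scores: np.ndarray,
    onset_labels: np.ndarray,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> dict:
    """Contrast baseline signature scores between subjects who develop the
    diagnosis by the follow-up horizon (label 1) and those who stay
    diagnosis-free (label 0); reports Cohen's d (bootstrap CI) and AUC."""
    scores = np.asarray(baseline_scores, float)
    labels = np.asarray(onset_labels).astype(int)
    if labels.sum() == 0:
        raise DataError("empty onset group")
    d = cohens_d(scores[labels == 1], scores[labels == 0],
                 n_bootstrap=n_bootstrap, seed=seed)
    return {**d, "auc": auc(scores, labels)}
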