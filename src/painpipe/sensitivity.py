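"""Medication-exclusion robustness of a signature's discrimination.

For each medication family, the signature's AUC and Cohen's d are recomputed
on the subjects not taking that family and compared against the full-cohort
values. Families are opaque flags; no drug ontology is modelled. A family
whose exclusion empties one outcome class is flagged and its metrics omitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cvtrain import auc
from .errors import DataError
from .synergy import cohens_d


@dataclass
class ExclusionReport:
    family: str
    n_excluded: int
    auc: float | None
    cohens_d: float | None
    delta_auc: float | None
    delta_d: float | None
    degenerate: bool = False


def medication_sensitivity(
    scores: np.ndarray,
    labels: np.ndarray,
    med_flags: pd.DataFrame,
    n_bootstrap: int = 200,
    seed: int = 0,
) -> list[ExclusionReport]:
    """Recompute discrimination after excluding each medication family's users."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    if med_flags.shape[1] == 0:
        raise DataError("at least one medication family required")
    if len(med_flags) != len(scores) or len(labels) != len(scores):
        raise DataError("scores, labels and medication flags must align")
    full_auc = auc(scores, labels)
    full_d = cohens_d(scores[labels == 1], scores[labels == 0],
                      n_bootstrap=n_bootstrap, seed=seed)["d"]
    reports = []
    for fam in med_flags.columns:
        keep = med_flags[fam].to_numpy().astype(int) == 0
        yk = labels[keep]
        if keep.sum() == 0 or np.unique(yk).size < 2:
            reports.append(ExclusionReport(
                family=str(fam), n_excluded=int((~keep).sum()), auc=None,
                cohens_d=None, delta_auc=None, delta_d=None, degenerate=True))
            continue
        sk = scores[keep]
        a = auc(sk, yk)
        d = cohens_d(sk[yk == 1], sk[yk == 0],
                     n_bootstrap=n_bootstrap, seed=seed)["d"]
        reports.append(ExclusionReport(
            family=str(fam), n_excluded=int((~keep).sum()), auc=a, cohens_d=d,
            delta_auc=a - full_auc, delta_d=d - full_d))
    return reports


def reports_to_frame(reports: list[ExclusionReport]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in reports])
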