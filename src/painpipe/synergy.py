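"""Risk-score pooling, quintile stratification and biological x psychosocial
odds-ratio synergy.

A subject's pooled risk score is the mean natural-log predicted probability
across the contributing disease models (probabilities clipped at 1e-6 so no
single model dominates). Subjects are then split at the empirical 20/40/60/80
percentiles into quintiles labelled low, reduced, neutral, elevated and high;
ties at a cut fall to the lower bin, making the assignment deterministic under
reordering of tied subjects. Synergy is read off the 5x5 grid of odds ratios
comparing each biological x psychosocial quintile combination against all
other participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DataError

QUINTILE_LABELS = ("low", "reduced", "neutral", "elevated", "high")
CLIP = 1e-6


@dataclass
class RiskScoreSet:
    scores: np.ndarray
    source: str
    contributing_models: list[str]
    quintiles: np.ndarray | None = None  # integer 0..4

    def quintile_labels(self) -> np.ndarray:
        if self.quintiles is None:
            raise DataError("quintiles not assigned yet")
        return np.array(QUINTILE_LABELS)[self.quintiles]


def pooled_risk_scores(
    prob_matrix: np.ndarray,
    source: str = "biological",
    model_names: list[str] | None = None,
) -> RiskScoreSet:
    """Mean ln(probability) over the contributing models, per subject."""
    prob_matrix = np.atleast_2d(np.asarray(prob_matrix, float))
    if prob_matrix.ndim != 2 or prob_matrix.shape[1] == 0:
        raise DataError("prob_matrix must be subjects x models with >= 1 model")
    scores = np.log(np.clip(prob_matrix, CLIP, 1.0 - CLIP)).mean(axis=1)
    names = model_names or [f"model_{j}" for j in range(prob_matrix.shape[1])]
    return RiskScoreSet(scores=scores, source=source, contributing_models=list(names))


def assign_quintiles(scores: np.ndarray) -> np.ndarray:
    """Quintile index 0..4 per subject; ties at a cut go to the lower bin."""
    scores = np.asarray(scores, float)
    if scores.size < 5:
        raise DataError("need at least 5 subjects for quintiles")
    if np.unique(scores).size < 5:
        import warnings

        warnings.warn("fewer than 5 distinct scores; quintile bins degenerate")
    cuts = np.percentile(scores, [20, 40, 60, 80])
    return (scores[:, None] > cuts[None, :]).sum(axis=1)


@dataclass
class OddsRatioResult:
    odds_ratio: float
    log_or: float
    ci_lower: float
    ci_upper: float
    table: tuple[float, float, float, float]  # a, b, c, d after any correction
    corrected: bool = False


def odds_ratio(a: float, b: float, c: float, d: float) -> OddsRatioResult:
    """Unconditional MLE odds ratio (a d)/(b c) from the 2x2 table
    (exposed cases, exposed controls, unexposed cases, unexposed controls),
    with the Haldane-Anscombe +0.5 correction when any cell is zero and a
    Wald 95% CI on the log scale."""
    cells = np.array([a, b, c, d], float)
    if (cells < 0).any():
        raise DataError("cell counts must be non-negative")
    if cells.sum() == 0:
        raise DataError("all-zero 2x2 table")
    corrected = bool((cells == 0).any())
    if corrected:
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    or_ = (a_ * d_) / (b_ * c_)
    log_or = float(np.log(or_))
    se = float(np.sqrt((1.0 / cells).sum()))
    return OddsRatioResult(
        odds_ratio=float(or_), log_or=log_or,
        ci_lower=float(np.exp(log_or - 1.96 * se)),
        ci_upper=float(np.exp(log_or + 1.96 * se)),
        table=tuple(cells), corrected=corrected,
    )


@dataclass
class ORGrid:
    diagnosis: str
    log_or: np.ndarray                 # 5x5, [bio quintile, psy quintile]
    odds_ratio: np.ndarray             # 5x5
    cell_tables: np.ndarray            # 5x5x4 counts before correction
    sparse_cells: np.ndarray           # 5x5 bool, any zero count
    marginal_bio: list[OddsRatioResult] = field(default_factory=list)
    marginal_psy: list[OddsRatioResult] = field(default_factory=list)


def quintile_or_grid(
    bio_quintiles: np.ndarray,
    psy_quintiles: np.ndarray,
    labels: np.ndarray,
    diagnosis: str = "pooled",
) -> ORGrid:
    """25-cell grid of (in quintile combination vs all others) odds ratios,
    plus the per-source marginal quintile ORs."""
    bq = np.asarray(bio_quintiles, int)
    pq = np.asarray(psy_quintiles, int)
    y = np.asarray(labels).astype(int)
    if not (len(bq) == len(pq) == len(y)):
        raise DataError("quintile and label vectors must align")
    if np.unique(y).size < 2:
        raise DataError("both classes must be present")

    def _or_for(mask: np.ndarray) -> tuple[OddsRatioResult, np.ndarray]:
        a = int((mask & (y == 1)).sum())
        b = int((mask & (y == 0)).sum())
        c = int((~mask & (y == 1)).sum())
        d = int((~mask & (y == 0)).sum())
        return odds_ratio(a, b, c, d), np.array([a, b, c, d], float)

    log_or = np.zeros((5, 5))
    ors = np.zeros((5, 5))
    tables = np.zeros((5, 5, 4))
    sparse = np.zeros((5, 5), bool)
    for i in range(5):
        for j in range(5):
            res, raw = _or_for((bq == i) & (pq == j))
            log_or[i, j] = res.log_or
            ors[i, j] = res.odds_ratio
            tables[i, j] = raw
            sparse[i, j] = res.corrected
    marginal_bio = [_or_for(bq == i)[0] for i in range(5)]
    marginal_psy = [_or_for(pq == j)[0] for j in range(5)]
    return ORGrid(diagnosis=diagnosis, log_or=log_or, odds_ratio=ors,
                  cell_tables=tables, sparse_cells=sparse,
                  marginal_bio=marginal_bio, marginal_psy=marginal_psy)


def cohens_d(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> dict:
    """Cohen's d with pooled (n-1 weighted) SD and a percentile bootstrap CI
    resampling within each group."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise DataError("each group needs >= 2 observations")

    def _d(x, z):
        sp2 = ((x.size - 1) * x.var(ddof=1) + (z.size - 1) * z.var(ddof=1)) / (
            x.size + z.size - 2
        )
        if sp2 <= 0:
            raise DataError("zero pooled SD")
        return (x.mean() - z.mean()) / np.sqrt(sp2)

    d = float(_d(a, b))
    rng = np.random.default_rng(seed)
    boots = np.array([
        _d(a[rng.integers(0, a.size, a.size)], b[rng.integers(0, b.size, b.size)])
        for _ in range(n_bootstrap)
    ])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return {"d": d, "ci_lower": float(lo), "ci_upper": float(hi),
            "n_bootstrap": n_bootstrap}


def spearman_assoc(score: np.ndarray, spread_category: np.ndarray) -> dict:
    """Spearman rho (average ranks for ties) and R^2 = rho^2."""
    score = np.asarray(score, float)
    cat = np.asarray(spread_category, float)
    if score.size < 3:
        raise DataError("need >= 3 subjects")
    if np.unique(score).size < 2 or np.unique(cat).size < 2:
        raise DataError("constant input")
    rho = float(stats.spearmanr(score, cat).statistic)
    return {"rho": rho, "r_squared": rho ** 2}
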