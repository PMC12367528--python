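"""Synthetic biobank-style cohort generator with planted ground truth.

Emulates the statistical structure that the downstream analysis assumes:

* per-modality blocks of correlated continuous features (blood-assay-like,
  connectivity-like, psychosocial) with optional confounder leakage,
* binary diagnoses drawn from sparse per-modality logistic models plus a
  biological x psychosocial latent interaction,
* chronic pain-site indicators driven predominantly by the psychosocial latent
  through a cumulative-logit spread model, with a rare pain-all-over state,
* exponential onset times with administrative censoring at the last follow-up,
* medication-family flags marginally associated with diagnosis status.

Every quantity used to generate the data is retained in ``CohortTable.truth``
so parameter-recovery tests have full access to the generating mechanism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataError
from .io import write_table

SITE_NAMES = ("head", "face", "neck_shoulder", "stomach_abdominal", "back", "hip", "knee")

PSYCHOSOCIAL = "psychosocial"


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class ModalityConfig:
    """One feature block (e.g. 52 blood assays, connectivity columns)."""

    name: str
    n_features: int
    n_latent: int = 4
    feature_block_correlation: float = 0.1
    effect_sparsity: float = 0.25
    effect_scale: float = 1.0


@dataclass
class ConfounderConfig:
    name: str
    kind: str = "continuous"  # continuous | binary
    leakage_strength: float = 0.0


@dataclass
class DiagnosisConfig:
    """A binary diagnosis generated from a sparse linear model on the features.

    ``modality_weights`` scales the contribution of each modality's planted
    linear predictor; ``interaction_strength`` (log-odds units) multiplies the
    product of the biological and psychosocial primary latents;
    ``confounder_weight`` routes signal through the confounders alone, which is
    how purely confounded labels are planted for deconfounding checks.
    """

    name: str
    base_rate: float = 0.10
    modality_weights: dict[str, float] = field(default_factory=dict)
    interaction_strength: float = 0.0
    confounder_weight: float = 0.0


@dataclass
class PainConfig:
    n_sites: int = 7
    psychosocial_weight: float = 1.0
    biological_weight: float = 0.3
    acute_rate: float = 0.05
    pain_all_over_cutpoint: float = 4.0


@dataclass
class FollowupConfig:
    visit_offsets_years: tuple[float, ...] = (4.0, 9.0)
    hazard_scale: float = 0.02  # per-year baseline event rate


@dataclass
class GeneratorConfig:
    n_subjects: int
    modalities: list[ModalityConfig]
    confounders: list[ConfounderConfig] = field(default_factory=list)
    diagnoses: list[DiagnosisConfig] = field(default_factory=list)
    pain: PainConfig = field(default_factory=PainConfig)
    followup: FollowupConfig = field(default_factory=FollowupConfig)
    medication_families: int = 11
    med_base_rate: float = 0.05
    med_dx_rate: float = 0.25
    missing_rate: float = 0.0
    shared_beta: bool = False  # all diagnoses share one planted vector/modality
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise ConfigError("n_subjects must be positive")
        if not self.modalities:
            raise ConfigError("at least one modality required")
        for m in self.modalities:
            if m.n_features < m.n_latent or m.n_latent < 1:
                raise ConfigError(f"modality {m.name}: need n_features >= n_latent >= 1")
            if not (0.0 <= m.feature_block_correlation < 1.0):
                raise ConfigError(f"modality {m.name}: block correlation must be in [0,1)")
            for v in (m.feature_block_correlation, m.effect_sparsity, m.effect_scale):
                if not math.isfinite(v):
                    raise ConfigError(f"modality {m.name}: non-finite config value")
        for d in self.diagnoses:
            if not (0.0 < d.base_rate < 1.0):
                raise ConfigError(f"diagnosis {d.name}: base_rate must be in (0,1)")
            if d.base_rate * self.n_subjects < 1:
                raise ConfigError(
                    f"diagnosis {d.name}: base_rate*n_subjects < 1, no cases possible"
                )
            vals = [d.base_rate, d.interaction_strength, d.confounder_weight,
                    *d.modality_weights.values()]
            if not all(math.isfinite(v) for v in vals):
                raise ConfigError(f"diagnosis {d.name}: non-finite config value")
        if self.pain.n_sites < 1 or self.pain.n_sites > len(SITE_NAMES):
            raise ConfigError(f"pain.n_sites must be in [1, {len(SITE_NAMES)}]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must be in [0,1)")
        if self.followup.hazard_scale <= 0:
            raise ConfigError("hazard_scale must be positive")


def load_generator_config(path: str) -> GeneratorConfig:
    """Build a :class:`GeneratorConfig` from a YAML key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw["modalities"] = [ModalityConfig(**m) for m in raw.get("modalities", [])]
    raw["confounders"] = [ConfounderConfig(**c) for c in raw.get("confounders", [])]
    raw["diagnoses"] = [DiagnosisConfig(**d) for d in raw.get("diagnoses", [])]
    if "pain" in raw:
        raw["pain"] = PainConfig(**raw["pain"])
    if "followup" in raw:
        fu = raw["followup"]
        fu["visit_offsets_years"] = tuple(fu.get("visit_offsets_years", (4.0, 9.0)))
        raw["followup"] = FollowupConfig(**fu)
    return GeneratorConfig(**raw)


# ---------------------------------------------------------------------------
# cohort container
# ---------------------------------------------------------------------------

@dataclass
class CohortTable:
    """Subjects x {features, confounders, labels, onsets, pain sites, meds}."""

    subject_id: np.ndarray
    X: dict[str, pd.DataFrame]
    C: pd.DataFrame
    y: pd.DataFrame
    onset: pd.DataFrame  # columns time_<dx>, event_<dx>
    pain: pd.DataFrame   # chronic_<site>, acute_<site>, pain_all_over
    med: pd.DataFrame
    truth: dict

    @property
    def n_subjects(self) -> int:
        return len(self.subject_id)

    def modality_names(self) -> list[str]:
        return list(self.X)

    def diagnosis_names(self) -> list[str]:
        return list(self.y.columns)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _calibrate_intercept(eta0: np.ndarray, target_rate: float) -> float:
    """Bisection for c with mean(sigmoid(c + eta0)) = target_rate."""
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _sigmoid(mid + eta0).mean() < target_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_cohort(config: GeneratorConfig) -> CohortTable:
    """Draw a cohort. Identical config + seed yields identical tables."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    subject_id = np.arange(n)

    # confounders
    cvals = {}
    for c in config.confounders:
        if c.kind == "binary":
            cvals[c.name] = rng.integers(0, 2, size=n).astype(float)
        else:
            cvals[c.name] = rng.standard_normal(n)
    C = pd.DataFrame(cvals, columns=[c.name for c in config.confounders])
    leak = np.array([c.leakage_strength for c in config.confounders])
    c_centered = C.to_numpy() - C.to_numpy().mean(axis=0) if len(config.confounders) else np.zeros((n, 0))

    # features: sqrt(rho) * latent + sqrt(1-rho) * noise + sum_k leak_k * c_k
    X: dict[str, pd.DataFrame] = {}
    latents: dict[str, np.ndarray] = {}
    for m in config.modalities:
        Z = rng.standard_normal((n, m.n_latent))
        latents[m.name] = Z
        rho = m.feature_block_correlation
        assign = np.arange(m.n_features) % m.n_latent
        noise = rng.standard_normal((n, m.n_features))
        Xm = np.sqrt(rho) * Z[:, assign] + np.sqrt(1.0 - rho) * noise
        if len(config.confounders):
            Xm = Xm + (C.to_numpy() * leak).sum(axis=1, keepdims=True)
        cols = [f"{m.name}_f{j}" for j in range(m.n_features)]
        X[m.name] = pd.DataFrame(Xm, columns=cols)

    # primary latents for the interaction and for the pain model: the first
    # latent of the first non-psychosocial modality (biological) and of the
    # modality named "psychosocial" (falls back to the last modality)
    bio_modality = next((m.name for m in config.modalities if m.name != PSYCHOSOCIAL),
                        config.modalities[0].name)
    psy_modality = PSYCHOSOCIAL if PSYCHOSOCIAL in latents else config.modalities[-1].name
    z_bio = latents[bio_modality][:, 0]
    z_psy = latents[psy_modality][:, 0]

    # planted coefficients: s = ceil(sparsity * p) nonzero entries with signed
    # heterogeneous magnitudes, normalized so that effect_scale is the
    # per-modality log-odds scale of X beta (||beta|| = effect_scale)
    def _draw_beta(m: ModalityConfig) -> np.ndarray:
        beta = np.zeros(m.n_features)
        if m.effect_scale != 0.0:
            s = max(1, math.ceil(m.effect_sparsity * m.n_features))
            idx = rng.choice(m.n_features, size=s, replace=False)
            mags = np.abs(rng.standard_normal(s)) + 0.2  # no vanishing entries
            vals = rng.choice([-1.0, 1.0], size=s) * mags
            beta[idx] = vals * m.effect_scale / np.linalg.norm(vals)
        return beta

    betas: dict[tuple[str, str], np.ndarray] = {}
    shared = {m.name: _draw_beta(m) for m in config.modalities} if config.shared_beta else {}
    for d in config.diagnoses:
        for m in config.modalities:
            betas[(m.name, d.name)] = shared[m.name] if config.shared_beta else _draw_beta(m)

    # diagnoses
    yvals, intercepts, etas = {}, {}, {}
    onset_cols = {}
    t_max = max(config.followup.visit_offsets_years) if config.followup.visit_offsets_years else 1.0
    for d in config.diagnoses:
        eta0 = np.zeros(n)
        for m in config.modalities:
            w = d.modality_weights.get(m.name, 0.0)
            if w != 0.0:
                eta0 = eta0 + w * (X[m.name].to_numpy() @ betas[(m.name, d.name)])
        if d.interaction_strength != 0.0:
            eta0 = eta0 + d.interaction_strength * z_bio * z_psy
        if d.confounder_weight != 0.0 and len(config.confounders):
            eta0 = eta0 + d.confounder_weight * c_centered.sum(axis=1)
        c0 = _calibrate_intercept(eta0, d.base_rate)
        p = _sigmoid(c0 + eta0)
        yvals[d.name] = (rng.random(n) < p).astype(int)
        intercepts[d.name] = c0
        etas[d.name] = eta0
        # onset: exponential hazard proportional to exp(eta0), administrative
        # censoring at the last follow-up offset
        lam = config.followup.hazard_scale * np.exp(eta0 - eta0.mean())
        t = rng.exponential(1.0 / lam)
        event = t <= t_max
        onset_cols[f"time_{d.name}"] = np.where(event, t, t_max)
        onset_cols[f"event_{d.name}"] = event.astype(int)
    y = pd.DataFrame(yvals, columns=[d.name for d in config.diagnoses])
    onset = pd.DataFrame(onset_cols)

    # pain sites: cumulative-logit spread model on the two primary latents,
    # equally spaced cutpoints alpha_k = 0.2 + 1.0 * k for k sites reached
    eta_pain = config.pain.psychosocial_weight * z_psy + config.pain.biological_weight * z_bio
    n_sites = config.pain.n_sites
    cuts = 0.2 + 1.0 * np.arange(n_sites)
    u = rng.random(n)
    # count = number of cutpoints cleared: P(count >= k+1) = sigmoid(eta - cuts[k])
    count = (u[:, None] < _sigmoid(eta_pain[:, None] - cuts[None, :])).sum(axis=1)
    pao = rng.random(n) < _sigmoid(eta_pain - config.pain.pain_all_over_cutpoint)
    chronic = np.zeros((n, n_sites), dtype=int)
    site_order = rng.random((n, n_sites)).argsort(axis=1)
    for i in range(n):
        if not pao[i] and count[i] > 0:
            chronic[i, site_order[i, : count[i]]] = 1
    acute = ((rng.random((n, n_sites)) < config.pain.acute_rate)
             & (chronic == 0) & (~pao[:, None])).astype(int)
    pain_cols = {}
    for j, s in enumerate(SITE_NAMES[:n_sites]):
        pain_cols[f"chronic_{s}"] = chronic[:, j]
    for j, s in enumerate(SITE_NAMES[:n_sites]):
        pain_cols[f"acute_{s}"] = acute[:, j]
    pain_cols["pain_all_over"] = pao.astype(int)
    pain = pd.DataFrame(pain_cols)

    # medication families: Bernoulli with diagnosis-conditional rates
    any_dx = y.to_numpy().any(axis=1) if len(config.diagnoses) else np.zeros(n, bool)
    rate = np.where(any_dx, config.med_dx_rate, config.med_base_rate)
    med = pd.DataFrame(
        {f"med_{k}": (rng.random(n) < rate).astype(int)
         for k in range(config.medication_families)}
    )

    if config.missing_rate > 0.0:
        for m in config.modalities:
            mask = rng.random(X[m.name].shape) < config.missing_rate
            X[m.name] = X[m.name].mask(mask)

    truth = {
        "beta": betas,
        "latents": latents,
        "bio_modality": bio_modality,
        "psy_modality": psy_modality,
        "z_bio": z_bio,
        "z_psy": z_psy,
        "eta": etas,
        "intercept": intercepts,
        "eta_pain": eta_pain,
        "spread_count": count,
    }
    return CohortTable(subject_id=subject_id, X=X, C=C, y=y, onset=onset,
                       pain=pain, med=med, truth=truth)


# ---------------------------------------------------------------------------
# phenotype derivation and control selection
# ---------------------------------------------------------------------------

def derive_pain_phenotypes(cohort: CohortTable) -> pd.DataFrame:
    """Derive the 14 binary pain phenotypes from the site indicators.

    Returns any-chronic, any-acute, seven per-site chronic phenotypes,
    pain-all-over, and four spread categories counting distinct chronic sites
    (1, 2, 3, 4+). Subjects with the pain-all-over flag count as any-chronic
    but are excluded from the per-site and spread phenotypes; a subject with
    every indicator at zero is a pain-free control.
    """
    pain = cohort.pain
    sites = [c.removeprefix("chronic_") for c in pain.columns if c.startswith("chronic_")]
    chronic = pain[[f"chronic_{s}" for s in sites]].to_numpy()
    acute = pain[[f"acute_{s}" for s in sites]].to_numpy()
    pao = pain["pain_all_over"].to_numpy().astype(bool)
    contradictory = pao & (chronic.sum(axis=1) > 0)
    if contradictory.any():
        bad = np.flatnonzero(contradictory)[:5]
        raise DataError(
            f"pain-all-over set together with site indicators for subjects {bad.tolist()}"
        )
    n_sites_chronic = chronic.sum(axis=1)
    out = {
        "chronic_any": ((n_sites_chronic > 0) | pao).astype(int),
        "acute_any": (acute.sum(axis=1) > 0).astype(int),
    }
    for j, s in enumerate(sites):
        out[f"chronic_{s}"] = chronic[:, j]
    out["pain_all_over"] = pao.astype(int)
    for k in (1, 2, 3):
        out[f"spread_{k}"] = ((n_sites_chronic == k) & ~pao).astype(int)
    out["spread_4plus"] = ((n_sites_chronic >= 4) & ~pao).astype(int)
    return pd.DataFrame(out)


def select_controls(cohort: CohortTable) -> np.ndarray:
    """Indices of subjects negative for every configured diagnosis."""
    if cohort.y.shape[1] == 0:
        raise DataError("no diagnosis labels present")
    mask = cohort.y.to_numpy().sum(axis=1) == 0
    if not mask.any():
        raise DataError(
            f"empty control set: all {cohort.n_subjects} subjects carry a diagnosis"
        )
    return np.flatnonzero(mask)


# ---------------------------------------------------------------------------
# text output
# ---------------------------------------------------------------------------

def write_cohort(cohort: CohortTable, out_dir: str, sep: str = "\t") -> list[str]:
    """Write the cohort as delimited text: one features file per modality,
    confounders, labels (+ onsets, pain, medications) and a planted-truth file.

    Returns the list of files written (relative names, sorted).
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    written = []

    def _emit(df: pd.DataFrame, name: str) -> None:
        table = df.copy()
        table.insert(0, "subject_id", cohort.subject_id)
        write_table(table, os.path.join(out_dir, name), sep=sep)
        written.append(name)

    for mname, Xm in cohort.X.items():
        _emit(Xm, f"features_{mname}.tsv")
    _emit(cohort.C, "confounders.tsv")
    _emit(cohort.y, "labels.tsv")
    _emit(cohort.onset, "onsets.tsv")
    _emit(cohort.pain, "pain_sites.tsv")
    _emit(cohort.med, "medications.tsv")
    rows = [
        {"modality": mname, "diagnosis": dname, "feature": f"{mname}_f{j}",
         "beta": b}
        for (mname, dname), beta in sorted(cohort.truth["beta"].items())
        for j, b in enumerate(beta)
    ]
    write_table(pd.DataFrame(rows), os.path.join(out_dir, "truth_beta.tsv"), sep=sep)
    written.append("truth_beta.tsv")
    return sorted(written)
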