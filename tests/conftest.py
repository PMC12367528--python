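import numpy as np
import pytest

import painpipe as pp


def small_generator_config(seed=0, n=2000, interaction=0.0, effect_scale=1.0,
                           leakage=0.3, n_diagnoses=1, shared_beta=False,
                           confounder_weight=0.0, psy_weight=0.5):
    """Compact two-modality cohort used across the unit tests."""
    mods = [pp.ModalityConfig("blood", 20, n_latent=4),
            pp.ModalityConfig("psychosocial", 12, n_latent=3)]
    for m in mods:
        m.effect_scale = effect_scale
    confs = [pp.ConfounderConfig("age", leakage_strength=leakage),
             pp.ConfounderConfig("sex", kind="binary")]
    dxs = [pp.DiagnosisConfig(f"dx{i}", 0.15,
                              {"blood": 1.0, "psychosocial": psy_weight},
                              interaction_strength=interaction,
                              confounder_weight=confounder_weight)
           for i in range(n_diagnoses)]
    return pp.GeneratorConfig(n_subjects=n, modalities=mods, confounders=confs,
                              diagnoses=dxs, shared_beta=shared_beta, seed=seed)


@pytest.fixture(scope="session")
def small_cohort():
    return pp.generate_cohort(small_generator_config())


@pytest.fixture(scope="session")
def fast_cv():
    return pp.CVConfig(outer_folds=3, inner_folds=2, repeats=1,
                       n_hyperparameter_draws=3, base_seed=0)


@pytest.fixture(scope="session")
def small_bundle(small_cohort, fast_cv):
    return pp.nested_cv_train(small_cohort.X["blood"],
                              small_cohort.y["dx0"].to_numpy(),
                              small_cohort.C, fast_cv, name="blood:dx0")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
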