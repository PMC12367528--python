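"""Shared demo cohort for the example scripts."""

import painpipe as pp


def demo_cohort(seed=0, n=4000, n_diagnoses=1, shared_beta=False,
                interaction=0.0):
    config = pp.GeneratorConfig(
        n_subjects=n,
        modalities=[pp.ModalityConfig("blood", 52),
                    pp.ModalityConfig("psychosocial", 30)],
        confounders=[pp.ConfounderConfig("age", leakage_strength=0.3),
                     pp.ConfounderConfig("sex", kind="binary")],
        diagnoses=[pp.DiagnosisConfig(
            f"dx{i}", base_rate=0.10,
            modality_weights={"blood": 1.0, "psychosocial": 0.5},
            interaction_strength=interaction) for i in range(n_diagnoses)],
        shared_beta=shared_beta,
        seed=seed,
    )
    return pp.generate_cohort(config)
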