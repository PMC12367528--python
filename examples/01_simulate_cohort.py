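"""Generate a synthetic biobank-style cohort and derive pain phenotypes.

The generator plants a known sparse coefficient vector per modality, leaks a
confounder (age) into the features, and draws diagnoses, pain-site indicators
and onset times from the resulting latent structure.
"""

import numpy as np

import painpipe as pp

config = pp.GeneratorConfig(
    n_subjects=5000,
    modalities=[pp.ModalityConfig("blood", n_features=52),
                pp.ModalityConfig("psychosocial", n_features=30)],
    confounders=[pp.ConfounderConfig("age", leakage_strength=0.3),
                 pp.ConfounderConfig("sex", kind="binary")],
    diagnoses=[pp.DiagnosisConfig("rheumatoid_arthritis", base_rate=0.10,
                                  modality_weights={"blood": 1.0,
                                                    "psychosocial": 0.5},
                                  interaction_strength=0.5)],
    seed=42,
)
cohort = pp.generate_cohort(config)

print(f"subjects: {cohort.n_subjects}")
print(f"diagnosis prevalence: {cohort.y['rheumatoid_arthritis'].mean():.3f} "
      f"(target {config.diagnoses[0].base_rate})")

phenotypes = pp.derive_pain_phenotypes(cohort)
print("\n14 derived pain phenotypes (prevalence):")
print(phenotypes.mean().round(3).to_string())
# chronic_any counts subjects with any chronic site or pain-all-over;
# spread_k counts subjects with exactly k chronic sites (4plus: four or more).

controls = pp.select_controls(cohort)
print(f"\ndiagnosis-free controls: {len(controls)} "
      f"({len(controls) / cohort.n_subjects:.1%} of the cohort)")
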