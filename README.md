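# painpipe

A reusable, tested implementation of the biopsychosocial biomarker workflow
for chronic pain conditions: given per-subject feature tables from one or
more modalities (blood-assay-like, connectivity-like, psychosocial), a
confounder table and binary diagnosis labels, it

1. trains **deconfounded nested cross-validated ridge logistic classifiers**
   (fold-wise residualization, balanced class weights, randomized L2 search),
2. interprets them through **encoding maps** (structure coefficients) and
   averages disease-specific maps into a **composite signature** that scores
   subjects by dot product, with density thresholding and permutation-null
   validation,
3. partitions **deviance explained (D²)** into unique and shared biological /
   psychosocial contributions,
4. quantifies **biological × psychosocial synergy** via pooled log-probability
   risk scores, quintile stratification and 5×5 odds-ratio grids,
5. contrasts baseline risk groups longitudinally (**Kaplan–Meier, log-rank,
   Cox hazard ratios**) and fits a **bootstrap path model** from risks through
   diagnosis onset to pain outcomes,
6. checks robustness to **medication-family exclusion**.

Because real biobank-scale cohorts are access-restricted, the package ships a
first-class **synthetic cohort generator** that plants known effects
(coefficient vectors, confounder leakage, latent interactions, onset hazards)
so every stage can be validated against ground truth.

It is aimed at biostatisticians and epidemiologists prototyping multimodal
risk-stratification analyses on tabular cohort data.

## The model in brief

For each diagnosis *d* and modality *m*, a ridge logistic model is trained by
repeated nested CV on residualized, standardized features
*x̃ = standardize(x − C β̂_OLS)* with balanced class weights
*w_c = n / (2 n_c)*. The encoding map assigns each feature the Pearson
correlation between *x̃_j* and the model's linear decision score on the
training folds; averaging maps over the well-classified diagnoses gives the
composite signature **s**, and subject scores are *⟨s, x̃_i⟩*.

Deviance explained is *D² = 1 − deviance(model)/deviance(intercept-only)* of
a logistic refit of *y* on the logit-scale predicted probabilities, with

    unique_bio = D²_{B∪P} − D²_P,   unique_psy = D²_{B∪P} − D²_B,
    shared     = D²_B + D²_P − D²_{B∪P}.

Risk scores pool models as mean ln p̂ per subject; quintile synergy compares
the odds of diagnosis for each biological × psychosocial quintile cell
against all other participants (unconditional MLE odds ratio
(a·d)/(b·c), Haldane–Anscombe corrected when a cell is empty).

## Worked example

`examples/` contains one short script per capability. For instance,
`python examples/04_synergy_and_survival.py` generates a 20,000-subject
cohort with a planted biological × psychosocial interaction (0.5 log-odds
units) and prints

```
log-OR grid (rows: biological quintile low->high; cols: psychosocial):
 ...
high-high log-OR 0.96 exceeds high-low -1.00 and low-high -1.15: the planted
interaction is visible as synergy

Cox HR per group vs the rest of the four groups:
     term    hr  ci_lower  ci_upper   p
  low-low 2.298     2.004     2.636 0.0
 high-low 0.313     0.253     0.387 0.0
high-high 2.303     2.010     2.638 0.0
 low-high 0.308     0.248     0.382 0.0
```

The high-high cell's log-odds ratio exceeds both single-high cells — the
supra-additive signature of a genuine interaction — and the high-high group's
onset hazard is several-fold that of the mixed groups. (With a symmetric
product interaction the low-low group is elevated as well; see the note in
the script.)

`examples/02_train_classifier.py` prints the nested-CV AUC next to the AUC of
the planted linear predictor, showing the classifier operating near the
generative ceiling, and `examples/05_path_model.py` recovers a planted
pathway in which biological risk influences pain intensity only through the
diagnosis.

The full chain (simulate → train → signature → deviance → synergy → survival
→ path model, with a manifest and delimited-text outputs) runs via

```python
import painpipe as pp
manifest = pp.run_pipeline(pp.RunConfig(generator=..., cv=..., out_dir="run"))
```

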