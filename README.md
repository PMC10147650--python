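# gutwave

Drug adverse-effect prediction from gastrointestinal slow-wave electrical
features.

## The problem

Gastrointestinal motility is coordinated by rhythmic electrical pacemaker
activity ("slow waves", cycles-per-minute range) generated by networks of
interstitial cells of Cajal. Recorded on a microelectrode array (MEA) grid
before and after acute drug treatment, these signals carry a drug-specific
fingerprint: a drug that excites or inhibits receptors expressed in the gut
changes the waves' frequency, power, amplitude, upstroke slope, propagation
velocity and regularity in a reproducible, tissue-specific way. Because the
gut expresses most receptor families found elsewhere in the body, that
electrical fingerprint is a candidate predictor not only of GI adverse
effects (vomiting, diarrhea, constipation) but also of cardiovascular,
immune and psychological ones.

`gutwave` implements that idea as a tested pipeline for computational
pharmacologists:

1. **Feature extraction** — 24 "electrical features" (EFs) per recording:
   dominant/average frequency, dominant power, amplitude, period, slope and
   propagation velocity; brady-/normal-/tachy-rhythm spectral power
   percentages; multiscale sample entropy at scales 1–5; detrended
   fluctuation analysis (DFA) exponents over short, long and overall window
   ranges; and five propagation-pattern percentages (forward, backward,
   radial, colliding, unorganized) plus a pattern-change index. Recordings
   failing baseline quality checks are rejected.
2. **Dataset assembly** — per-feature percentage-change normalization
   `(X_post − X_baseline)/X_baseline × 100` (plain differences for features
   already expressed as percentages), a merge with a side-effect-resource
   (SIDER)-style table of (drug, adverse effect, role) rows with an
   *indication override* (a drug clinically indicated for a condition is
   labelled 0 for it regardless of side-effect reports), balance-ratio
   filtering (`Ratio = positives / total drugs`, keep 0.25 ≤ Ratio ≤ 0.75),
   and three dataset kinds: repeat-averaged 96-feature rows, full single
   rows, and tissue splits.
3. **Classification protocol** — per adverse effect: a pooled-variance
   two-sample *t*-test screen (keep p < 0.05), five classifier families
   (naïve Bayes, linear discriminant, classification tree, k-NN, linear
   SVM) plus an averaging ensemble, seven randomized stratified half/half
   splits, and a *random-dataset validation*: the same protocol is re-run
   on per-feature Gaussian resamples (matching each column's mean and
   sample SD) and the real model must beat the control by > 0.5 accuracy
   points (mean or best) to be kept.
4. **Refinement and reporting** — binary predictions are averaged over
   experimental repeats (strict > 0.5), optionally combined across doses
   with descending weights (1, 0.5, 0.3, 0.1, 0.05), and the seven
   randomized predictions per drug are averaged into a probability that is
   always a multiple of 100/7 %.
5. **Drug–AE network** — drugs embedded by their refined EF profile with
   positive/negative correlation pole nodes; pole separation measures the
   model's discriminability and a nearest-neighbour score quantifies
   receptor-class clustering.

Because MEA drug-screening recordings are not publicly deposited, the
package ships a first-class seeded synthetic-study generator
(`gutwave.synth`) that emulates the whole study design — drug libraries
with receptor-class structure, travelling-wave grid recordings with
per-tissue drug effects, and label tables with planted feature→AE rules —
so every stage is testable end to end.

## Worked example

```python
from gutwave.pipeline import (
    analyze_study, extract_study_features, make_planted_study, study_label_table,
)
from gutwave.refine import generate_report, format_report

# A small synthetic study: 8 drugs, 2 receptor classes, 3 doses, 4 tissues,
# 3 repeats, with planted excitatory and inhibitory adverse-effect rules.
bundle = make_planted_study(
    n_drugs=8, n_classes=2, effect_size=1.5, prevalence=0.5, master_seed=1,
    design_kwargs=dict(duration_s=120.0, fs=4.0),
)
norm, ef, rejected = extract_study_features(bundle)   # 288 conditions
table = study_label_table(bundle)
fit = analyze_study(norm, table, master_seed=2)

ae = "diarrhea"
kind, results = fit.outcomes[ae].best_validated()
print(results.summary())
```

```
AE classification protocol results
==================================================
AE:                 diarrhea
dataset kind:       tissue_split (colon)
rows / drugs:       72 / 8
balance ratio:      0.625
selected features:  14
randomizations:     7
mean accuracy:      0.818
best accuracy:      0.944
coverage > 80%:     True
validation:         PASS (control aborted at selection)
--------------------------------------------------
algorithm       mean acc  best acc
knn                0.857     0.944
ensemble           0.837     0.889
svm                0.833     0.889
naive_bayes        0.802     0.861
tree               0.802     0.833
discriminant       0.778     0.861
```

The planted "diarrhea" rule raises colonic frequency and power, so the best
model is the colon tissue split; its mean test accuracy over the seven
randomized splits is 0.818 and it passes validation (here the Gaussian
control failed to select any significant feature). The per-drug report then
averages the seven randomized refined predictions:

```python
ds_by_ae, models_by_ae = fit.report_inputs()
report = generate_report({ae: ds_by_ae[ae]}, {ae: models_by_ae[ae]}, table)
print(format_report(report))
```

```
drug        adverse effect           probability   known   hit
drug000     diarrhea                        100%       1   yes
drug001     diarrhea                          0%       0   yes
drug002     diarrhea                        100%       1   yes
drug003     diarrhea                        100%       1   yes
drug004     diarrhea                        100%       0    no
drug005     diarrhea                        100%       1   yes
drug006     diarrhea                          0%       0   yes
drug007     diarrhea                        100%       1   yes
```

Probabilities are multiples of 100/7 % (here saturated at 0 or 100 because
the planted effect is strong); `hit` compares the thresholded probability
with the known label. See `docs/methods.md` for the model details, defaults
and limitations.

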