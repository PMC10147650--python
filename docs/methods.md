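# Methods

This note documents the models, defaults and design choices behind
`gutwave`: what the synthetic-study generator emulates, how each of the 24
electrical features (EFs) is defined, and how the classification protocol,
refinement, and network stages are parameterized. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic studies

Real MEA drug-screening recordings are not publicly deposited, so the
generator (`gutwave.synth`) produces seeded stand-ins at the level of the
*study design*, not the biophysics.

**Waveform.** Each channel carries a travelling periodic wave: a sinusoidal
fundamental at the tissue's base frequency plus one second-harmonic
component (relative amplitude 0.25), with per-cycle period jitter drawn
i.i.d. per cycle (baseline coefficient of variation 0.02). The jitter gives
the entropy and DFA features a non-trivial response; the harmonic gives the
upstroke slope a handle independent of amplitude. Additive white Gaussian
noise (default SD 10 µV against a 100 µV wave) is drawn per channel.

**Tissue base frequencies** (cycles/min): stomach 5, duodenum 17, ileum 12,
colon 7 — order-of-magnitude GI slow-wave values. Only relative
(post/baseline) changes matter downstream, so these anchors are
conventions, not physiological claims.

**Propagation.** The wave travels along the grid's column (longitudinal)
axis at 600 µm/s by default; each column is delayed by an integer number of
samples (`round(fs · pitch/velocity)`), so noiseless adjacent columns are
exact time-shifted copies. Grid default: 8×8 electrodes, 300 µm pitch.

**Drug effects.** A drug's profile maps each tissue to multiplicative
effects on frequency, amplitude, slope and velocity plus an additive
increase in period-jitter SD. Libraries have receptor-class structure:
class centroids are drawn with log-multiplier SD 0.35 and drugs scatter
around their centroid with SD 0.08, so within-class effect distances are
smaller than between-class distances. Dose–response is monotone: at dose
rank r of n (rank 1 = highest) the log-effect is scaled by
`((n − r + 1)/n) ** dose_scaling` (default exponent 1), so the highest dose
expresses the full effect.

**Planted adverse-effect rules.** A rule lists (tissue, parameter,
direction) triples with an effect size `d`; drugs drawn positive (Bernoulli
with the rule's prevalence) have each listed log-multiplier shifted by
`d × 0.35`, i.e. `d` population standard deviations. The default rule set
contains three "excitatory" AEs (colonic frequency and power up, gastric
power down) and two "inhibitory" AEs (duodenal slope, amplitude and
frequency down). Rules may optionally couple positivity to receptor class
via per-class prevalences — drugs acting on similar receptors tend to share
adverse effects — which the network demo study uses (0.9 vs 0.1). A
configurable fraction of positives also emits an `indication` row to
exercise the labelling override.

**What the generator does not emulate:** interstitial-cell network
biophysics, electrode artifacts and drift, dead channels, inter-animal
covariates, real pharmacological effect magnitudes (the planted `d` is a
free parameter, not an estimate), and any ontology structure in the AE
terms. Passing tests therefore demonstrate that the *pipeline* recovers
what was planted under realistic noise — not that real recordings would
yield the same accuracies.

**Seeding.** Every recording's RNG stream derives from the study master
seed plus a stable CRC of (drug, dose, tissue, repeat, phase), so studies
are reproducible and individual recordings can be regenerated in isolation.

## Feature extraction

**Analysis band** 0.5–60 cpm everywhere. Rhythm bands are relative to the
tissue base frequency f₀: normal = [0.5·f₀, 1.5·f₀], brady below, tachy
above; the three bands partition the analysis band so the percentages sum
to exactly 100. They are computed on the channel-averaged Welch spectrum.

**Spectra.** Welch estimator, Hann window, 50 % overlap, segment length of
8 dominant periods (falling back to the whole record), zero-padded so the
frequency grid resolves 0.25 cpm. Dominant frequency is the in-band argmax
(ties broken toward the lower frequency); dominant power is the peak
density integrated over one bin.

**Events.** Channels are band-passed (order-2 zero-phase Butterworth over
the analysis band); peaks are detected with a refractory distance of half
the dominant period and prominence ≥ 3× the MAD of the out-of-band
residual (with a small relative floor for noiseless input). Each event's
trough is the preceding minimum and its onset the steepest upstroke sample.
Average frequency is 60·(n−1)/elapsed between first and last peak; period
is the mean inter-peak interval; amplitude the mean peak-to-trough; slope
the mean per-event maximum upstroke rate.

**Sample entropy** uses the Richman–Moorman convention (first n−m templates
for both the m- and (m+1)-length counts, self-matches excluded, Chebyshev
distance ≤ r), m = 2, r = 0.15 × the series' sample SD, held fixed across
the five coarse-graining scales so values are amplitude-invariant and
comparable across scales. When no (m+1)-match exists the finite cap
`ln(B(B−1)+1)` replaces +∞ so downstream t-tests stay defined; the event is
logged. A brute-force O(n²) oracle in the test suite pins the fast
implementation to ≤ 1e-12.

**DFA**: integrate the mean-removed series, detrend order-1 inside
non-overlapping windows (12 log-spaced sizes from 4 to 64 samples), and fit
log F(n) vs log n over 4–16 (short), 16–64 (long) and 4–64 (overall)
windows. White noise gives α ≈ 0.5 and its running sum α ≈ 1.5 (verified
over 20 seeds). Requires ≥ 4× the largest window (256 samples).

**Velocity** comes from adjacent-electrode cross-correlation lags
(parabolic sub-sample refinement, search limited to half a dominant period
so no phase wrapping is possible between neighbours), combined into a
plane-wave slowness vector; speed = 1/|slowness|, capped at 20 mm/s and
flagged for near-synchronous activity. Requires a 2-D grid and ≥ 4 non-flat
channels.

**Propagation patterns.** Wave anchors are the onset times of the channel
with the most events; each wave's arrival time per channel is matched by
region growing across grid neighbours (nearest event within 0.6 dominant
periods of the already-matched neighbour), which accumulates lags without
wrapping. Each matched lag field is classified: plane fit with R² ≥ 0.7 and
direction within ±45° of the longitudinal axis → forward (opposite →
backward); opposing half-grid plane fits → colliding; linear arrival time
versus distance from an interior earliest-onset source → radial; anything
else (including waves matching fewer than half the channels) →
unorganized. The pattern-change index is 1 − (modal-pattern fraction).

**Aggregation.** Per-channel scalar features are aggregated by median
(robust to dead electrodes); velocity and propagation are grid-level.
MSE and DFA are computed on a fixed subset of 4 channels spread evenly over
the grid and aggregated by median — these are the costliest features, and
medians over a spatial spread are stable because the planted dynamics are
grid-wide. MSE is computed on the band-passed trace (rhythm complexity),
DFA on the raw trace.

**Quality control** rejects a recording when > 50 % of channels are flat
(SD < 1 µV), when the band-passed amplitude is below 5 µV, or when the
channel-averaged spectrum has no in-band peak ≥ 4× the in-band median. All
thresholds live in `ExtractorConfig` (YAML round-trip provided).

## Dataset assembly

Unit-bearing features normalize as `(post − baseline)/baseline × 100`;
features already expressed as percentages normalize as plain differences.
The pattern-change index, a bounded fraction whose baseline is legitimately
0 on regular recordings, is also difference-normalized — ratio
normalization would discard every clean recording through the
degenerate-baseline error path. Zero unit-bearing baselines raise an error
and the condition is dropped and logged.

Labels: 1 iff a side-effect row exists and no indication row exists for the
(drug, AE) pair; an indication row forces 0 regardless (recorded as
provenance `indication_override`). AE matching is exact on lower-cased
names. The balance ratio is positives/total drugs; AEs with ratio < 0.25 or
> 0.75 are excluded (boundaries retained).

Dataset kinds: *full* (one row per drug–dose–tissue–repeat, 24 features),
*averaged* (one row per drug–dose; per-tissue repeat means aligned into 96
tissue-prefixed columns; untested tissues yield missing values), and
*tissue-split* (full partitioned by tissue, plus a derived intestine view
pooling the three non-gastric segments). Missing values exclude
discriminant analysis and the SVM; full datasets use the three NaN-tolerant
families, matching the 3-member vs 5-member ensemble split.

## Classification protocol

Feature screen: per-feature pooled-variance two-sample t-test between
positive and negative rows, keep p < 0.05, pairwise NaN dropping, constant
features get p = 1. No multiple-testing correction is applied at this
screen — the recorded p-values let users re-filter — and selection happens
once on the whole dataset before splitting, as in the original protocol.

Splits are stratified half/half by row (the default), with a drug-wise mode
available because row-wise splitting places repeats of one drug on both
sides. Rows are put in canonical condition order before splitting, so the
split depends only on which conditions exist, not on storage order.

Algorithm defaults: Gaussian naïve Bayes (a NaN-marginalizing variant when
missing values are present); linear discriminant (least-squares solver,
shrinkage 1e-6); Gini tree with minimum leaf 3; k-NN with k = 5 on z-scored
features; linear SVM (C = 1) with a logistic link mapping margins to
[0, 1]. Features are standardized with training-half statistics. Binary
class = score strictly > 0.5 everywhere, so a tied ensemble votes negative.
The ensemble averages member *binary* votes.

Seven randomizations per dataset (odd, to avoid ties downstream); the best
model is the (randomization, algorithm) with the highest test accuracy
among splits whose training half covers > 80 % of drugs, ties broken by
higher true-positive rate then earlier randomization. The random control
resamples each feature column independently from Normal(mean, sample SD)
with labels preserved; validation passes when the real protocol beats the
control by > 0.5 accuracy points in mean or best accuracy, or when the
control fails to select any feature.

The null-specificity check permutes labels at *row* level. Drug-level
permutation would leave each drug's repeats labelled consistently, and with
row-wise splits a memorizing classifier recovers the permuted labels
through repeat leakage — row-level permutation is the permutation under
which a leak-free harness must sit at chance.

## Refinement and reports

Order is fixed and logged: average repeat predictions within (drug, dose)
first (strict > 0.5), then combine doses with weights (1, 0.5, 0.3, 0.1,
0.05) in descending dose order as a weighted vote (strict > 0.5). With
fewer than five doses the first k weights are used so the highest dose
always carries weight 1; more than five doses is an error rather than a
silent extension. Swapping the two steps changes results on constructed
inputs, so the order is part of the contract. Each of the seven randomized
models contributes one refined binary; the report probability is
100 × positives/7, rounded to integer percent in the human-readable view
with exact fractions in the CSV/DataFrame.

## Drug–AE network

Drugs are embedded as per-drug means of the refined (t-test-selected)
features, z-scored per feature (skipped, with a warning, for a single
drug). Distances are Euclidean; similarity is 1/(1+distance). Pole nodes
sit at the positive- and negative-class centroids; pole separation is their
Euclidean distance. Drug–drug edges keep the top 10 % most similar pairs by
default; drug–pole edges always exist. Layout is force-directed for
rendering only — coordinates are non-contractual. The receptor-class
cluster score is the fraction of drugs whose nearest neighbour shares their
class.

The bundled network demo study uses two receptor classes with AE positivity
coupled to class (prevalences 0.9/0.1) and a large planted effect (d = 3):
with labels drawn independently of class, receptor-class variance is a
label-independent nuisance in the pole geometry and nearest-pole agreement
plateaus around 0.8 no matter how strong the planted effect — the coupled
construction reflects the premise that receptor pharmacology drives both
the electrical profile and the adverse effects.

## Problem sizes and numerical choices

The reference planted study used by the tests and the acceptance script is
40 drugs × 4 receptor classes × 3 doses × 4 tissues × 3 repeats (2880
recordings), simulated at 120 s / 4 Hz; the generator's defaults remain
300 s / 10 Hz. 4 Hz comfortably samples the 60 cpm analysis-band edge and
120 s leaves ≥ 256 samples for the largest DFA window; the reduced scale is
the package's choice of desk-scale study size. The network demo study is
20 drugs × 2 classes at the same acquisition settings.

Other numerical guards: zero-variance features standardize with scale 1;
velocity slowness below 1/20 000 µm/s is capped and flagged; spectral ties
resolve toward lower frequency; k-NN distance ties resolve toward lower row
index; empty bands, empty test sets, single-class labels, and < 2 events
raise typed errors rather than returning sentinels.

## Limitations

Accuracies measured on synthetic studies say nothing quantitative about
real recordings; the models are uncalibrated (scores are not probabilities
of the AE in any clinical sense); row-wise splitting leaks drug identity
between halves, which inflates absolute accuracies — the random-dataset
validation and the drug-wise split mode are the available counterweights;
dose weights are fixed, not learned; and AE labels are binary with no
frequency information.
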