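# Methods

`oscnet` implements a resting-state oscillatory-connectivity classification
pipeline for a chronic-migraine-like two-group problem, together with a
synthetic cohort generator that makes every stage testable without access
to source-space MEG recordings.  This note records the models, the
defaults and why they were chosen, the numerical conventions, and the
limits of what the synthetic experiments demonstrate.

## Connectivity model

Functional connectivity between ROI time series x and y is the
**imaginary coherence**

    IC_xy(f) = | Im( S_xy(f) / sqrt(S_xx(f) S_yy(f)) ) |,

the magnitude of the imaginary part of coherency.  A purely instantaneous
(zero-lag) dependence — the signature of linear field spread or source
crosstalk — produces a real coherency and therefore IC = 0; only
phase-lagged coupling registers.  The absolute value is taken so edge
weights are nonnegative and node strength, a sum of weights, is monotone
in coupling strength; the sign convention of the imaginary part is
otherwise arbitrary.

Cross-spectra are Welch estimates: 1024-sample segments (0.5859 Hz bins at
600 Hz — printed as 0.586 Hz), periodic Hann taper, 50 % overlap, per-
segment constant detrend, conjugate products averaged across segments.
Scaling follows one-sided density conventions (it cancels in coherency).
Per-frequency IC matrices are averaged into five band matrices using
inclusive bin-centre membership: delta 1–4, theta 5–7, alpha 8–13, beta
14–25, gamma 26–40 Hz.  Gaps between bands (e.g. 4–5 Hz) are simply
unused.  Band values are **means** over bins rather than sums, so they
remain interpretable as coherences in [0, 1]; bins where a channel has
zero power are flagged NaN, warned about, and excluded from the mean
rather than counted as zero, which would bias weights downward on
degenerate inputs.

**Estimator noise floor.**  For K averaged segments the |Im coherency| of
truly independent channels has expectation ≈ sqrt(1/(π K)) (folded-normal
mean of a 1/sqrt(2K)-scale Gaussian).  At 10 s and the default segment
length (K ≈ 10) this floor is ≈ 0.18; claims of "no coupling ⇒ band IC
below 0.1" therefore only hold once K ≳ 35.  Tests that assert the
zero-lag-blindness property use 30–40 s fixtures (or shorter segments when
the band resolution allows) for exactly this reason; at the 5-minute
default recording length the floor is ≈ 0.03 and negligible.

## Networks and features

Five networks are defined over 22 bilateral cortical ROIs (24 with the
optional precuneus): pain-related (MI, SI, SII, ACC, insula), default
mode (MF, IP, PCC, LT, MT), sensorimotor (SI, SII, MI), visual (V1), and
insula–DMN.  The insula–DMN network is **bipartite**: only insula↔DMN
edges contribute, since within-DMN edges are already represented by the
DMN network itself.  The precuneus is excluded from the default DMN and
available behind a toggle, because the two membership listings that exist
for this parcellation disagree; no attempt is made to decide which one
produced any published figure.

The node strength of ROI r in network N is Σ_{r'∈N, r'≠r} IC[r, r']
(opposite-part co-members only for bipartite networks).  One feature
exists per (network, band, ROI); an ROI shared between networks (e.g. SI
in PN and SMN) yields distinct features because its co-member set — hence
its strength — differs.  With the default catalog this gives
(10+10+6+2+12) × 5 = 200 features.

## Feature selection

Per-feature independent two-sample t-tests (pooled-variance Student by
default; Welch optional — the source method statement does not specify)
with Benjamini–Hochberg step-up FDR adjustment, q = 0.05.  Correction is
applied **within each network's feature family** by default, following the
phrase "discriminative features from each network"; a global-pool mode is
provided because the alternative reading is equally defensible.  Tests of
family-wise calibration use the global mode, under which the probability
of any selection on a global null is ≈ q; with five per-network
corrections that probability compounds to ≈ 1 − (1−q)^5 by construction.
The selection result is serialised with feature *ids* and re-applied by
id, never by column position, so held-out tables (even with permuted
columns) are filtered identically.

Features with zero within-group variance get t = 0, p = 1 by convention
(logged); q = 0 legitimately selects nothing.

## Classifiers

Five families — CART decision tree (depth ≤ 8), linear discriminant
(lsqr solver, Ledoit–Wolf shrinkage), gaussian naive Bayes, SVM (linear
or gaussian kernel, C = 1), kNN (k = 5, Euclidean on standardised
features) — fitted with scikit-learn.  Gaussian kernel-scale presets
follow the common toolbox convention: medium = √P, fine = √P/4,
coarse = 4√P for P selected features, with gamma = 1/scale².  The fine
preset is deliberately narrow and is not expected to generalise even on
separated clouds; it is included for completeness of the grid.

"5-fold leave-one-out cross-validation" is contradictory on its face; it
is implemented as **stratified 5-fold CV** (the stated fold count, and the
common reading), with a leave-one-out option.  Standardisation (mean/SD,
with an SD floor for constant columns) is fitted inside each training
fold only.  Metrics — accuracy (%), sensitivity, specificity, AUC — are
computed once on the **pooled out-of-fold predictions** rather than
averaged per fold, which is stabler with small folds; the choice is
stated here so results are reproducible.  The positive class is the
patient-like group (CM), so sensitivity counts detected patients.  AUC
uses the midrank (Mann–Whitney) formula, ties ½; ROC curves are reported
both from continuous decision values and from predicted labels.

Fitted models are frozen by extracting the fitted parameters (support
vectors and dual coefficients, hyperplane coefficients, class means and
variances, tree arrays, or the training set for kNN) into JSON, and
decision scores are recomputed natively from those parameters — a saved
model reloads to bit-identical predictions, and external validation can
be proven refit-free by comparing serialisations.

Model ranking evaluates the 11 network combinations (every PN-containing
subset of {PN, DMN, SMN, Ins-DMN} plus each single network) against the
algorithm grid; rows with CV accuracy < 75 % **or** AUC < 0.75 are
flagged excluded (both readings of "performance values below 0.75" are
enforced, with separate flags stored).

## Permutation significance

Group labels are shuffled and the full training pipeline re-run per
permutation; by default feature selection is refit inside each
permutation, since reusing the observed selection leaks information and
is optimistic.  The default p-value uses add-one smoothing,
p = (1 + #{null ≥ observed}) / (n_perm + 1), which cannot return 0; the
literal exceedance proportion #{null > observed}/n_perm is reported
alongside for comparability.  When a permutation selects no feature the
majority-class rate is recorded for that draw (no usable classifier
exists).  Calibration tests run 500 replicates at n_perm = 199 — reduced
from the 10,000-draw default, which is impractical to repeat hundreds of
times — and check the rejection rate at α = 0.05.

## Shapley attribution

Features are players in a cooperative game whose value is the model's
continuous decision score with out-of-coalition features marginalised
over a background sample (interventional expectation; the background is a
seeded subsample of the training set, ≤ 100 rows).  Exact mode enumerates
all 2^P coalitions with Shapley weights (refused above P = 12); sampled
mode averages marginal contributions along seeded random feature
permutations.  Both modes satisfy efficiency *exactly* (telescoping sums),
and symmetry/null-player hold exactly in exact mode and to sampling noise
otherwise.  Attributions are summarised as mean |value| per feature,
summed per ROI area across networks and bands (the published aggregation
to "brain areas" is not specified further), then averaged across the
models that survive the exclusion rule.

## Synthetic cohorts

Each ROI channel is 1/f^a background noise (default a = 1, plus a white
floor carrying 25 % of background variance — amplitude spectra of
source-space current density are not characterised in the source
material, so this is an explicit modelling assumption) at 600 Hz for
5 minutes by default.  Couplings inject a shared band-limited source
(white noise through a 4th-order two-pass Butterworth band-pass,
stationary and reproducible) into both edge endpoints; the second
endpoint receives the source with every spectral component rotated by the
configured phase lag (analytic-signal rotation), so the lag is exact
across the band — an integer-sample delay would make the lag
frequency-dependent.  Coupling amplitude is per group, in units of
background SD.  Per-subject randomness derives from (config seed, subject
index) through numpy's seed-sequence mechanism, so any subject can be
regenerated in isolation and cohorts are bit-reproducible.

The default study regime mirrors the training problem: 56 controls vs 80
patients, with the patient group's coupling reduced (0.8 → 0.3) on eight
edges spanning PN (theta/alpha/beta/gamma), DMN (beta/gamma), a
PN-SMN-shared edge, and insula–DMN (beta/gamma), with the visual network
left intact — the "decreased connectivity in patients" pattern.  A
ground-truth manifest lists every (network, band, ROI) feature touched by
an edge whose strength differs between groups, enabling exact
sensitivity/specificity scoring of the selection stage.

**What the generator does not emulate:** physiological nonstationarity,
1/f slope heterogeneity across cortex, amplitude–phase cross-frequency
structure, residual sensor artifacts, volume-conduction leakage between
ROIs (couplings are planted with pure lags; real source reconstructions
mix), and demographic covariates.  Passing tests therefore demonstrate
that the pipeline is correct and well-calibrated under its stated
assumptions — not that the classifier would reach any particular accuracy
on clinical recordings.

## Problem sizes in the test suite

Simulated experiments are sized for a single CPU: selection-calibration
nulls use 200 cohorts of 20+20 subjects at 10 s; recovery runs plant a
d ≈ 2 node-strength effect (strengths 0.55 vs 0.30, 20 s recordings);
classifier-recovery and generalisation runs use ten seeded 56+80 training
and 14+20 held-out cohorts at 20 s; the acceptance script uses 40 s
recordings.  Recording length trades only estimator variance against run
time; the defaults above keep every property comfortably inside its
asserted bound (see the noise-floor note).

## Known limitations

* The per-network vs pooled FDR question and the fold-pooled vs
  fold-averaged metric question are resolved by documented defaults with
  the alternative available, not by evidence.
* kNN serialisation stores its training matrix; model files for large
  cohorts are correspondingly large.
* Exact Shapley is exponential and capped at 12 features; sampled-mode
  error scales as 1/sqrt(n_samples) per entry.
* The permutation test re-fits the entire pipeline per draw; at the
  published 10,000 iterations this is expensive and is intended for
  one-off significance, not repeated calibration studies.
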