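# Methods

This note documents the models, estimators, numerical choices and
limitations of `qeegpred`: a pipeline that extracts quantitative sleep-EEG
biomarkers from 19-channel (10–20 system) recordings and builds a logistic
prediction model for encephalopathic evolution of childhood focal epilepsy
(SeLECTS → EE-SWAS).

## Synthetic cohort generator

Real patient EEGs are not available, so every stage is validated against
simulated recordings with exactly known ground truth.

**Background.** Gaussian noise shaped in the frequency domain to
power ∝ 1/f^β, default β = 1.5 (sleep-like), per-channel RMS 20 µV.
Optional band-limited components (band-restricted Gaussian noise, unit RMS
scaled to a requested amplitude) add oscillatory peaks; defaults give both
groups 6 µV theta and alpha components on top of the 1/f floor.

**Coupling.** For each listed electrode pair, a narrow-band source (1 Hz
bandwidth centred on the band's centre frequency f₀) is added to both
channels; the second channel's copy is delayed by τ = φ/(2πf₀), so the
pair carries phase lag φ at f₀ (applied as an exact frequency-domain time
shift).  Coupling strength c mixes the shared source with independent
same-band noise at constant power: √(1−c²)·independent + c·shared.  Zero
lag reproduces the volume-conduction confound: PLV sees it, PLI/wPLI do
not.

**Spike-wave complexes.** A biphasic sharp transient (40 ms) followed by a
half-sine slow wave (300 ms), amplitude 5 × the channel SD, at Poisson
onsets.  Each injection is appended to the annotation list, so SWI/SWF
have event-level ground truth; morphology is deliberately stereotyped
because only timing and coverage matter downstream.

**Group contrasts** (`study_cohort_spec`, the study conditions): the
EE-SWAS-like group has spike rate 0.42/s vs 0.35/s (so the SWF scale
matches the reported group means of ≈42 vs ≈35 per 100 s), alpha amplitude
4 µV vs 6 µV (lower relative alpha), delta coupling with lag π/4 vs lag 0
at equal strength 0.8 (higher delta wPLI without separating PLV — the
same rationale that motivates lag-based metrics on real data), and a ring
-lattice vs random coupling topology of 19 pairs (longer delta CPL).
Subject-level parameters get multiplicative log-normal jitter (σ = 0.15).
`effect_scale=0` collapses both groups onto the benign parameters (a null
cohort).  All draws descend from a single root seed via
`SeedSequence.spawn`; subject k uses child k, with fixed sub-spawns for
background, coupling and spikes.

**What the generator does not emulate:** sleep architecture (spindles,
K-complexes, stage transitions), ocular/muscle artifacts, realistic
volume conduction through a head model (sources are injected at
electrodes, so the CSD transform acts as a spatial filter on sensor
mixtures rather than a true de-blurring), or the clinical population's
feature distributions.  Passing tests therefore demonstrate correctness of
the estimators and the direction-recovery behaviour of the pipeline, not
clinical performance.

## Preprocessing

Zero-phase band-pass 1–40 Hz: Hamming-window linear-phase FIR, transition
width 25% of the band edge (≈6600 taps at 500 Hz), applied with exact
group-delay compensation via frequency-domain multiplication of the
reflection-padded signal by the filter's delay-compensated (purely real)
response.  Resampling to 500 Hz is polyphase and anti-aliased; upsampling
is rejected.  The first 5 minutes (or the full recording, rounded down to
whole epochs, when shorter) is cut into contiguous half-open 2-s epochs;
concatenating them reproduces the segment exactly.  Artifact handling is
an amplitude-threshold flag (±200 µV, data unchanged) standing in for
manual review; synthetic data is generated clean, so rejection is
exercised only in targeted tests.  Common average referencing subtracts
the instantaneous 19-channel mean.  For connectivity, a spherical-spline
surface-Laplacian CSD (spline order 4, regularisation 1e-5, 50 Legendre
terms; electrode positions from the standard 10–20 montage) is applied;
because the transform is linear and instantaneous it is extracted once as
a 19×19 operator and cached.

## Spike burden

SWI counts 1-s bins [k, k+1) having positive-length overlap with any
event, on any channel; overlapping events never double-count a bin.  SWF
counts event onsets inside the window per 100 s, so long or split
complexes are not double-counted by duration.  The screening gate excludes
subjects with SWI ≥ 50% (boundary inclusive).

## Spectral features

Welch PSD with 2-s Hamming windows, 50% overlap, 0.5 Hz resolution,
one-sided density in µV²/Hz, without detrending (the signal is already
high-passed at 1 Hz).  Band powers integrate the density over half-open
intervals [low, high) — 4 Hz belongs to theta, 8 Hz to alpha, 13 Hz to
beta — so the bands partition the axis.  Relative power divides by the
1–40 Hz total (the filtered range); zero total power raises instead of
silently producing zeros.  Whole-brain values are arithmetic means over
channels.

## Connectivity

Band-filtered analytic signals come from one FFT of the concatenated
epochs: the band's zero-phase FIR response and the Hilbert positive
-frequency gain are applied in the frequency domain, one inverse FFT per
band.  Metrics are computed within each 2-s epoch over the central 80% of
samples (Hilbert edge distortion) and averaged across epochs, in single
precision (sample means of unit-scale quantities; error ≪ any tolerance
used).  sign(0) counts as 0 in PLI, so identical signals give exactly 0.
wPLI uses the per-sample cross-spectrum S = z_a·conj(z_b); an epoch with
an all-zero imaginary part is undefined (NaN) and excluded from the
average rather than counted as 0.  The per-epoch estimator implies a
sampling floor set by the effective samples per epoch (≈2·bandwidth·T),
noticeably high for delta with 2-s epochs; this floor is a property of
the estimator, not a bug, and matches the magnitude of published global
values.  Graph edges use a separate across-epoch PLV: single Hann taper
per 2-s epoch, spectra decimated to the 1 Hz grid, per-bin modulus of the
across-epoch mean unit cross-spectrum, averaged over in-band bins.

## Network metrics

Proportional thresholding keeps the top round(s·171) pairs by weight,
ties broken by lexicographic electrode-pair order (deterministic).  CPL
uses edge lengths 1/weight and Floyd–Warshall all-pairs distances
(numba-compiled); when thresholding disconnects the graph the mean is
taken within the largest connected component and the disconnection is
logged.  CC is the Onnela geometric-mean-triangle coefficient on
max-normalised weights, 0 for nodes of degree < 2.  Sigma compares CC and
CPL with degree-preserving Maslov–Sneppen rewired nulls (10 accepted
swaps per edge, weights shuffled onto the rewired topology), γ = CC/⟨CC₀⟩,
λ = CPL/⟨CPL₀⟩, Σ = γ/λ; if a sparse graph draws an all-triangle-free
null ensemble the ensemble is redrawn once, and Σ is NaN if the mean null
CC is still zero.  Each metric is computed on the sparsity grid
0.10–0.50 (step 0.05) and summarised by the trapezoidal integral divided
by the grid width — the sparsity-averaged value on the metric's own scale
("normalised AUC"; the interval-width normalisation is our reading of an
ambiguous convention, recorded here).  Sigma is computed per sparsity and
then AUC-summarised.

## Prediction model

Continuous features use Shapiro–Wilk (α = 0.05) per group to choose
between the t-test and Mann–Whitney U; categoricals use Pearson chi-square
without continuity correction (this choice reproduces the published 2×2
p-values exactly; Yates is available behind a flag), switching to
Fisher's exact when an expected cell is below 5.  p-values are BH-FDR
corrected within the feature family.  Univariable logistic screening
keeps features with FDR-adjusted Wald p < 0.20; constant features are
dropped, separated fits are retained with a warning.  The multivariable
step is backward elimination by likelihood-ratio test, removing the least
significant variable while its removal p exceeds 0.10; an IQR-categorised
variable's quartile dummies are removed as a block, and its training
cut-points are stored for reuse on new data (values outside the training
range fall into the extreme categories).  When the screen passes more
candidates than one per ten subjects, only the smallest adjusted p-values
enter the stepwise — an events-per-variable guard that also stabilises
bootstrap refits.  Near-collinear candidate sets that make the Newton
Hessian singular fall back to BFGS.  Standardised (per-SD) log-odds are
reported alongside raw coefficients.

The nomogram assigns the design column with the largest |β·range| a 0–100
point span; other columns scale proportionally, and total points map to
probability through the logistic inverse link, so the nomogram reproduces
model probabilities exactly up to point rounding (< 0.01 verified).
Discrimination is the Mann–Whitney AUC with a DeLong CI (bootstrap CI
behind a flag); calibration uses decile-of-risk bins and the
Hosmer–Lemeshow χ² with df = bins − 2 (empty deciles merged with a
warning); decision curves report net benefit against treat-all and
treat-none.  Internal validation is Harrell's bootstrap optimism: the
whole screen + stepwise pipeline is refit on each resample, optimism is
the mean of (resample AUC − resample-model AUC on the original data), and
one-class resamples are redrawn and counted.  With aggressive selection
on null data the corrected AUC is an honest but noisy estimate (per-seed
SD ≈ 0.06) and the plain bootstrap under-corrects fit-all models — known
properties of the estimator; validation claims in the tests are therefore
made on Monte-Carlo means.

## Problem sizes

Study-scale defaults follow the source cohorts: 300-s recordings at
500 Hz, 64 + 42 training subjects, 100 Sigma nulls, 1000 bootstrap
resamples.  The replicated end-to-end validation (and the acceptance
script) uses reduced sizes chosen as this package's own simulation design:
16–20 s recordings (8–10 two-second epochs), 5–8 Sigma nulls, 100
bootstrap resamples, 20 replicates of 60 + 40 training plus 12 + 8
held-out subjects.  With large engineered effects these sizes give
essentially perfect held-out discrimination, which is the intended regime
for direction-recovery checks.

## Known limitations

Sensor-level injection means CSD cannot fully localise the simulated
sources; strong injected amplitudes leak weak zero-lag components into
many pairs.  The per-epoch wPLI floor compresses the dynamic range of the
delta-band coupling contrast to a few hundredths — comparable to the
published group difference, and detectable only at cohort level.  Sigma
with few nulls is noisy and occasionally undefined at sparsity 0.10;
affected subjects are handled by complete-case analysis.  Backward
stepwise selection among correlated features keeps one representative per
cluster, so a "true" feature's information may enter the final model
through a surrogate (e.g. absolute instead of relative alpha power).
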