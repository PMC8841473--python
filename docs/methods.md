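# Methods

`neurofuse` implements a multimodal EEG–fNIRS analysis chain for two-condition
(neutral vs. preferred music) sessions: preprocessing, per-second feature
packaging, Normalized-ReliefF feature-level fusion, and cross-validated binary
classification. This note documents the models, estimators, defaults and
numerical choices, and what the synthetic study conditions do and do not show.

## Preprocessing

**EEG** (32 channels, 500 Hz): common-average re-reference (per-sample channel
mean subtracted), then a zero-phase Butterworth band-pass 0.5–50 Hz (order 4,
applied forward–backward with `sosfiltfilt`). Zero-phase filtering is a
deliberate choice: it preserves event latencies, so epoch boundaries and the
pre-stimulus baseline interval stay aligned with the marker table. The stimulus
epoch is the half-open window [onset+5 s, onset+205 s) with sample count
⌊duration·fs⌋ (0-based samples; the same floor convention at both device
rates). Baseline correction subtracts each channel's mean over the 10 s
immediately before stimulus onset; because that interval lies outside the
epoch, the operation is deliberately *not* idempotent. Ocular-artifact removal
by ICA is exposed only as an external pass-through hook — inputs are assumed
already cleaned (or synthetic, which contains no ocular artifacts).

**fNIRS** (44 channels, 3.91 Hz, dual wavelength 760/850 nm): a 4th-order
zero-phase Butterworth band-pass 0.01–0.1 Hz removes cardiac (~1 Hz),
respiratory (~0.2 Hz) and Mayer-wave (~0.1 Hz) physiology. The filter is
applied to fluctuations about each channel's mean intensity and the mean is
re-added (`keep_mean=True`), because the subsequent Beer–Lambert step takes a
log of the intensity ratio and needs strictly positive input. Conversion to
chromophore concentration changes inverts the modified Beer–Lambert law per
site:

    ΔOD(λ) = −log10(I/I_ref) = [ε_HbO(λ)·ΔHbO + ε_Hb(λ)·ΔHb] · d · DPF(λ)

solved as a 2×2 system per site, with ΔHbO/ΔHb in µM. Defaults: I_ref = the
channel's mean intensity over the recording, DPF = 6.0 at both wavelengths,
source–detector distance d = 3 cm, molar extinction coefficients from a
compiled in-vivo hemoglobin table (690–850 nm, linearly interpolated). All are
overridable; wavelength pairs whose extinction system is near-singular are
rejected. Epoching and 10 s baseline correction then proceed as for EEG
(filter first, then convert, then segment).

## EEG features (per channel, per 1 s window)

A 200 s epoch is packaged into 200 non-overlapping 1 s windows — one feature
row per second, the common rate at which the two modalities are fused. Row
counts are derived from the *nominal* epoch length (t_end − t_start), not the
sample count, so the 500 Hz and 3.91 Hz streams always package to identical
row counts.

* **Time-domain statistics** (6): mean; population variance (divide by N);
  mean absolute first difference δ (divide by N−1); mean absolute second
  difference γ (divide by N−2, comparing S(i+2) with S(i)); and δ/σ, γ/σ. A
  zero-variance window sets the normalized forms to 0 with a warning.
* **Band power** (5): one-sided boxcar periodogram with density scaling,
  p(f) = |DFT(w·x)|²/(Fs·Σw²), integrated by the rectangle rule over
  δ 0.5–3, θ 4–7, α 8–13, β 14–30, γ 30–50 Hz (half-open bands). With this
  scaling Σp·Δf equals the windowed signal's mean square (Parseval), which
  the tests assert to 1e−6 relative.
* **Differential entropy** (5): the Gaussian closed form ½·ln(2πe·σ̂²) in
  nats, where σ̂² is the band-limited population variance — the standard EEG
  DE estimator. The whole epoch is filtered once per band and per-window
  variances are then taken, avoiding per-window filter transients. Zero
  variance maps to a −745 sentinel with a warning.
* **Wavelet entropy** (1): db4 decomposition at 5 levels using the periodized
  orthonormal DWT (level energies then sum exactly to signal energy);
  p_i = level-i energy share over the 5 detail levels plus the final
  approximation (J = 6 components), SWT = −Σp_i ln p_i with 0·ln 0 = 0, so
  0 ≤ SWT ≤ ln 6. Wavelet family and depth are configurable.
* **RASM** (15 pairs × 17 features): the left/right ratio of every
  per-channel feature over the 15 mirrored electrode pairs of the 32-channel
  montage (midline Cz/Pz excluded). The divisor is guarded by ε = 1e−12
  (magnitude floored, sign kept), so a zero right-hemisphere value yields a
  flagged 1e12 rather than an infinity.

Total: 32·17 + 15·17 = 799 labelled columns. Every column carries a
structured (modality, channel/pair, family, band) label that round-trips
through the TSV + JSON sidecar serialization.

## fNIRS features (per channel, per chromophore, per 1 s window)

* **Window statistics** (44·2·2 = 176): the mean *absolute* concentration
  change, normalized by the nominal sample count fs·(t2−t1), and the ordinary
  population variance about the window mean. (The variance is taken about the
  signed window mean; defining it about the absolute-mean statistic would be
  internally inconsistent.)
* **GLM activation beta** (44·2 = 88): the least-squares coefficient of the
  stimulus regressor, B = (XᵀX)⁻¹XᵀY. For per-second packaging the beta is
  fitted on a causal sliding context (default 20 s) ending at each window, so
  every row carries an activation estimate; a whole-epoch fit replicated
  across rows is available via `design="whole"`. Because the epoch lies
  entirely inside the stimulus and is baseline-corrected to the pre-stimulus
  interval, a plain boxcar regressor is constant over the epoch; the sliding
  design therefore carries the stimulus regressor alone (adding an intercept
  would make it exactly collinear). The HRF kernel defaults to none (boxcar);
  the canonical double-gamma (peak ≈ 5 s, undershoot at 16 s, 1:6 ratio) is
  available and is what the recovery checks use on full recordings, where the
  regressor does vary and an intercept is included. The general `glm_beta`
  solver rejects rank-deficient designs, naming the collinear columns.

Total: 264 columns. The paper-scale analogue would print 400 rows (two 200 s
epochs) × 264; the statistic/GLM split is 176 + 88, which follows from
44 channels × 2 chromophores × the feature definitions.

**Condition contrast**: per-channel two-sample pooled-variance t-test between
the two conditions' per-window HbO means, two-sided p, significance mask at
α = 0.05 (configurable). The unit of observation is the packaged window;
windows of slow hemodynamic signals are serially correlated, so the map is a
screening statistic, not a calibrated inference (pre-whitened GLM inference is
out of scope).

## Normalized-ReliefF fusion

The fusion method is the composition: min–max normalize each modality's table
to [0, 1] per column → concatenate EEG-then-fNIRS at the shared 1 Hz row rate
→ ReliefF-weight every column → drop columns below the selection threshold.

ReliefF scores a feature by contrasting, for m probe samples S, its k nearest
same-class hits NH and k nearest other-class misses NM(C):

    ω(x) ← ω(x) − Σⱼ diff(x,S,NHⱼ)/(m·k)
                 + Σ_{C≠cl(S)} [P(C)/(1−P(cl(S)))] · Σⱼ diff(x,S,NM(C)ⱼ)/(m·k)

with diff(x,a,b) = |a[x]−b[x]|/(max(x)−min(x)) on continuous features, so
ω ∈ [−1, 1]; a constant feature has diff ≡ 0 and weight exactly 0. Neighbor
search uses the Manhattan distance over all diff-normalized features, with
ties broken by lowest sample index. Defaults: k = 10; m = "all" (one
deterministic pass over every sample in index order; an integer m draws probes
from a seeded RNG); selection threshold 0 in strict mode (ω must *exceed* the
threshold, so zero-weight constant or irrelevant features are dropped); a
`top_n` mode keeps the n largest instead. If no weight clears the threshold
the single best column is kept so downstream classifiers always see input.
The vectorized implementation is tested bit-equal against a naive
O(m·n²·p) loop reference.

Leakage policy: inside cross-validation, normalization extrema, the diff
ranges, and the ReliefF weights are all fitted on the training folds only and
applied frozen to the held-out fold. The pooled `normalized_relieff` entry
point (everything fitted once on all rows) exists for exploratory use and for
exporting the weight table.

## Classification

Six scikit-learn classifiers under fixed defaults: SVM (RBF, C = 1,
γ = "scale"), KNN (k = 5), random forest (100 trees), AdaBoost (50 stumps),
Gaussian naive Bayes, and a linear discriminant-analysis classifier. Folds are
stratified 5-fold with seeded shuffling; accuracy is the headline metric
(confusion matrices are retained per fold). The ablation grid evaluates four
fusion methods — direct splicing, normalization only, ReliefF only,
Normalized-ReliefF — across all six classifiers and reports mean accuracies
with row/column averages; per-method wall time is recorded as informational
output.

## Synthetic study conditions

The generator stands in for undeposited recordings and defines the default
study conditions: a 2-4-2-4-2 minute rest/neutral/rest/preferred/rest
paradigm (840 s), EEG at 500 Hz × 32 channels, fNIRS at 3.91 Hz × 44 sites,
and a shared trigger table.

EEG channels are sums of five band-limited noise processes (white noise
filtered into each canonical band, rescaled to δ 20, θ 10, α 15, β 5, γ 2 µV
RMS) plus 5 µV broadband noise. Condition effects multiply band amplitudes on
ten frontal/occipital electrodes, strongest in the low bands
(δ ×1.2 neutral / ×1.5 preferred, θ ×1.1/×1.3, α ×1.15/×1.3, β ×1.05/×1.1) —
moderate, plausible modulations that make the session clearly but not
trivially separable.

fNIRS ground truth is a boxcar convolved with the canonical double-gamma HRF:
ΔHbO amplitude 0.6 µM (neutral) and 1.0 µM (preferred) on the first 20
"active" sites, zero elsewhere; activation ΔHb = −⅓·ΔHbO. Systemic
oscillations (cardiac 1 Hz at 0.3 µM, respiratory 0.2 Hz and Mayer 0.1 Hz at
0.2 µM, random per-site phases) enter *both* chromophores in phase (Hb at ⅓
amplitude) — coupling them anticorrelated would nearly cancel in the 760 nm
optical density and erase the physiological peaks the filter is there to
remove. White noise: 0.2 µM on ΔHbO (activation SNR 5 by default), a third of
that on ΔHb. The concentrations are pushed through the Beer–Lambert forward
model to raw dual-wavelength intensities, so the package's inverse conversion
is exercised end-to-end. All draws derive from a single seed; identical
configs are bit-identical.

What the generator does **not** emulate: 1/f EEG background spectra, volume
conduction and inter-channel covariance, eye-blink/motion artifacts, optode
gain drift, habituation within a stimulus block, and between-subject
variability (one synthetic session ≈ one subject). Passing tests therefore
show that the chain is correct and behaves sensibly under controlled
conditions — not that the specific accuracies would transfer to real
recordings.

There is also a direct feature-level generator (planted informative columns
with a 2 SD class shift among pure-noise columns, optionally scale-mismatched
between modalities) used for the selection-ranking and ablation-direction
checks, where simulating full sessions would only add noise around the
property under test.

## Numerical choices and degenerate inputs

* Floor convention everywhere: sample counts and window edges are
  ⌊t·fs⌋, windows half-open.
* Packaged row counts come from the nominal epoch length, so both modalities
  always align row-for-row.
* Zero-variance guards: time statistics (normalized forms → 0), DE (→ −745
  sentinel), RASM (ε = 1e−12 divisor floor), min–max normalization (constant
  columns → 0), contrasts (both-groups-constant → t = 0, p = 1); each warns.
* ReliefF determinism: `m="all"` is fully deterministic; probe draws,
  fold shuffles and tree-based classifiers all consume the single run seed.
* The internal on-disk container is an `.npz` holding the float64 data plus a
  JSON metadata block; round-trips are bit-exact.

## Problem sizes used in checks

Formula-oracle comparisons run at n ≤ 1000 samples and up to 200×50 feature
matrices; parameter recovery and null calibrations use 20–100 seeded
replicates; end-to-end discriminability uses the full default 840 s session
(400 packaged rows, 799 + 264 features); table-structure checks use a
100-row subset of that session. These sizes make every property decidable
with comfortable margins while keeping a complete run of the suite and the
reproduction script short.

## Known limitations

* GLM inference ignores serial correlation (no pre-coloring/pre-whitening);
  betas are used as features, not as calibrated test statistics.
* The sliding-context beta with the default boxcar kernel is proportional to
  a context mean on baseline-corrected data; it becomes a genuinely distinct
  regression estimate only with the double-gamma kernel or on windows
  containing onset transients.
* The SNIRF reader covers raw dual-wavelength continuous-wave layouts
  (data type 1) with one stim group per condition; full probe geometry is
  not parsed (distances default to 3 cm when absent).
* Single-session scope: no subject-level pooling or leave-one-subject-out
  evaluation.
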