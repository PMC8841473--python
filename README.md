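# neurofuse

Feature-level fusion of simultaneous EEG and fNIRS recordings for
distinguishing two brain states — here, listening to *preferred* versus
*neutral* music. The package implements the full chain: reading standard
formats (BrainVision, EDF, SNIRF), the preprocessing each modality needs,
five EEG and two fNIRS feature families packaged at a common 1 Hz sample
rate, the **Normalized-ReliefF** fusion method, and a six-classifier
cross-validation harness with the fusion-method ablation. A seeded synthetic
session generator with known ground truth stands in for private recordings.

## The problem and the method

EEG (32 channels, 500 Hz, µV) and fNIRS (44 channels, 3.91 Hz, µM after
Beer–Lambert conversion) live on incommensurate scales and rates. Direct
concatenation ("splicing") of their features lets one modality dominate any
distance-based learner and drags along redundant columns. Normalized-ReliefF
addresses both:

1. **Normalize**: each feature column is min–max scaled,
   Feat′ = (Feat − min)/(max − min) ∈ [0, 1].
2. **Fuse**: the per-second feature rows of both modalities are concatenated,
   MulFeat = [Feat′₁ … Feat′ᵢ].
3. **Weight** (ReliefF): each feature x gets a relevance weight from k-nearest
   hits NH and misses NM over m probe samples S,

       ω(x) ← ω(x) − Σⱼ diff(x,S,NHⱼ)/(m·k)
                    + Σ_{C≠cl(S)} [P(C)/(1−P(cl(S)))] Σⱼ diff(x,S,NM(C)ⱼ)/(m·k)

   with diff(x,a,b) = |a[x]−b[x]|/(max(x)−min(x)), so ω ∈ [−1, 1]: a feature
   that separates classes gets a positive weight, an irrelevant one drifts
   to 0, a misleading one goes negative.
4. **Select**: columns with ω below the threshold (default 0) are dropped.

Upstream, EEG features per channel per 1 s window are six time-domain
statistics [µ, σ², δ, δ/σ, γ, γ/σ], periodogram band powers and Gaussian
differential entropies ½ln(2πeσ²) for the δ/θ/α/β/γ bands, wavelet entropy
−Σpᵢ ln pᵢ of the db4 level-energy distribution, and RASM left/right ratios
over 15 symmetric electrode pairs (799 columns). fNIRS features per channel
per chromophore are window statistics [mean |x|, variance] and a GLM
activation beta B = (XᵀX)⁻¹XᵀY against the stimulus regressor (264 columns).
Inside cross-validation every data-dependent step (normalization statistics,
ReliefF weights) is fitted on training folds only.

## Worked example

```python
from neurofuse import (SimConfig, simulate_session, ReliefFConfig, ClassifierSpec)
from neurofuse.classify import ablation_compare
from neurofuse.containers import FeatureMatrix
from neurofuse.eeg_features import extract_eeg_features
from neurofuse.fnirs_features import extract_fnirs_features
from neurofuse.pipeline import RunConfig, preprocess_eeg, preprocess_fnirs

eeg_rec, fnirs_rec, truth = simulate_session(SimConfig(seed=1))
cfg = RunConfig()
eeg_fm = FeatureMatrix.vstack(
    [extract_eeg_features(ep) for ep in preprocess_eeg(eeg_rec, cfg)])
fnirs_fm = FeatureMatrix.vstack(
    [extract_fnirs_features(ep) for ep in preprocess_fnirs(fnirs_rec, cfg)])
print("EEG features:  ", eeg_fm.shape)
print("fNIRS features:", fnirs_fm.shape)

table, _ = ablation_compare(
    eeg_fm, fnirs_fm,
    specs=(ClassifierSpec("svm", seed=1), ClassifierSpec("dac", seed=1)),
    folds=5, seed=1, relieff_cfg=ReliefFConfig(k=10, seed=1))
print((100 * table).round(2).to_string())
```

prints

```
EEG features:   (400, 799)
fNIRS features: (400, 264)
                   Splicing  Only normalization  Only ReliefF  Normalized-ReliefF  Averaged accuracy
SVM                   93.25               99.75          92.0               100.0              96.25
DAC                   99.75               99.75         100.0               100.0              99.88
Averaged accuracy     96.50               99.75          96.0               100.0              98.06
```

Reading it: the default synthetic session packages each 200 s stimulus epoch
into 200 one-second rows (400 rows total, two conditions). The scale-sensitive
SVM loses ~7 points under raw splicing; normalizing recovers it, and
Normalized-ReliefF (normalize + ReliefF selection) is best or tied-best in
every column — the qualitative ordering the fusion method is designed to
produce. On easy synthetic sessions the gap is small; it widens with
scale-mismatched, noise-heavy features (see the ablation tests).

The same run from the shell, plus a full pipeline with all six classifiers,
HbO contrast map and results tables:

```bash
neurofuse simulate --seed 1 --out session/
neurofuse run --config examples/pipeline.toml
```

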