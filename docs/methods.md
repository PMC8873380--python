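# Methods

## Problem and model

The package decodes a binary affective state — initial romantic attraction
*engendered* vs *un-engendered* — from epoched EEG recorded while a
participant views photographs of potential partners. The class label comes
from the participant's own 0–3 dating-interest rating (2–3 positive, 0
negative, 1 excluded as ambiguous). The working hypothesis, standard in
affective EEG decoding, is that the state expresses itself as
(i) event-related changes in oscillatory band power relative to the
pre-stimulus baseline (notably alpha/beta desynchronization over posterior
cortex) and (ii) hemispheric asymmetries of those changes (notably
frontal/parietal alpha asymmetry). The feature set measures exactly these
two quantities and nothing else; classification is deliberately generic
(a random forest).

## Feature extraction

**Time–frequency decomposition.** Each channel is convolved with
unit-energy, five-cycle complex Morlet wavelets at integer frequencies
1–49 Hz; squared magnitudes are sampled on a nominal 12-ms hop grid. Two
discretization facts are worth stating plainly:

* 12 ms is not an integer number of samples at 512 Hz (6.144). The grid is
  an exact 12-ms lattice anchored at stimulus onset, with each grid time
  evaluated at the nearest sample (indices alternate between steps of 6
  and 7 samples).
* −0.2 s is 102.4 samples at 512 Hz. The epoch holds
  `round(512 × 2.2) = 1126` samples on the half-open interval
  [−0.2, 2.0) s; no sample falls exactly on t = 0, baseline samples are
  those with t < 0.

**Windows and band averages.** For band *w* and channel *i*, V is the mean
of grid power first over the band's frequency bins and then over the grid
times of the viewing window [0, 2.0) s; B likewise over the baseline
window [−0.2, 0) s. Both windows are half-open on the grid. The PSF is
(V − B)/B; any consistent wavelet normalization cancels in this ratio, as
does any per-epoch scale factor (tested as an invariance).

**Band-edge binning.** The printed band edges overlap (4, 8, 13, 30 Hz).
On the 1-Hz grid each boundary bin belongs to the lower band exclusively
(half-open `[fmin, fmax)`), except gamma which keeps 49 Hz, so every bin
belongs to exactly one band: delta {1–3}, theta {4–7}, alpha {8–12},
beta {13–29}, gamma {30–49}.

**Edge handling (the one genuinely open numerical choice).** A five-cycle
wavelet at 1 Hz spans several seconds — longer than the whole epoch — and
even at 13 Hz its support exceeds the 0.2-s baseline. Every
time–frequency cell therefore carries a validity flag (full wavelet
support inside the epoch, support defined as the ±5σ kernel actually used
in the convolution). Band averages use valid cells only, per frequency;
for a frequency with *no* valid cell in the requested window — unavoidable
for all bands below ~26 Hz in the baseline window — the average falls back
to the zero-padded cells of that frequency. The fallback biases absolute
power downward at the epoch edges, but the bias is class-independent and
largely cancels between V and B; low-frequency baselines (delta
especially) should nevertheless be treated as unreliable in absolute
terms. Passing `strict=True` turns the fallback into an error for callers
who prefer refusal over bias.

**Asymmetry scores.** AS = PSF(left) − PSF(right) per pair and band. Field
usage varies between differences of baseline-corrected quantities and raw
band powers; the baseline-corrected difference is the default because it
shares the PSF's scale invariance, and `asymmetry="power"` switches to the
raw viewing-window power difference.

## Feature selection and evaluation

* **Filter.** Two-class t-test at α = 0.05. The paired variant pairs the
  i-th engendered epoch with the i-th subsampled un-engendered epoch (the
  matching created by balancing) and requires equal counts; the subject-wise
  outer splits of nested CV leave training folds slightly unbalanced, so
  within-fold filtering uses Welch's unpaired test. If fewer than two
  features pass (possible in null runs), the two smallest p-values are
  kept so the next stage stays well defined.
* **RFECV.** scikit-learn's `RFECV` with elimination step 1, inner
  stratified k-fold (10 by default) scored by accuracy; importance is the
  forest's Gini importance. Ties in mean inner accuracy resolve to the
  smaller subset.
* **Classifier.** `RandomForestClassifier` with Gini impurity and
  max depth 30. The package default is 50 trees: at the sample sizes this
  pipeline sees (tens to a few hundred epochs per fold), forest
  performance is flat between 50 and 100 trees while step-1 RFECV costs
  ~(inner folds + 1) × n_features forest fits per outer fold, so the
  smaller default keeps a full nested run tractable on one CPU. Set
  `trees=100` for the conventional default.
* **Nested CV.** Outer `GroupKFold` over subjects (default 10 folds); all
  filtering and selection happen inside each outer training set
  (`filter_scope="within_fold"`). `"global_paper_mode"` instead applies
  the paired-t filter once to the full balanced table before the loop —
  a variant common in the literature but leakage-prone; it exists for
  comparison and is not the default. A leakage audit (mutating held-out
  rows must not change the fold's selection) is part of the test suite.
* **Metrics.** CA, SE, SP, JI, FM from the confusion counts; AUC by the
  rank (Mann–Whitney) formulation; PAM = (Σ rₖrₖ₊₁)/6 over the vertex
  order (CA, SE, SP, AUC, JI, FM). Aggregation across folds is the
  unweighted mean and sample SD (ddof = 1; a single fold reports SD 0).

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, at
the recording geometry of the emulated setup (512 Hz, 128 channels, 55
symmetric pairs, −0.2–2.0 s epochs):

* **Background**: 1/f^a noise per channel (default a = 1), unit RMS.
* **Oscillations**: constant-amplitude sinusoids with per-epoch random
  frequency (uniform within the band) and phase, amplitude set by `snr`
  (oscillation RMS : noise RMS).
* **Class effects**: for engendered epochs only, and only for t ≥ 0, the
  oscillation amplitude on the named channels is multiplied by the effect
  multiplier (pairs: multiplier on the left member, reciprocal on the
  right). The baseline segment is untouched, making the PSF the sufficient
  statistic for the planted effect and keeping baselines
  class-independent (tested).
* **Subject variability**: each subject draws a random exponent
  ~N(1, 0.1²) applied to the log multiplier, so effect sizes vary between
  subjects but a null effect (multiplier 1) stays exactly null.
* **Ratings**: engendered → 2 or 3 (equiprobable), un-engendered → 0;
  with probability `rating_noise` a rating contradicts the true class, and
  a `rating1_fraction` of trials get the ambiguous rating 1 (later
  excluded). Class prevalence defaults to 0.086 (~1 : 10.6), matching the
  severe imbalance of attraction ratings, so balancing is exercised.

Defaults for which no external anchor exists (subject-effect SD 0.1, the
acquaintance-rating distribution 0.90/0.07/0.03, SNR 1) are one-time
choices of plausible magnitude, not tuned quantities.

What the generator does **not** emulate: ERP waveshapes, artifacts
(blinks, muscle), volume conduction/channel covariance, non-stationary
amplitude envelopes, or realistic electrode geometry (the montage is
positionless pair bookkeeping). Passing tests on this data shows the
pipeline recovers the band-power/asymmetry structure it targets when that
structure is present, and finds nothing when it is absent — it does not
show that real attraction EEG carries such structure.

A note on label noise and imbalance: at prevalence p, a rating-flip rate r
sends ~r(1−p)/p of the majority class into the minority class. At p ≈ 0.09
even r = 0.02 makes ~18% of the "engendered" class effect-free, which caps
attainable sensitivity accordingly. The separable demo configuration
(`demo_config`) therefore sets rating noise to zero; the general default
keeps 0.05 as a realism reminder.

## Validation scales

The end-to-end validation runs use 10 subjects × 60 trials (a balanced
table of ~100 epochs after labeling), nested 10×10 CV at the default
configuration, with a matched effects-disabled run as the null; the RFECV
recovery experiment uses 20 seeded runs of 2 informative + 50 noise
features at n = 80 with 30-tree forests. These sizes are the package's
validation conditions; larger runs only sharpen the same contrasts.

## Known limitations

* Absolute low-frequency power (delta, low theta) is edge-biased by
  design; only its class contrast is meaningful.
* The paired/unpaired choice for the t-test filter and the PSF-vs-raw
  asymmetry definition are genuinely underdetermined in the literature;
  both are exposed as options with the defaults argued above.
* `GroupKFold` balances fold sizes, so with exactly 10 subjects each outer
  fold is one subject; per-fold metric variance is correspondingly high.
* The CLI's re-entrancy is file-existence based; it does not hash configs,
  so editing a config without `--force` (or deleting stale artifacts) can
  mix stages from different configurations.
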