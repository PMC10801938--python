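# Methods

## Problem and model

`fhrfusion` classifies fetal acidosis (umbilical-artery pH < 7.15) from the
last 30 minutes of a 4 Hz fetal-heart-rate (FHR) trace — 7200 samples.  The
classifier is multi-modal:

* an **expert branch** computes 45 hand-designed heart-rate-variability
  features (21 morphological time-domain, 14 frequency-domain, 10
  nonlinear) and projects them through two linear layers into a single
  256-wide token;
* a **signal branch** (SE-TCN) maps the raw window through a multi-scale
  depthwise-separable convolution front end (MDSC: parallel kernels
  1/3/5/7, 16 channels each) and five residual blocks of dilated causal
  convolutions (kernel 15, dilations 2, 4, 8, 16, 32, strides 3/1/3/1/2,
  channels 64/64/128/128/256) with batch norm, ReLU, dropout 0.1 and a
  squeeze-and-excitation gate on each 1×1-convolution shortcut, producing a
  400 × 256 latent sequence;
* **cross-modal fusion (CMFF)**: each modality runs intra-modal multi-head
  self-attention (8 heads × 32); each attended position is scored by cosine
  similarity against the *other* modality's time-mean embedding, softmaxed
  over positions into a cross-modal attention score (CMAS), used to weight
  the sequence before concat(GAP, GMP) pooling (512-d per modality); the
  concatenated 1024-d vector feeds a 1024→256→2 softmax head.

Training: Adam, batch 16, up to 120 epochs with early stopping, cosine
annealing from 2.5e-4 with warm restarts every 30 epochs and peak decay
0.8.  Evaluation uses stratified 5-fold cross-validation; the test
prediction is the mean of the fold-model probabilities.  Metrics are
accuracy, specificity, sensitivity, precision and F1 in percent with the
pathological class positive; ties at probability 0.5 classify as
pathological.

## Interpretive choices the architecture description leaves open

* **CMAS axis.**  The cosine-similarity score between the two attended
  latents is computed per position of one modality against the time-pooled
  embedding of the other, and the softmax normalizes over sequence
  positions.  This is the only reading that makes the subsequent
  per-position weighting non-degenerate; for the single expert token the
  CMAS is identically 1 and the weighting is the identity.
* **Expert latent layout.**  The 45 features become a one-token sequence
  (B × 1 × 256) so both modalities share head sizes (8 × 32 = 256).
* **Stride placement.**  Each block's stride sits on the first of its two
  dilated convolutions, and on the 1×1 shortcut so the two paths align.
  Sequence lengths follow ceil(L/stride): 7200 → 2400 → 2400 → 800 → 800
  → 400.
* **SE placement.**  The squeeze-and-excitation gate sits only on the
  shortcut path, as described; a config switch (`se_enabled`) removes it.
* **MDSC padding.**  "Same" padding is implemented as same-*length* padding
  applied entirely on the left, keeping the front end causal; a centered
  pad would leak up to 3 future samples through the kernel-7 branch.
* **Causality and the SE gate.**  The SE squeeze is a global time average,
  so with gating enabled every output depends (weakly) on every input —
  the gate is a per-channel scalar and carries no temporal structure, but
  strict sample-level causality holds only for the convolution stack.  The
  causality probes therefore run with `se_enabled=False`.
* **Cosine-annealing "decay".**  Read as warm restarts every 30 epochs with
  the cycle-peak learning rate multiplied by 0.8 at each restart.
* **Late fusion** trains two independent heads (one per modality) jointly on
  the mean of their cross-entropies and averages their probabilities 1:1;
  **early fusion** concatenates the time-pooled latents (512-d) before a
  single head.

## Expert features

RR is derived samplewise as RR = 60000 / FHR (ms); NN = diff(RR).  The
ordering of the 45 features is fixed (see `FEATURE_NAMES`); `SD_Ration`, a
historical spelling of the Poincaré ratio, is kept as an alias of
`SD_Ratio`.

* **Baseline** — iterated trimmed moving median: centred 10-minute rolling
  median, refined 3 times with samples > 15 bpm from the current estimate
  excluded, clipped to [50, 240] bpm.  Accelerations/decelerations are
  excursions ≥ 15 bpm from baseline sustained ≥ 15 s (FIGO convention).
* **STV** — mean absolute difference of consecutive 2.5-s epoch means of
  rr; **LTV** — mean over minutes of the range of the 24 epoch means
  within each minute.
* **Tri/TINN** — interval histogram with 7.8125 ms bins (1/128 s);
  Tri = n / max bin count; TINN is the base width of the least-squares
  triangle (searched over all (M, N) bin pairs around the mode).
* **Spectra** — the rr series is mean-detrended, linearly resampled onto a
  uniform 4 Hz grid against cumulative rr time, and transformed by an FFT
  periodogram (boxcar window).  Band powers (ms²) integrate the
  periodogram over VLF 0–0.03, LF 0.03–0.15, MF 0.15–0.5, HF 0.5–1 Hz;
  total power is defined as the sum of the four band powers so the
  percentages sum to exactly 100; `rr_ratio` = LF/(MF+HF).  Zero total
  power yields zero percentages and ratio.  Note the cumulative-time
  resampling means a spectral feature's frequency axis lives in
  cumulative-rr seconds; the test oracles generate their sinusoids in that
  same time base.
* **Nonlinear** — SD1 uses the *uncentered* second moment of successive
  differences, so SD1 = RMSSD/√2 holds exactly; SD2 is the centred
  dispersion along the identity line (the asymmetry is deliberate and
  documented).  ApEn/SampEn use m = 2, r = 0.2·std(rr); FuzzyEn uses
  mean-centred templates with membership exp(−(d/r)²); ShannEn is the
  16-bin amplitude-histogram entropy in bits; LZC is the LZ76 phrase count
  of the median-binarized series normalized by n/log2(n); FD is the
  Higuchi fractal dimension with kmax = 10; Hurst comes from rescaled-range
  analysis over log-spaced window sizes.  Degenerate constant series
  return 0 for the entropies and the Poincaré ratio, 1.0 for FD and 0.5
  for Hurst, keeping every feature finite on any cleaned input.

Entropy parameters, histogram bins and kmax are the field-standard
defaults and are exposed as function arguments.

## Preprocessing

Missing samples are encoded as 0 bpm (the WFDB convention of intrapartum
CTG archives).  The pipeline order is **filter → clean → window**: records
with fewer than 10 000 valid samples are discarded as severely incomplete;
samples outside [50, 240] bpm are treated as missing and all gaps filled
by linear interpolation between nearest valid neighbours (nearest-value
extension at the edges); the final 7200 samples are then taken.  Cleaning
is idempotent, and windowing after cleaning means gaps never shorten the
clinical window.

## Synthetic data generator

The generator emulates the statistical structure the method assumes, not
cardiotocographic physiology: baseline drawn per record around 135 ± 10
bpm with a slow sinusoidal drift (± 5 bpm, 20-min period), sinusoidal
components in the four HRV bands (4/3/1.5/0.8 bpm at 0.01/0.08/0.3/0.7
Hz, random phases), Gaussian variability (sd 2 bpm), Poisson-placed
trapezoidal accelerations (3 per 30 min) and decelerations (1 per 30 min)
of 20 bpm × 60 s, 5% of samples dropped in contiguous ~15-s runs, and
class-conditional pH from truncated normals (normal: 7.25 ± 0.05 truncated
at ≥ 7.15; pathological: 7.05 ± 0.05 truncated at < 7.15) so the labelling
rule is exercised end-to-end.  The pathological class multiplies
variability by 0.5 and adds 3 decelerations per 30 min — the direction of
the clinical picture of acidosis (reduced variability, more
decelerations).  Raw traces are 12 000 samples (50 min) so records with
modest dropout still clear the completeness filter before windowing.
These effect sizes make the classes strongly separable; passing the
learnability checks demonstrates that the pipeline can extract and fuse
the intended signal structure, **not** that it reaches any particular
accuracy on clinical recordings, where effects are weaker, noise is
structured, and labels are imperfect.

## Numerical and engineering choices

The network, autodiff and optimizer are implemented in this package on
numpy (float32 working precision): a small reverse-mode engine with a
window-gather primitive that expresses dilated causal convolution as a
matmul, strided slice-adds in its adjoint, He-normal seeded
initialization, and Adam.  Gradients of every primitive are verified
against central finite differences in float64.  O(n²) entropy kernels are
numba-compiled.  Batch norm keeps running statistics (momentum 0.1,
eps 1e-5); inference always runs in eval mode, making predictions
deterministic.  Cosine similarity adds 1e-12 inside the norms so zero
vectors score 0 and CMAS degrades to uniform weights.

## Desk-scale problem sizes

Full-width training (256-channel ladder) is reported structurally but not
trained in the test suite; the learnability study uses a width-reduced
configuration — channels (8, 8, 16, 16, 32), MDSC 2 channels/branch, 4
attention heads — with the architecture, kernel, dilations, strides and
training recipe unchanged, on 250 synthetic records (200 train / 50 test,
balanced).  The cross-modal model trains 30 epochs; the early/late fusion
baselines reported alongside train 12 epochs each.  The default backbone
at full width has ≈ 2.7 M parameters (logged for comparison; the exact
count depends on choices such as the SE reduction ratio and biases that
the architecture description leaves open).

## Known limitations

* The synthetic generator's additive sinusoid + noise + ramp model has no
  uterine-contraction coupling, no autonomic nonstationarity, and
  labels that are perfectly consistent with the generating process.
* The sparse-dictionary denoising and GAN-based minority-class synthesis
  used in the original clinical study are out of scope; cleaning is
  interpolation-based and imbalance handling is train-set-only minority
  oversampling.
* Clinical headline numbers require the CTU-UHB archive; with it, the
  documented protocol is a 444/80 split (40/40 test) with 5-fold CV on the
  training set.
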