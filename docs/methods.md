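# Methods

## Signal model and what the generator emulates

The synthetic generator produces the steady-state, amplitude-coded structure
that the pipeline assumes: for each movement and channel, a white Gaussian
carrier is passed through the same 4th-order Butterworth band-pass used by
the analysis front end (20–500 Hz by default), normalized to unit empirical
RMS, scaled by the movement's per-channel amplitude, and contaminated with
white Gaussian noise of configurable RMS. Defaults are two channels, ten
movements (T, I, M, R, L, TI, TM, TR, TL, HC), six trials of five seconds
at 2000 Hz. The amplitude table spans 0.04–0.40 with a noise RMS of 0.03,
putting per-channel SNRs in roughly the 2–23 dB range typical of wet-electrode
forearm recordings; movements T and I are deliberately weak (near the noise
floor) because discriminating weak contractions is what the nonlinear
features are for.

Normalizing the carrier to unit empirical RMS per trial makes the configured
amplitude equal the noiseless channel RMS exactly, which keeps the SNR
bookkeeping transparent.

What the generator does **not** emulate: motor-unit action potentials and
their recruitment/firing statistics, force-level dynamics, onset/offset
transients, electrode shift, power-line harmonics, or any spectral
difference between movements — classes differ *only* in amplitude pattern.
Passing tests therefore demonstrate the pipeline's arithmetic, contracts and
the amplitude-scaling mechanism; they do not predict absolute accuracy on
human recordings, where class structure is richer and noisier.

Seeding: one master seed; each (movement, trial, channel) stream is derived
through `SeedSequence([seed, movement_idx, trial_idx, channel])`, so
regenerating one trial never perturbs the rest.

## Preprocessing

* Band-pass: 4th-order Butterworth, 20–500 Hz, applied forward–backward
  (zero phase). Order and design are package choices; zero phase avoids
  window-boundary phase artefacts.
* Notch: second-order IIR at 50 Hz with quality factor 30, also zero-phase.
* Trials are filtered whole, then segmented, so windows carry no per-window
  transients.
* Windowing is disjoint, anchored at sample 0, `floor(n/window_len)`
  windows, trailing remainder discarded (5 s at 2 kHz with 250 ms windows
  → exactly 20 windows of 500 samples).
* AWGN contamination measures each channel's mean-square power and adds
  Gaussian noise of power `P/10^(SNR/10)` — the `'measured'` semantics of
  the common MATLAB `awgn` usage. For SNR sweeps, noise is injected into
  the **raw** trials, before digital filtering.

## Features

LMAV and NSV both guard their logarithm with ε = 1e-12 so constant or
all-zero windows stay finite (keeping downstream ULDA well-posed). A note
on NSV's bracketing: with a real signed cube root,
`(cbrt(d))² = (d²)^{1/3} = |d|^{2/3}`, so the two per-term readings of the
formula coincide; the `inner_square` flag exists to make that explicit.
Whether the deviation uses raw or rectified samples is a genuine choice;
raw samples are used (the deviation is taken from the rectified mean).

Classical features follow the standard Hudgins-style definitions.
Comparison conventions that matter: ZC and WAMP use `>= thr` on the jump
magnitude (defaults 0 and 0.01); SSC uses a **strict** `> thr` on the slope
product (default 0) so that flat segments — and all-zero windows — count no
slope-sign changes; MYOP uses `>= thr` with default 0.016. AR coefficients
are Yule–Walker estimates (biased autocorrelation, Levinson–Durbin via
`solve_toeplitz`) with the convention `xᵢ ≈ Σ a_k x_{i−k}`: order 6 in FS1,
order 4 in the proposed set.

TD-PSD (FS3) and TSD (FS4) estimate spectral moments in the time domain:
`m0` from `Σx²`, `m2` from `Σ(Δx)²`, `m4` from `Σ(Δ²x)²`, each root-squared,
then power-transformed `m ← m^λ/λ` with λ = 0.1 before forming
log-compressed descriptors (moments, irregularity factor `m2/√(m0·m4)`,
sparseness, waveform-length ratio; TSD adds a coefficient of variation and
summed Teager–Kaiser energy, this package's construction of those two named
descriptors). The power transform cancels in the ratio descriptors, which
are therefore scale-invariant, and the irregularity factor is exactly 1 for
a single spectral line.

Features are computed per channel and concatenated channel-major; there are
no cross-channel features.

## ULDA, RES, scatter

ULDA is computed by total-scatter whitening plus SVD of the whitened
between-class scatter: with `S_t = Σ(x−μ)(x−μ)ᵀ` (sum convention), the
fitted projection satisfies `Gᵀ S_t G = I` and has rank ≤ K−1 (singular
values below 1e-10 of the maximum are truncated). This route remains
well-posed when the within-class scatter is singular, which happens
routinely in small folds. Inside cross-validation, ULDA is refitted per
fold on training windows only, to avoid information leakage.

The RES index divides the mean pairwise Euclidean distance between class
means of a 2-D embedding by the mean within-class per-feature standard
deviation (sample SD, N−1 denominator — a deliberate convention choice).
It refuses embeddings that are not exactly 2-D rather than silently
generalizing. Scatter export fits ULDA on all windows (a visualization, so
no train/test split), takes the first two dimensions, min–max normalizes
to [0,1], and in "paper mode" keeps every 4th window — five evenly spaced
points per 20-window trial, giving the conventional 300-point plot for
10 movements × 6 trials. RES is computed on the raw (pre-normalization)
embedding; it is invariant to translation and global scaling, though not to
the per-axis rescaling min–max applies, hence the ordering.

## Classification and evaluation

"LDA with quadratic function" is read as a Gaussian discriminant with
per-class covariance (quadratic boundary), implemented with a tiny shrinkage
(reg 1e-6) and a lowered rank tolerance so near-zero within-class variance
directions — common after ULDA on well-separated data — do not abort the
fit; a pooled-covariance linear variant sits behind `quadratic=False`. The
SVM uses an RBF kernel `exp(−‖u−v‖²/2σ²)` with σ = 1 on the ULDA-reduced
features, without further standardization (the reduction already whitens
total scatter). KNN uses k = 3 with cityblock (L1) distance.

Cross-validation is leave-one-trial-out: T folds, fold t training on all
movements' trials ≠ t. Metrics come from the fold confusion matrix,
one-vs-rest per movement (accuracy, sensitivity, specificity, precision,
F1, all percent), macro-averaged; zero-denominator metrics report 0 with a
warning so sweep aggregation stays total. Reports carry per-fold values,
mean ± SD across folds, and the pooled confusion matrix.

Feature-set comparisons use a two-group one-way ANOVA with Bonferroni
correction (p × n_comparisons, capped at 1); with synthetic data,
"subjects" are independent generator seeds.

## Forward selection

Greedy: pick the best single feature, then repeatedly add the best-scoring
extension while it gains at least `min_gain` (default 0.25 points of the
scored metric; metric selectable, default macro F1). Ties break toward the
earlier pool position. The 32-feature candidate pool is the registry's
enumeration — LMAV, NSV, sixteen classical features, AR1–AR4 individually,
the six TD-PSD descriptors and the two TSD-only descriptors — documented
in `selection.DEFAULT_POOL` and overridable, since any particular study's
pool membership is a configuration, not an algorithm property.

## Problem sizes and numerical choices

The test suite and acceptance script run the default conditions
(10 × 6 × 5 s, 1200 windows) for windowing, ULDA, scatter and CV checks,
and a reduced configuration (4 movements × 3 trials × 1.4 s) for the
7-point window and 21-point SNR sweep grids — enough to exercise every axis
point while keeping a full run in seconds. The weak-movement mechanism
fixture uses five movements (two weak at amplitudes ~0.04–0.055 against a
0.03 noise floor, three strong) across three seeds.

## Known limitations

* Amplitude-only class structure means most feature sets saturate near
  100% F1 on the default conditions; differences show up mainly in the RES
  index, at short windows, and at low SNR.
* FS3/FS4 descriptor algebra has several published variants; the constants
  here (λ = 0.1, log compression) are pinned and documented but not the
  only defensible choice.
* The RBF SVM inherits the ULDA output scale; with sum-convention
  whitening the transformed distances are small, and σ = 1 is kept as
  specified rather than rescaled, so SVM scores run below LDA's on these
  conditions.
* Overlapped windowing, frequency-domain and wavelet features, and
  transient (onset) segments are out of scope.
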