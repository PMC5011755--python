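# Methods

This note documents the models, algorithms, numerical choices and known
limitations of the toolkit. It is the place where design decisions that
were genuinely open are recorded.

## Preprocessing chain

Raw SELDI-TOF spectra arrive on heterogeneous m/z axes with a slowly
varying chemical/matrix background, high-frequency detector noise, and
small rigid m/z miscalibrations. The chain is fixed as

resample → baseline correction → denoising → peak alignment → normalization

and the order is part of the contract (alignment needs a corrected,
denoised signal; normalization must come last so every earlier stage is
scale-equivariant).

* **Resampling** — linear interpolation onto a uniform grid of `grid_n`
  points (default 15,000) over [`grid_lo`, `grid_hi`] (default m/z
  2000–10000, the band where serum-protein information concentrates;
  both endpoints are grid points). Regions outside the input's support
  are set to 0.
* **Baseline** — windowed running minimum (window `baseline_window`,
  default 200 m/z units) smoothed by a uniform filter of the same width,
  subtracted; negative residuals are clipped to 0 because downstream
  normalization assumes nonnegativity. The window must sit well above
  the peak widths (serum peaks in this band have σ ≈ 5–25 m/z); a window
  comparable to a peak width would eat the peak.
* **Denoising** — wavelet (sym8) soft thresholding at depth
  `denoise_level` (default 4) with a MAD-estimated universal threshold;
  a moving-average mode is available. A zero threshold (noiseless
  input) returns the signal unchanged. Total ion current is preserved
  to well under 5%.
* **Alignment** — a single rigid m/z shift per spectrum (no warping),
  estimated by cross-correlating the spectrum with a synthetic reference
  of unit Gaussians at the configured reference peaks (defaults
  3883.321 and 7766.159). The integer-grid correlation optimum is
  refined to a sub-grid shift by parabolic interpolation — essential
  when the grid step exceeds the typical miscalibration — clamped to
  `align_max_shift` (default 10 m/z, with a warning when the optimum
  lies beyond the bound; one extra step past the bound is evaluated to
  detect this). Shifts below 2% of a grid step are treated as zero.
* **Normalization** — total-ion-current scaling to unit sum (default) or
  max-peak scaling to unit apex.

Every stage is independently switchable, so other preprocessing dialects
can be configured. The chain asserts only input/output dimensions and
qualitative behaviour (peak preservation, noise reduction, alignment to
reference positions); no claim is made that it reproduces any specific
historical preprocessing implementation bit for bit.

## PPCA

The latent-variable model s = Wx + μ + ε with isotropic noise. Two
fitters:

* `fit_ppca_closed_form` — the exact ML solution from the
  eigendecomposition of the sample covariance: σ̂² = mean of the d−q
  discarded eigenvalues, Ŵ = U_q(Λ_q − σ̂²I)^{1/2}. Attains the global
  maximum of the log-likelihood; used as the oracle for EM and as the
  default reducer in experiments.
* `fit_ppca_em` — EM on the covariance form:

      W̃ = U W (σ²I + M⁻¹WᵀU W)⁻¹,
      σ̃² = (1/d) tr(U − U W M⁻¹W̃ᵀ),     M = WᵀW + σ²I,

  iterated from a seeded standard-normal W (scaled to the data's overall
  standard deviation) until the relative change of L drops below `tol`
  (default 1e-7) or `max_iter` (default 500). The per-iteration L trace
  is recorded and checked non-decreasing (1e-8 relative slack); a
  decrease raises an internal-consistency error.

Numerical choices:

* For d > N all covariance products go through the centered data matrix
  (Gram route), keeping memory O(Nd + dq); L is evaluated through the
  q×q matrix M via the determinant lemma (ln|C| = (d−q)ln σ² + ln|M|)
  and the Woodbury identity (tr(C⁻¹U) = (tr U − tr(M⁻¹WᵀUW))/σ²). C is
  never materialized.
* σ² is floored at 1e-12 of the mean per-coordinate variance: at exactly
  zero the likelihood is unbounded for q ≥ rank(U) and the q-form
  algebra loses all precision.
* σ² = 0 with residual variance outside span(W) yields L = −∞ as an
  explicit value, not a crash.

Projections: the default `posterior-mean` mode z = M⁻¹Wᵀ(s − μ) is the
posterior expectation E[x|s]; the `adjoint` mode z = Wᵀ(s − μ) is the
plain adjoint projection used literally in some published pipelines (it
omits the M⁻¹ factor). Reconstruction uses the pseudo-inverse
composition ŝ = W(WᵀW)⁻¹z + μ, which for adjoint-mode scores is exactly
the orthogonal projection onto μ + span(W). (Published statements of
the posterior density in this family sometimes carry typographical
inconsistencies; the canonical posterior N(M⁻¹Wᵀ(s−μ), σ²M⁻¹) is
assumed throughout.)

Latent dimension: `choose_q_by_cumvar` picks the smallest q whose
cumulative variance fraction reaches a threshold (default 99.99%, the
convention for this cohort, which yields q ≈ 215 at full scale); ties
resolve to the smaller q. In experiments q is additionally capped at
n_train − 2, since the covariance of n centered samples has rank ≤ n−1
and PPCA needs residual variance outside span(W).

### Why experiments default to the closed-form fit

Both fitters target the same optimum, and the test suite verifies they
agree (σ² to 1e-4 relative, principal angle < 1e-3 rad) on small
instances run to tight tolerance. At experiment scale (d in the
thousands, q ≈ 50–150, N ≈ 150) EM under any practical iteration budget
can stop with span(W) still far from the principal subspace — measured
on a desk-scale cohort this cut PPCA-SVM accuracy from 100% to 54% while
σ² was already correct. The experiment protocol therefore uses the
exact eigendecomposition fit by default (`ppca_fit="closed-form"`);
`ppca_fit="em"` reproduces the iterative route.

### PPCA-SVM versus PCA-SVM

With the exact ML fit, the PPCA posterior-mean scores are per-component
rescalings of the classical PCA scores: W = U_q(Λ_q−σ²I)^{1/2} is
axis-aligned with the principal directions, so M is diagonal and
z_ppca = D z_pca for a fixed diagonal D. Per-feature standardization
(applied before the RBF kernel because score scales vary by component)
cancels any diagonal scaling, so the two stacks produce identical
predictions. Observed differences between PCA-SVM and PPCA-SVM in this
design can therefore only arise from the optimizer path (EM
initialization and stopping) or other implementation details, not from
the projection itself. The toolkit's comparison experiments reflect
this: the two methods tie on synthetic cohorts, satisfying the
directional expectation that PPCA-SVM is not materially worse than
PCA-SVM.

## Classification

The soft-margin RBF-SVM (minimize ½‖w‖² + cΣξ_i) is solved by
scikit-learn's libsvm binding. The toolkit owns:

* per-feature standardization learned on training scores only
  (zero-variance features get sd 1 with a warning), carried with the
  classifier so prediction never touches test statistics;
* stratified k-fold (default 10) cross-validated grid search over the
  conventional exponential grids c ∈ 2⁻⁵…2¹⁵, g ∈ 2⁻¹⁵…2³ (step 2²,
  configurable); the selection criterion is mean fold accuracy, ties
  break toward smaller c then smaller g;
* the decision threshold 0 contract: predicted label sign always
  matches the decision value used for ROC.

## Evaluation protocol

Per repeat r (seed + r): a stratified random 70/30 split (training size
= round(0.7N); per-class counts by largest-remainder rounding; every
class keeps ≥ 1 sample on each side — for 216 samples, 121/95, this
gives 151 training / 65 test with 85 positives and 66 negatives in
training); reducer fitted on the training partition only (a
`pooled_reduction` switch fits on all samples first, reproducing
protocols that select q from the pooled eigenspectrum — it leaks test
information and is off by default); grid search and SVM training on
training scores; confusion counts, percent metrics, ROC (threshold
sweep with tie grouping, trapezoidal AUC, curve anchored at (0,0) and
(1,1)) on the held-out partition. Metrics whose denominator is zero are
reported as NaN flags, never crashes. Averages are arithmetic means of
unrounded per-run values; display rounding to 2 decimals is separate.

A note on averaging published tables: for the reference 10-run
comparison table, the mean of the printed per-run sensitivity and
specificity entries reproduces the printed average row exactly (82.70 /
83.88 and 92.98 / 88.97), while the printed accuracy averages differ
slightly from the mean of their own per-run entries (83.33 vs 83.34 and
90.60 vs 90.80). The toolkit always reports true means; only the
internally consistent columns are used as numeric references.

## Synthetic cohorts

`synthspec.generate` emulates a case/control SELDI serum cohort: default
121 cancer / 95 healthy samples on a raw axis of 36,000 points over m/z
700–12000 (a full-fidelity 360,000-point mode is a config change; the
default keeps a full-cohort simulation in seconds). Each spectrum is a
sum of Gaussian peaks with class-dependent amplitudes — the hallmark
pair at 3883.321 (healthy 126 / cancer 130) and 7766.159 (719 / 608),
deliberately a weak signal on its own, plus three differential peaks
(4500, 6200, 8900) that give the default cohort a clearly separable
low-rank class signature and three class-invariant peaks — scaled by a
per-spectrum unit-mean lognormal factor (CV 0.15), shifted rigidly by a
per-spectrum N(0, 1.5 m/z) jitter (exercising alignment), over an
exponential baseline (amplitude 80, decay 2500 m/z) with additive white
noise (sd 8), truncated at zero. Peak widths, baseline and noise levels
are plausibility choices typical of matrix background and detector
noise in this band; no published noise statistics exist for the
reference cohort. Everything is deterministic under the config seed.

What passing tests on these cohorts do **not** show: real SELDI spectra
have isotope envelopes, adduct peaks, m/z-dependent peak width and
asymmetry, detector saturation and non-white noise, none of which are
modeled; absolute accuracies on synthetic cohorts say nothing about
clinical performance. The simulator's role is to give every pipeline
stage a signal with known ground truth.

`generate_latent_gaussian` samples directly from the PPCA generative
model with orthogonal ground-truth loadings; the true parameters depend
only on (d, q, scale) so replicate draws share one ground truth for
recovery tests.

## Problem sizes

Tests and the acceptance script run the full protocol at desk scale —
raw axis 6,000–12,000 points, grids of 800–3,000 points, 1–10 repeats,
a 6×5 hyperparameter grid — chosen so the complete suite runs in about
a minute on one CPU while exercising every code path at full cohort
size (216 samples). All dimensions are configuration, not code: the
full-scale protocol (360,000 → 15,000 points, 21×19 grid) is the same
calls with default configs.

## Known limitations

* Alignment estimates one rigid shift per spectrum; non-rigid warping is
  out of scope.
* No missing-data EM, mixtures of PPCA, or Bayesian (ARD) extensions.
* The SVM stage offers no probability calibration; ROC uses decision
  values.
* Statistical tests comparing the two method stacks are not provided.
* matrix/score files are plain CSV; no mzML/vendor formats, no streaming
  I/O for >10⁶-point spectra.
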