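# Methods

This note documents the models, numerical procedures and design choices
behind `eegspd`, in the spirit of the methods documentation of packages
like `statsmodels` or `msprime`: what is computed, under what assumptions,
which knobs matter, and what the synthetic benchmarks do and do not show.

## The decoding problem

Motor EEG decoding rests on the observation that imagined or executed
movement modulates oscillatory band power (alpha ~8–13 Hz, beta ~13–30 Hz,
high gamma ~60–90 Hz) at task-specific electrodes.  The sample covariance
matrix (SCM) of a band-filtered multichannel trial captures exactly this
spatial-spectral structure: variances carry per-electrode band power,
off-diagonals carry inter-electrode coupling.  SCMs of full-rank trials
are symmetric positive definite (SPD) and live on a curved Riemannian
manifold, where distances respecting the geometry (AIRM, LEM) support
stronger classifiers than naive Euclidean treatment.

`eegspd` implements two end-to-end decoders around this idea:

- **The end-to-end network** — a learnable temporal filterbank
  (free convolution kernels, or sinc-parameterised bandpass filters)
  duplicates each electrode signal `Nf` times, filters it, and a
  covariance pooling layer forms an `Nf·Ne × Nf·Ne` SCM per trial.  A
  stack of `NBiRe` BiMap→ReEig pairs (`W^T S W` with Stiefel-constrained
  `W`, then eigenvalue flooring at ε) halves the matrix dimension per
  pair; LogEig maps the result to the tangent space, a norm-preserving
  half-vectorisation flattens it, and an affine map produces class
  scores trained with softmax cross-entropy.  Filterbank and SPD stack
  are optimised jointly by backpropagation.
- **The search-based variant** — a black-box optimiser proposes sinc
  cutoff pairs, scores each candidate filterbank by cross-validated
  accuracy of a lightweight proxy classifier (rMDM or rSVM) on the pooled
  SCMs of the training set only, and the best filterbank's SCMs feed the
  same SPDNet stack.

## Geometry

For SPD matrices `S1, S2`:

- AIRM distance: `||logm(S1^{-1/2} S2 S1^{-1/2})||_F`, invariant under any
  congruence `S → A S A^T`.
- LEM distance: `||logm S1 − logm S2||_F`.
- Fréchet means: LEM has the closed form `expm(mean(logm Si))`; the AIRM
  (Karcher) mean is computed by manifold gradient descent — initial step
  1.0, halved whenever the residual grows, stopping when the mean tangent
  displacement falls below 1e−9 (Frobenius) or after 200 iterations, in
  which case an error carrying the last iterate is raised.
- Tangent projection: LEM is reference-free (`vect(logm S)`); AIRM whitens
  by a reference (`vect(logm(R^{-1/2} S R^{-1/2}))`), with the reference
  estimated from training data only so the test set never leaks into it.

The rMDM classifier assigns a test matrix to the class of the nearest
per-class Fréchet mean; exact ties break toward the lowest class index.
The rSVM is a linear-kernel SVM (C = 1.0 by default) on tangent vectors;
feature standardisation is off by default and exposed as a flag, since the
tangent coordinates already share a common scale.

## Differentiation and optimisation

No autodiff framework is used; every layer implements its exact adjoint:

- Spectral layers (ReEig, LogEig) use the Daleckii–Krein theorem: for
  `f(S) = U f(Λ) U^T`, the gradient is `U (K ∘ (U^T Ḡ U)) U^T` where `K`
  holds divided differences of `f` off the diagonal and `f'` on (and for
  eigenvalue pairs closer than 1e−12, where the divided difference is
  numerically unstable).  This handles coincident eigenvalues without the
  explicit jitter sometimes used for eigendecomposition backprop, because
  only spectral functions — not raw eigenvectors — are differentiated.
- BiMap: `∂L/∂S = W Ḡ W^T`, `∂L/∂W = 2 S W Ḡ` (with `Ḡ` symmetrised).
- Covariance pooling: linear in the outer products; centering is its own
  adjoint.  When interband covariance is removed, the off-diagonal blocks
  of the upstream gradient are zeroed before propagating.
- Sinc kernels `k = (2 f_h sinc(2 f_h t) − 2 f_l sinc(2 f_l t))·w_hamming/fs`
  differentiate in closed form (`∂k/∂f = 2 cos(2π f t)·w/fs`).  Cutoffs are
  parameterised as (low, bandwidth) through softplus with bandwidth ≥ 1 Hz
  and the upper cutoff clamped below 0.99·Nyquist, so no gradient step can
  produce an invalid `low ≥ high` pair; clamped coordinates receive zero
  gradient.

The whole backward pass is verified against central finite differences in
the test suite (relative tolerance 1e−4; observed agreement ~1e−7).

The optimiser is a Riemannian Adam: Euclidean parameters follow standard
Adam with L2 weight decay added to the gradient; Stiefel-housed BiMap
weights have their gradient projected onto the tangent space, Adam moments
kept in ambient coordinates, the step re-projected, and the new point
obtained by sign-fixed QR retraction, after which the first moment is
re-projected (an inexpensive stand-in for parallel transport).  Weight
decay is not applied to Stiefel weights — on the manifold there is no
meaningful origin to decay toward.  The retraction keeps
`||W^T W − I||_F` at machine precision (~1e−15) throughout training; the
test suite audits < 1e−6 after 50 steps.

Defaults: learning rate 1e−3, weight decay 1e−4, batch size 32,
epochs 100 (fixture-tuned; real datasets would warrant their own search).
`NBiRe = 3` is the default depth; each BiMap floor-halves the matrix
dimension, so configs whose widths reach zero are rejected.  The ReEig
threshold defaults to ε = 1e−4, the value customary in the SPDNet
literature, and is configurable.  Conv kernels initialise from a zero-mean
Gaussian scaled by `1/sqrt(kernel_len)`; Stiefel weights from the Q factor
of a seeded Gaussian; sinc low cutoffs spread evenly over the usable
spectrum with seeded jitter.  The default kernel length is fs/4 rounded to
odd (≈250 ms, resolving ≥4 Hz structure); convolution is valid-mode
(no padding), so pooling sees only fully filtered samples
(`Nt' = Nt − kernel_len + 1`).

## Filterbank semantics

`Nf` is the number of times each electrode signal is duplicated and
filtered.  Channel-independent (ChInd) filtering applies each of the `Nf`
filters to all electrodes; channel-specific (ChSpec) filtering learns one
filter per (filter, electrode) pair.  Both produce `Nf·Ne` rows in
band-major order (all electrodes of band 1, then band 2, …), so the
covariance dimension — and every downstream layer size — is identical in
the two modes.  For ChInd models the off-diagonal blocks of the pooled
covariance are interband covariances (between electrodes of different
bands); they can be kept or zeroed, and zeroing them equals concatenating
the per-band SCMs block-diagonally (the package computes the no-interband
path exactly that way, so the identity is exact rather than to rounding).

Vectorisation stacks the `n(n+1)/2` unique upper-triangular entries with a
√2 coefficient on off-diagonals so the vector 2-norm equals the matrix
Frobenius norm.

## Filterbank search

The search space is per-filter (low, bandwidth), bandwidth ≥ 1 Hz; the
objective filters the training trials with static sinc kernels, pools
covariances (block-diagonal concatenation across bands for ChInd), and
scores a stratified 5-fold CV with the chosen proxy classifier.  The
engine is a small sequential model-based sampler behind a propose/observe
interface: 10 uniform start-up trials, then candidates drawn from a
Gaussian KDE over the top 25% of observed configurations and ranked by the
good-to-rest density ratio (a TPE-style acquisition), with a 25% floor of
pure uniform exploration per iteration so the sampler cannot lock onto an
early local optimum.  Budgets are dual: a trial count and a walltime; a
started evaluation always completes and is logged.  ChSpec at high `Nf`
multiplies the dimensionality of the space and degrades any sequential
sampler toward random search; the package warns in that regime.

## Analyses

- **Frequency gain**: Welch averaged-periodogram amplitude spectra
  (half-overlapping segments, nperseg = min(256, Nt')) before and after
  the filterbank, averaged over trials (and electrodes, for ChInd);
  gain = 20·log10(post/pre) dB.  Bins at −∞ (post-filter amplitude zero)
  are linearly interpolated; spectra with more than 50% such bins are
  discarded and carry no values.
- **Peak counting / multiband detection**: moving-average smoothing
  (5 bins), median-zeroing, then peak detection with height ≥ 25% of the
  smoothed maximum, width ≥ 2 Hz, and prominence ≥ 6 dB.  The prominence
  floor is what separates sub-dB passband ripple of one wide band from
  genuinely disjoint pass regions; all three thresholds are heuristic and
  exposed as arguments.
- **Layer-by-layer probing**: at the pooled covariance and after every
  BiMap and ReEig, a Euclidean probe (linear SVM on vectorised maps) and a
  Riemannian probe (LEM rSVM) are fitted on training-set feature maps and
  scored on test-set maps, reporting probe-minus-network accuracy.
  Non-PD maps are eigenvalue-floored first.
- **ReEig audit**: percentage of feature-map eigenvalues below ε per
  stage; after any ReEig stage this is exactly 0 by construction, which
  the test suite asserts as an equality.
- **BiMap gain**: summing the bilinear coefficients of `W^T C W` over all
  output entries collapses to the rank-1 form `G = s s^T` with `s` the row
  sums of `W`; per-electrode values fold the band-major rows back onto
  electrodes.  The tests verify the closed form against the explicit
  double sum at 1e−12.
- **Electrode-frequency relevance**: per class, the gradient of the class
  score with respect to the pooled covariance (through the SPD stack
  only), summed across matrix rows to per-(band, electrode) scalars,
  averaged over trials, and multiplied by that filter's 0–1 min-max
  normalised gain spectrum (per-filter normalisation; a global
  normalisation would let one dominant filter suppress the rest).
  Raw gradients are used, not gradient×input.

## Synthetic data

The generator emulates what covariance pooling can exploit and nothing
more: spatially correlated broadband noise (1/f with exponent 1.0 plus a
white floor 20 dB below the 1 Hz level, mixed by a uniform-ρ correlation
matrix, ρ = 0.2) plus class-dependent narrowband oscillations at chosen
electrodes.  Oscillations are random-phase narrowband-filtered noise, not
sinusoids, so the class signal lives in band power (covariance), not
phase.  `snr` scales oscillation RMS relative to the noise RMS inside the
same band at the same electrode.

Canonical fixtures: `easy4` (four classes, disjoint alpha / beta /
low-gamma / high-gamma bands at distinct electrode pairs, snr 4),
`hard4` (overlapping bands, shared electrodes, snr 0.75), `singleband`
(all class information as graded power in one 20–30 Hz band at two
electrodes — for band-recovery scoring), and `multiband` (a 2×2 power
design over 10–14 Hz and 60–70 Hz, so that a single filter must pass both
disjoint bands to separate all four classes).  Default cohort scale is 8
electrodes, 2 s trials at 250 Hz, 40 trials per class; the end-to-end
benchmark uses a 24-electrode variant of `easy4` (the planted structure
still occupies electrodes 0–7; the rest carry only noise).  The wider
cohort matters because each BiMap halves the matrix dimension: from 8
electrodes, three halvings bottom out in a 1×1 final matrix, and from 16
in a 2×2 (three vectorised features for four classes) — degeneracies of
desk-scale widths, not of the method.  At 24 electrodes the final stage
is 3×3 (six features), which four-class training fits reliably.

What passing these benchmarks shows: the gradients are correct, the
geometry is right, optimisation converges, planted spectral structure is
recovered, and the conv-vs-sinc multiband distinction emerges for the
designed reason.  What they do not show: performance on real EEG, with its
nonstationarity, artifacts, volume conduction, and inter-subject
variability — none of which the generator models.

## Evaluation protocol and statistics

Models are trained and tested per participant with several random seeds
(default 3); accuracies (percent, unseen test split, stratified shuffle
split) are averaged across participants and seeds.  Paired model
comparisons use the exact two-sided Wilcoxon signed-rank test (no normal
approximation): at the small n of paired condition means, all-same-sign
differences give the characteristic discrete values p = 2·2^−n —
0.0078125 at n = 8 and 0.015625 at n = 7.  Zero differences are dropped
before ranking; an all-tied comparison returns p = 1 with a warning.

## Known limitations

- CPU-only, dense linear algebra; trial counts and matrix sizes beyond a
  few hundred electrodes×filters will be slow.
- The BiMap reduction factor is fixed at one half per pair.
- No Riemannian batch normalisation, no spatial convolutions, no cropped
  (sliding-window) decoding.
- The search engine models dimensions independently; strongly coupled
  cutoff interactions are only found through its exploration floor.
- Weight decay on Stiefel parameters is deliberately omitted (see above);
  optimisers that define an ambient decay will not be matched exactly.
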