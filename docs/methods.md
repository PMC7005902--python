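# Methods

`emrestore` is a headless restoration engine for slice-and-view volume
electron microscopy (SBF-SEM, FIB-SEM and serial-section TEM stacks). This
note documents the model it assumes, the algorithms and their parameters,
the synthetic phantoms the test suite runs on, and the numerical choices
made where the design was open.

## Forward model

An acquired stack `y` is modeled per slice as

    y = H x + n

with `x` the degradation-free image on the [0, 1] intensity scale, `H` an
isotropic 2-D Gaussian point-spread function of standard deviation
`sigma_psf` pixels, and `n` i.i.d. mean-zero Gaussian noise of standard
deviation `sigma_noise` (constant variance per pixel). The PSF family is not
observable from the interface we emulate, which exposes only a scalar
blur width for its deconvolution modes; an isotropic Gaussian is the
conventional reading of that single parameter. The PSF kernel is truncated
at `ceil(4*sigma)` pixels per side and renormalized to unit sum, so blur
preserves the image mean. All spatial filtering uses mirror (symmetric)
boundary padding, which avoids the dark-frame artifacts of zero padding on
block-face images. Degraded images are deliberately not clipped to [0, 1];
clipping is an explicit export step (`clip_unit`, PNG export).

Shorter dwell times during acquisition raise `sigma_noise`; the package's
purpose is to undo that so dwell time can be shortened without hurting the
downstream visualization, segmentation, or counting.

Volumes are processed strictly slice-by-slice: every restoration algorithm
is 2-D and is applied independently per z-plane. The 3-D term of the total
variation functional is therefore dropped, and the wavelet transform is 2-D
per slice.

## Noise and blur estimation

Two median-absolute-deviation estimators are provided:

* `mad_raw`: `sigma_hat = med(|y - med(y)|)` on raw intensities. This is the
  historically used estimator, kept verbatim. It is biased in two ways: on
  pure Gaussian noise it returns `0.6745*sigma` (the median of a
  half-normal), and any signal texture inflates it.
* `mad_wavelet`: `med(|d|)/0.6745` over the finest diagonal (HH) Haar
  coefficients, computed per slice. Smooth signal content is nearly absent
  from HH, and the 0.6745 constant makes the estimator consistent for
  Gaussian noise; parameter calibration uses this variant. On the textured
  phantoms it recovers injected sigma in {0.02, 0.05, 0.1, 0.2} within 5%.

The blur metric compares absolute first-order differences of the image with
those of a moving-average-smoothed copy (default length 9), separately along
x and y: `v = max(0, |D y| - |D y'|)`, `b_dir = (sum|D y| - sum v)/sum|D y|`,
and `b = max(b_x, b_y)` in [0, 1] (0 = sharp). The printed form of the
difference-of-variations is ambiguous about signs; absolute variations are
used, as in the blur-metric literature this construction comes from, because
signed sums can make the metric negative. A direction with zero total
variation contributes no blur evidence; a fully constant image is rejected.

## Restoration algorithms

All eight denoisers take and return one 2-D float slice. Fixed window sizes
follow the interactive plugin conventions.

* **Gaussian filter** — convolution with a normalized 7x7 Gaussian kernel of
  std `sigma_g` (window fixed).
* **Wavelet soft-thresholding** — undecimated (stationary) 2-D wavelet
  transform (`sym4`, default 6 scales), soft-threshold
  `sign(z)max(|z|-T, 0)` on every detail band, approximation kept, inverse
  transform. The undecimated transform was chosen for its shift invariance —
  the same property that motivates dual-tree complex transforms — and
  reconstructs to ~1e-12 at T = 0. `soft_threshold` shrinks complex
  coefficients in magnitude, preserving phase, so it is reusable for complex
  transforms. Because the transform is energy-normalized and redundant, the
  per-band noise level is below the image-domain sigma, so useful thresholds
  are smaller than naive universal-threshold intuition suggests
  (calibration handles this).
* **Anisotropic diffusion** — explicit 4-neighbor Perona-Malik iterations
  `x <- x + eta * div(c(|grad x|) grad x)` with conductance evaluated per
  arm on forward differences. `c(s) = exp(-(s/kappa)^2)` (default) or
  `1/(1+(s/kappa)^2)`. The stability bound `eta <= 0.25` is enforced; within
  it the scheme is a convex average, so a discrete extremum principle holds.
  As `kappa -> inf` one iteration tends to the linear heat step.
* **Bilateral filter** — weighted mean over a fixed 15x15 window with a
  spatial Gaussian (`sigma_sp`, px) and an intensity Gaussian (`sigma_int`,
  [0,1] scale). The textbook sum is not self-normalizing, so weights are
  normalized to unit sum per pixel — a deliberate correction without which
  constant images would not be preserved.
* **Tikhonov denoising/deconvolution** — `min_x ||y-Hx||^2 + lam||Lx||^2`
  with `L` the 5-point Laplacian, solved by conjugate gradients on the
  normal equations under periodic boundary. Periodicity makes the exact FFT
  solution available as an independent oracle; an optional mirror-pad/crop
  wrapper (`pad=` argument) suppresses wrap-around on real data. CG residual
  2-norms legitimately spike on ill-conditioned spectra, so divergence is
  reported only on sustained growth (5 consecutive increases beyond 10x the
  initial residual).
* **Total variation denoising** — `min_x ||y-x||^2 + lam * sum sqrt(Dx^2 +
  Dy^2 + eps^2)` with forward differences, Neumann boundary and
  `eps = 1e-3` smoothing (default 100 iterations). The solver is first-order
  descent with Barzilai-Borwein step initialization and monotone
  backtracking; plain fixed-step descent is impractically slow in the
  large-`lam` regime where the curvature scales like `lam/eps`, while BB
  steps reach the flat (constant-mean) limit within a few thousand
  iterations. The smoothed objective is directly evaluable, which the
  monotonicity tests use. Minimizing from `x = y` preserves the mean exactly.
* **BLS-GSM** — Bayesian least squares under a Gaussian scale mixture prior.
  The image is decomposed on an undecimated frequency-domain steerable
  pyramid (default J = 3 scales, K = 8 orientations, raised-cosine radial
  transitions of one octave, angular windows `|cos|^(K-1)`); the squared
  band masks sum to one, so the frame is tight and synthesis is exact. Per
  subband, each 3x3 coefficient neighborhood `w` is modeled as
  `sqrt(z) u + n` with `u ~ N(0, C_u)`; the center coefficient estimate is
  the posterior average over z of Wiener estimates
  `z C_u (z C_u + C_n)^-1 w`. `C_n` is obtained deterministically by
  propagating white noise of the given sigma through each band filter
  (inverse FFT of the squared mask gives the autocorrelation); `C_u` is the
  subband sample covariance minus `C_n` with negative eigenvalues clipped to
  zero. The z prior is Jeffreys-noninformative on log z, discretized on 13
  log-spaced points spanning [exp(-20.5), exp(3.5)] and rescaled to unit
  prior mean. The neighborhood is purely spatial (no parent coefficient).
  Oriented bands and the highpass residual are estimated; the lowpass
  residual passes through. The method involves no randomness and is
  bit-reproducible. Images are mirror-padded by `2^(J+1)` before the
  periodic pyramid.
* **Nonlocal means** — `x_i = sum_j w_ij y_j / sum_j w_ij` with
  `w_ij = exp(-0.5 ||y_Ni - y_Nj||^2 / h)` over the (2W+1)^2 search window,
  patches of half-size B, mirror padding. The damping `h` divides the raw
  squared patch distance (not h^2, no per-pixel normalization), kept
  verbatim; consequently h values transfer between images only at the same
  B, and at large B the noise floor `2 sigma^2 (2B+1)^2` of the patch
  distance caps how much averaging a small h can do. A `normalize_patch`
  flag (default off) divides the distance by the patch pixel count.
* **Nonlocal means deconvolution** — weights are computed once on an NLM
  pilot (same h, B, W) and held fixed; the objective
  `||y - Hx||^2 + lam * sum_ij w_ij (x_i - x_j)^2` is minimized by the same
  BB-initialized monotone descent (default 20 iterations). The pairwise sum
  is restricted to the search window — outside it the weights are
  numerically zero — and out-of-image neighbors are mirrored, which makes
  the prior an explicit graph Laplacian that a dense linear solve can check
  on small inputs. H is applied via periodic FFT so its adjoint is exact and
  every accepted step decreases the objective.

## Automatic parameter initialization

For an algorithm `f_theta`, calibration degrades K clean benchmark images
with noise `sigma_m`, grid-searches theta minimizing the summed squared
restoration error (ties resolve toward the smoothing-weakest grid point),
fits per-parameter polynomials `theta_j(sigma)` of degree q in {1, 2} by
least squares, and at run time evaluates them at the estimated noise level,
clipping to the searched bounds. Degree selection prefers q = 1 unless q = 2
reduces the fit residual by more than 20%. Multi-parameter algorithms are
searched on a full Cartesian grid so an exhaustive oracle is exact; grid
search (rather than continuous optimization) was chosen for
reproducibility.

The benchmark bank is a reproducible mix of the three phantom families
(default K = 10 at 128 px; the desk-scale tests use K = 3). Default search
grids bracket the parameter values reported for real acquisitions (e.g.
damping h in 0.05-1.2 around the published 0.05-0.7 range, diffusion kappa
around 0.18, Tikhonov lambda around 1.5) with roughly geometric spacing,
5-6 points per parameter; non-searched parameters are pinned to the fixed
plugin settings (bilateral window 15x15, NLM B = 4/W = 5, diffusion
eta = 0.07 with 5 iterations, BLS-GSM J = 3, 3x3 neighborhood).

## Phantoms

No external data is required; the generators produce EM-like structures
with exact ground truth:

* `membranes` — Voronoi cell partition from seeded random sites; boundaries
  dilated to a configurable width (default 5 px, matching the membrane
  width used for ground-truth dilation in the neuron-segmentation
  experiments we emulate); dark membranes (0.3) on a bright background
  (0.75) carrying smoothed-noise texture of amplitude 0.05 — a flat
  background would flatter every denoiser.
* `sarcomere` — alternating dark A-bands and bright I-bands (default period
  24 px, contrast 0.3, duty cycle 0.5) with slightly smoothed transitions;
  the label mask (A = 1, I = 2) comes from the unsmoothed square wave.
* `filaments` — bright disks on a dark background, rejection-sampled
  (10,000-attempt cap) so centers are more than `2r + 2` px apart; the true
  count is exact by construction.

Phantoms are noise-free; degradation happens only through the forward
model, so every experiment has an exact reference. What the phantoms do not
emulate: detector MTF, charging and curtaining artifacts, spatially varying
noise, anisotropic PSFs, and the rich texture of real tissue. Passing tests
therefore demonstrate algorithmic correctness and the direction of the
denoise-then-segment effect, not absolute performance on real acquisitions.

## Evaluation

PSNR is `10 log10(1/MSE)` for [0, 1] references, capped at a 300 dB
sentinel for identical inputs. Dice is `2|P&S|/(|P|+|S|)` with two empty
masks defined as 1. Threshold segmentation is inclusive at both ends,
matching the closed intensity ranges the interactive workflow reports.
Component counting uses 8-connectivity (the 2-D particle-analysis
convention) after removing components below `min_size`; `split_touching`
first applies a watershed on the negated Euclidean distance transform,
seeded from its h-maxima with depth 1 px — plain 3x3 local maxima produce
spurious seeds on ridge plateaus of thin bridges, which the h-maxima
criterion suppresses. The Fourier high-pass detail map zeroes all
coefficients below `cutoff_frac * Nyquist` (radially) and inverts; it is the
sharpness-comparison tool for short-dwell + denoise versus coarser pixels.

## Workflow contracts

`preview_roi` restores a margin-expanded rectangle and returns the central
crop; when the margin is at least the algorithm's influence radius (3 px
for the 7x7 Gaussian, 7 px for the 15x15 bilateral, B+W for NLM, one pixel
per iteration for diffusion, unbounded for the global solvers) the preview
equals the same crop of a full-slice run, and a warning is issued otherwise.
`apply_to_stack` never mutates its input, processes an inclusive 0-based
slice range, and returns a `RunRecord` (algorithm spec, noise/blur
estimates, slice range, timestamp, input SHA-256) that is embedded as JSON
in the TIFF ImageDescription tag; `rerun_from_record` verifies the checksum
and reproduces the output bit-identically. Restored data is written as
float32 pages; integer/PNG export is an explicit lossy step.

The throughput calculator is plain arithmetic,
`(n_images * pixels * dwell + n_slicings * slice_time)/3600`, taking the
image and slicing counts directly as inputs (the published worked example
uses 500 images and 499 slicings, which it reproduces: 58 h at 4 us dwell,
16 h at 1 us, a 3.5x speedup).

## Problem sizes used by the tests and acceptance script

Oracle-equivalence checks run at 8-32 px where double-loop references are
exact and fast; estimator checks at 256-512 px; efficacy and calibration at
K = 3 benchmark images of 128 px evaluated on a held-out 256 px phantom;
the segmentation trend at 192 px with 5 seeds per noise level. These sizes
were chosen so the full suite runs in well under a minute on one core while
every statistical check retains comfortable margin.

## Known limitations

* Single Gaussian PSF model; no spatially varying or measured PSFs.
* Additive constant-variance Gaussian noise only (no Poisson component).
* TV deconvolution (H != I) is not offered, mirroring the emulated tool.
* BLS-GSM does not aim for numerical parity with any specific published
  implementation (no parent coefficients, undecimated pyramid).
* The raw-distance NLM weighting makes published h values meaningful only
  at the same patch size; see the damping discussion above.
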