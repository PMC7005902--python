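# emrestore

Headless restoration engine for volume electron microscopy (SBF-SEM,
FIB-SEM, serial-section TEM). Slice-and-view 3D EM trades acquisition speed
against noise: shorter pixel dwell times cut imaging sessions from days to
hours but bury ultrastructure in noise. `emrestore` provides the
computational side of a denoising workflow for such stacks — noise and blur
estimation, automatic parameter initialization, eight restoration
algorithms, ROI preview, slice-by-slice batch processing with reproducible
run metadata — as a Python library and a small CLI, with no GUI and no GPU
requirement.

## Model and methods

An acquired slice is modeled as **y = Hx + n**, with `H` an isotropic 2-D
Gaussian PSF and `n` mean-zero Gaussian noise of constant variance σ² on
the [0, 1] intensity scale. On top of this forward model the package
implements:

* noise estimation by median absolute deviation — the raw form
  σ̂ = med(|y − med(y)|) and a Gaussian-consistent wavelet-domain variant
  med(|HH|)/0.6745 — and a directional blur metric in [0, 1];
* restoration: Gaussian filtering, soft-threshold wavelet shrinkage
  sign(z)·max(|z|−T, 0), Perona–Malik anisotropic diffusion (exponential and
  rational conductances), bilateral filtering, Tikhonov
  denoising/deconvolution min ‖y−Hx‖² + λ‖Lx‖², smoothed total-variation
  denoising, BLS-GSM (Bayesian least squares under a Gaussian scale-mixture
  prior on steerable-pyramid neighborhoods), and nonlocal means
  denoising/deconvolution with weights w_ij = exp(−½‖y_Ni − y_Nj‖²/h);
* automatic parameter initialization: per-noise-level optimal parameters
  θ_m = argmin Σ_k ‖f_θ(y_k,m) − x_k‖² by grid search over a phantom
  benchmark bank, a linear/quadratic polynomial fit θ(σ), and prediction at
  the estimated noise level;
* evaluation: PSNR, Dice 2|P∩S|/(|P|+|S|), inclusive intensity-threshold
  segmentation, connected-component counting with optional watershed
  splitting, Fourier high-pass detail maps, and acquisition-throughput
  arithmetic.

Ground-truth test data comes from built-in EM-like phantoms (membrane
networks, sarcomere A/I bands, filament cross-sections); no downloads are
needed. See `docs/methods.md` for assumptions, parameter defaults, and
numerical choices.

## Worked example

Generate a membrane phantom, degrade it with σ = 0.1 noise, estimate the
noise level, denoise with nonlocal means, and measure what the restoration
did:

```bash
emrestore phantom --kind membranes --output clean.tif --size 128 --seed 1
emrestore phantom --kind membranes --output noisy.tif --size 128 --seed 1 --sigma-noise 0.1
emrestore estimate --input noisy.tif
emrestore denoise --input noisy.tif --output den.tif --algorithm nlm --h 0.4 --B 4 --W 5
emrestore evaluate --input den.tif --truth clean.tif --threshold 0.0,0.55
```

prints

```json
{
  "sigma_mad_raw": 0.10251867771148682,
  "sigma_mad_wavelet": 0.10680489026678329,
  "blur": 0.17122370044603832
}
{
  "psnr_db": 26.15052120573418,
  "dice": 0.9974286448958601,
  "count": 3
}
```

The wavelet-domain MAD estimate (0.107) recovers the injected σ = 0.1; the
raw variant is reported alongside for reference. After denoising, the
restored image sits at 26.2 dB PSNR against the clean phantom (the noisy
input is at ~20 dB), and a plain intensity threshold of the denoised image
overlaps the true membrane mask with Dice 0.997. The denoised TIFF carries
a JSON run record (algorithm, parameters, noise estimate, input checksum)
in its ImageDescription tag, so the exact run can be reproduced later.

The throughput calculator reproduces the acquisition arithmetic for a
500-image stack of 10⁸-pixel images with 18 s slicing events:

```bash
emrestore plan --n-images 500 --pixels-per-image 1e8 --dwell-us 4 --n-slicings 499
# {"hours": 58.05...}   (4 us dwell; 1 us dwell gives 16.4 h, a 3.5x speedup)
```

Calibration tables are built and queried the same way
(`emrestore calibrate build|predict`), and everything the CLI does is also
available as library calls (`emrestore.apply_to_stack`,
`emrestore.build_table`, ...).

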