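# Methods

## Problem and model

Clinical brain MRI of people with multiple sclerosis is often acquired as
multi-slice 2D stacks: in-plane resolution around 1 mm but slice spacing
of several millimetres, which prevents reliable 3D lesion quantification.
`slicesr` implements single-image super-resolution that raises the
through-plane resolution of such volumes from 6 mm slice spacing to a
1 mm isotropic grid.

The forward (acquisition) model for a low-resolution multi-slice image is

    y_i = M_i(x) = D B R_i(x)

where `R_i` selects the slice direction, `B` blurs along that direction
with the slice-selection profile, and `D` decimates by the slice spacing.
Defaults are slice thickness 5 mm and spacing 6 mm, i.e. an explicit 1 mm
gap of unexcited tissue between slabs.  Because volumes are held in a
fixed canonical axis order, `R_i` is an axis permutation, never an
interpolating rotation.

Training pairs are 3-channel 2D patches: the channels are three
contiguous planes along the in-plane dimension orthogonal to the patch
plane, so a 2D network sees local 3D context exactly as an RGB image.
HR patches are 96x96 in a plane containing the slice axis; their LR
counterparts (96x16 or 16x96) are exact sub-grids of the simulated LR
volume, which makes the LR-HR correspondence lossless and testable at
zero tolerance.

Fine-tuning minimizes the content loss

    L_c = L_perceptual + eta * L_1          (eta = 1)

with Adam and cosine annealing with warm restarts (stepped per epoch),
and selects the weight snapshot with minimum validation L_c.  The GAN
variant adds `lambda * L_GAN` (lambda = 0.05) with per-pixel sigmoid BCE
from a spectrally normalized U-Net discriminator, one discriminator step
per generator step; the adversarial term is excluded from the selection
criterion.

Whole volumes are reconstructed by sliding a 3-plane window along each of
the two in-plane axes, pre-interpolating each window to the HR grid,
running the network, accumulating output channels at their plane
positions with center-heavy weights (0.25, 0.5, 0.25, renormalized at
boundaries), and averaging the two per-axis volumes.

## Numerical and design choices

* **Slice-selection profile.** The literature this follows states
  thickness/spacing/gap but not the filter shape; the default is a boxcar
  of width = thickness (idealized slab excitation, making the 1 mm gap
  explicit), with a Gaussian of FWHM = thickness as an option.  Taps are
  normalized to sum 1, so constants are preserved.
* **Phase convention.** The first slab footprint starts at HR index 0, so
  the first slice center sits at 2.0 mm on the HR grid ((thickness-1)/2).
  The same offset is used by the cubic interpolator, which keeps patch
  extraction, pre-upsampling and reconstruction mutually consistent.
* **Boundary.** The HR extent is truncated to the largest multiple of the
  decimation step; no out-of-volume signal is invented.
* **Anisotropic x6 factor.** Published SR architectures upsample
  isotropically by 2/3/4 with pixel shuffle; the through-plane factor
  here is 6 in one axis.  The pipeline therefore pre-interpolates the LR
  input to the HR grid (Keys cubic kernel, a = -0.5, clamp-to-edge) and
  runs the networks in a scale-1 mode with the upsampling head removed.
  In this mode the network predicts a residual added to its interpolated
  input, with the final convolution zero-initialized: an untrained model
  is exactly the interpolation identity, so any measured improvement over
  bicubic is a training effect.  Pixel-shuffle modes are retained for
  parameter-count checks and isotropic experimentation.
* **Intensity normalization.** Networks consume [0,1] inputs.  Volumes
  are divided by the 99.5th percentile of intensities inside the brain
  mask and clipped; this is robust to hyperintense lesion tails while
  keeping lesions mostly below 1.  The scale is returned so SR outputs
  can be mapped back.
* **Perceptual features.** The canonical recipe uses five pre-activation
  VGG-19 stages with weights (0.1, 0.1, 1.0, 1.0, 1.0); the provider is
  an injectable callable.  The package ships two self-contained frozen
  providers: an identity provider (reduces L_perceptual to a weighted
  L_1; used in tests) and a multi-scale gradient pyramid (smoothing +
  orthogonal derivative filters at five dyadic scales) used as the
  default.  Any VGG-backed provider can be injected where its weights are
  available.
* **"Most of the patch area is brain"** is quantified as >= 50% brain
  coverage in the central channel plane — the weakest reading of "most" —
  with rejection sampling bounded at 100 attempts per patch.
* **Scheduler.** lr = floor + (lr0 - floor)(1 + cos(pi T_cur/T_i))/2 with
  cycle lengths T0, T0*T_mult, ...; floor 1e-7.  Defaults: EDSR
  lr0 = 2e-4, T0 = 8, T_mult = 2; generator 1e-4/6/1; discriminator
  5e-6/8/2; batch size 6; 100 epochs.  Stepping is per epoch, consistent
  with T0 values of order 6-8 against 100 epochs.
* **Failure handling.** Non-finite training losses abort with epoch/batch
  diagnostics rather than being clipped; weight snapshots are deep copies
  (no aliasing with live weights).
* **Masked metrics.** PSNR and SSIM are computed inside the brain mask on
  [0,1]-normalized volumes with data range 1, so uniform background air
  cannot inflate them.  SSIM uses a Gaussian window (sigma 1.5, truncated
  at 4 sigma, nearest-edge padding) with K1 = 0.01, K2 = 0.03.  The five
  perceptual patch metrics (VIF, FSIM, VSI, HaarPSI, DISTS) are delegated
  to an external provider behind an adapter and reported as unavailable —
  never silently zero — when no backend is importable.

## Compute backend

The networks, losses and optimizer run on a compact reverse-mode autodiff
core over NumPy (`slicesr.nn`): strided/padded 2D convolution, pixel
shuffle, nearest upsampling, average pooling, Leaky/ReLU, concatenation,
stable sigmoid BCE, spectral weight normalization (one power iteration
per step, exact gradient with the iteration vectors detached), and Adam.
Convolutions are einsum contractions over sliding-window views, which
keeps both passes memory-bandwidth friendly at desk scale.  Gradients of
every operation are verified against central finite differences in the
test suite, and the convolution forward against an independent
`scipy.signal` oracle.  Checkpoints are plain name->array `.npz`
dictionaries with shape-matched partial loading (mismatches enumerated in
a report), mirroring the partial-loading semantics used when transferring
trunk weights between scale modes.

## Synthetic phantoms: what they do and do not show

The phantom generator produces, on a 1 mm isotropic grid, nested
smooth-boundary tissue regions (CSF shell, grey matter, white matter,
central CSF cavity) as deformed ellipsoids, ellipsoidal hyperintense
(FLAIR-like) or hypointense (T1-like) lesions placed fully inside white
matter, a smooth multiplicative bias field (amplitude 0.1), and additive
Gaussian noise (sigma 0.01 of the intensity scale; magnitude-MRI Rician
is available).  Default tissue means are CSF 0.15 / GM 0.55 / WM 0.40 /
lesion 0.85 in FLAIR-like mode and CSF 0.15 / GM 0.45 / WM 0.70 /
lesion 0.35 in T1-like mode, chosen as typical relative contrasts for
those sequences; the default grid is 96^3 so one phantom yields exact
96x96 patches.  Generation is fully deterministic given the seed.

Phantoms have curved tissue boundaries, lesions, bias and noise — the
features the SR must restore — but no cortical folding, no skull, and no
acquisition artifacts beyond the slice-profile degradation.  Passing
tests on phantoms therefore demonstrate that the pipeline's geometry,
losses, optimization and reconstruction behave as specified, not that a
desk-scale model reaches clinical-grade SR quality; that requires
full-size networks and real multi-center MRI.

## Desk-scale problem sizes

The end-to-end experiment (`slicesr.experiments.tiny_training_experiment`,
also driven by `scripts/acceptance.py`) uses four training phantoms and
one validation phantom (96^3), 204 training / 18 validation patch pairs
over all three slice orientations, a 2-block / 8-feature EDSR in scale-1
mode (3,363 parameters), 15 epochs at batch size 6, and two held-out
phantoms for the comparison against cubic through-plane interpolation.
These sizes were chosen so the whole experiment runs in a few minutes on
one CPU while still exhibiting a genuine training effect: validation L_c
drops below its value at initialization and the reconstruction's
brain-masked PSNR exceeds bicubic interpolation on both held-out
phantoms (by a few hundredths of a dB at this model size).

## Known limitations

* Desk-scale training margins are small; the tiny network mainly learns
  mild edge sharpening on piecewise-constant phantoms.
* Only integer decimation steps on a 1 mm HR grid are supported; oblique
  slice directions would require resampling, which is out of scope.
* The published torch-format EDSR/RealESRGAN checkpoints are not parsed;
  weights must be provided as `.npz` dictionaries matching the parameter
  names of these implementations.
* The perceptual-metric adapter requires an external backend for
  VIF/FSIM/VSI/HaarPSI/DISTS; without one these metrics are reported as
  unavailable.
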