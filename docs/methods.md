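# Methods

`pactdiff` restores subsampled volumetric photoacoustic computed tomography
(PACT) reconstructions to full-array quality with a two-step generalized
("cold") diffusion model, and provides the synthetic acquisition pipeline
needed to train and evaluate it without access to animal or clinical data.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic experiments do and do not establish.

## The restoration problem

A hemispherical transducer array with N elements records one ultrasound
time series per element after a laser pulse; delay-and-sum (DAS)
back-projection turns those channels into a volume. Two economical
acquisition modes degrade the image in characteristic ways:

- **sparse** — keep every 4th element (`4i+1`, quasi-uniform over the
  aperture). Full angular coverage but undersampled: radial streak
  artifacts.
- **cluster** — keep a contiguous block of elements (indices `1..k`), a
  small cap of the dome. Well-sampled but a narrow aperture: lateral blur.

Restoration maps a degraded reconstruction `x_T` back to the full-array
image `x_0`, slice by slice with 3-slice context.

## Deterministic diffusion with a Gabor degradation

The forward process interpolates between clean and degraded slices through
a linear frequency-selective operator built from a Gabor filter

    G(i, j) = exp(-(i'^2 + gamma^2 j'^2) / (2 sigma^2)) * cos(2 pi i'/lambda + psi),

with rotated coordinates `i' = i cos(theta) + j sin(theta)`,
`j' = -i sin(theta) + j cos(theta)`. Defaults: theta = pi/4, lambda = 3.3,
sigma = 10, psi = 0, gamma = 1. The schedule is linear,
`alpha_t = 0.999 (T - t)/(T - 1)` for `t = 1..T`, and

    x_t = D(x0, xT, t) = alpha_t G x0 + (1 - alpha_t G) xT .

At `t = T` the process returns `x_T` exactly; there is no stochastic noise
anywhere, so the whole chain — forward, sampling, restoration — is a pure
function of its inputs.

**How G is applied.** The product `G x` is not uniquely determined by the
formula; this package defaults to a pointwise multiplication of the
(fftshifted) 2D spectrum by G evaluated on centered frequency-bin
coordinates, with a pixelwise spatial mask retained as a config
alternative (`operator.domain_mode`). The frequency reading is preferred
because the degradation is described as removing frequency components and
because the sampling identities below require pointwise division in a
domain that diagonalizes G. In frequency mode the mask is additionally
symmetrized under frequency negation, `(G(k) + G(-k))/2`. Without this the
carrier term breaks Hermitian symmetry on the Nyquist rows, the real-part
projection after the inverse FFT is no longer exactly a pointwise mask,
and the inversion identity degrades from machine precision to ~1e-2. The
symmetrized mask is a zero-phase band filter; `|G| <= 1` is preserved.

**Sampling identities.** Given a stage-one estimate `x̂0`, the endpoint
estimate inverts the forward process pointwise,

    x̂_T = (x_t - alpha_t G x̂0) / (1 - alpha_t G),

guarded by clamping the divisor to +/- eps (eps = 1e-3, sign-preserving)
where `|1 - alpha_t g|` is small — the divisor is singular where
`alpha_t g -> 1`, which the schedule touches at `alpha_1 = 0.999` at the
mask's passband peak. The corrected reverse step

    x̂_{t-1} = x_t - D(x̂0, x̂_T, t) + D(x̂0, x̂_T, t-1)

cancels the restorer's own error instead of accumulating it: with a
perfect `x̂0` the chain reproduces the true `x_{t-1}` exactly (verified to
1e-9 in tests). `alpha_0` is deliberately undefined; the sampler never
evaluates D at step 0 — the final output comes from the stage-two network.

## Network

`RestorationNetwork` is a U-shaped encoder-decoder over 3-channel slice
stacks (previous, current, next slice). Encoder stages and the bottleneck
each carry an **EHM block**:

1. **ECA** — per-channel gates from a zero-padded 1D convolution (kernel
   k = 3) across the channel axis of the globally pooled descriptor, passed
   through a sigmoid.
2. **Reduced-KV self-attention** — pointwise Q/K/V projections; keys and
   values average-pooled by r per axis (default r = 2), exploiting the
   low-rank structure of the attention map; scores scaled by `s = C^(1/3)`
   (`sqrt_C` selectable — the printed form of the scale is ambiguous, so
   both conventions are exposed).
3. **Selective SSM refiner** — a Mamba-style diagonal state-space layer
   scans the raster-flattened pooled key and value sequences (state size
   N = 8, input-dependent Delta/B/C, learned negative-real diagonal A,
   learned skip). Discretization is exact zero-order hold per diagonal
   entry: `Abar = exp(Delta A)`, `Bbar = (exp(Delta A) - 1)/A * B`.
4. Residual output projection, zero-initialized so the block starts as the
   identity.

The decoder uses plain convolution blocks with skip connections. A
sinusoidal time embedding passed through a 2-layer MLP conditions every
convolution block via a learned per-channel bias. The network head is
zero-initialized and a global residual adds the degraded center slice, so
the untrained network is the identity map — this stabilizes early training
and makes single-pair overfitting fast. The scan order of the SSM is
row-major and unidirectional.

**Error-modulated conditioning.** At the second sampling stage the input
`x̂_{t-1}` is generated from `x̂0` rather than drawn from the forward
process, so the fixed time embedding is misaligned with it. A shallow
network (two pointwise convolutions on the concatenated `(x̂0, x_T)`,
global pooling, zero-initialized head) emits `(beta, gamma)` and the
embedding becomes `f~ = (1 + gamma) f + beta` — an identity at
initialization.

The gradient-bearing operations (im2col convolution, softmax attention,
the fused selective scan with an analytic reverse recurrence, pooling,
group normalization) run on a small reverse-mode autodiff engine written
for this package (`pactdiff.nn`); every op's gradient is validated against
central finite differences in the test suite.

## Training

Two stages per iteration, `t` drawn uniformly from `{2..T}` (with the
deployed `T = 2`, every step exercises both stages):

- stage one: `x̂0 = R(x_t^c, t)`, loss `||x̂0 - x0||`;
- consistency: `x̂_{t-1} = D(x̂0, x_T, t-1)`, loss `||x̂_{t-1} - x_{t-1}||`;
- stage two: restore `x̂_{t-1}` (detached) with the modulated embedding,
  loss against `x0`.

The total is the plain sum of the three. The norm is mean-squared error by
default with L1 selectable; the re-degraded image entering stage two is
detached from the stage-one gradient path (the consistency term still
trains stage one through the degradation operator, which is self-adjoint,
so its adjoint is itself). Optimizer: Adam, lr 2e-4, betas (0.9, 0.99),
batch 4, random 128x128 crops (full slices when smaller), edge-replicated
neighbors at volume boundaries. Full-scale defaults are 125 000 iterations
and 9 792 transfer iterations; transfer fine-tuning copies all weights from
a sparse-pretrained checkpoint and changes nothing but the iteration
budget.

## Synthetic acquisition model

The simulator emulates the acquisition regime of a 1024-element
hemispherical array (2.02 MHz center frequency, 54% fractional bandwidth)
over a 12.8 mm cubic field of view, with configurable radius (default
60 mm), speed of sound (1.5 mm/us) and sampling rate (40 MHz) — values
not pinned down by any quantity this package verifies.

- **Elements** sit on a Fermat spiral from the pole: `z_k` uniform (hence
  uniform area density), azimuth advancing by the golden angle. This
  single 1-based ordering makes prefixes `1..k` compact caps (cluster)
  and stride-4 subsets quasi-uniform (sparse) — both regimes from one
  numbering, as the subsampling formulas require. The original device's
  element-numbering map is not public; the spiral is an emulation of its
  behavior, not a reproduction.
- **Phantoms** are seeded random branching tubes with Gaussian profiles —
  sparse bright curvilinear structure on a dark background. They are
  plausibility stand-ins for vasculature, not anatomy.
- **Forward model**: every absorbing voxel emits a Gaussian-modulated
  sinusoid (scipy's `gausspulse` at the transducer band) delayed by
  time-of-flight and attenuated by 1/r; contributions superpose linearly.
  Implementation: amplitudes are deposited at fractional delay bins and
  each channel is convolved once with the wavelet — exactly the
  superposition model, evaluated efficiently. No directivity, attenuation,
  or acoustic heterogeneity.
- **DAS** interpolates each channel at the voxel's delay and averages over
  channels, so reconstructions from different aperture subsets share one
  intensity scale; without the averaging, a k-of-N subset reconstruction
  is ~N/k dimmer and pair residuals are dominated by the brightness gap
  rather than by artifact structure.
- **Pairs** are jointly min-max normalized (one scale per pair, not per
  image) to [0, 1].

The simulator reproduces the artifact phenomenology that motivates the
restorer — sub-voxel DAS localization, ~4x wider point half-max footprint
under cluster-32, ~3x higher background RMS under sparse-64, and more
high-band residual energy for sparse than for cluster pairs — but passing
tests on it demonstrate the pipeline's correctness and trainability, not
performance on in-vivo data: real tissue adds speckle, heterogeneous sound
speed, limited-view effects of actual element layouts, and anatomical
texture the tube phantoms lack.

## Scaled study conditions

Tests and the acceptance script run the same pipeline at reduced size,
chosen so the whole suite executes on one CPU in minutes: 256 elements at
24 mm radius (sparse-64 and cluster-32 keep the exact index formulas),
(6, 48, 48) grids at 0.2 mm, network base 8 channels / 2 scales /
kv-reduction 4 / 32-wide embedding, 30 training volumes, 400 Adam
iterations on 32x32 crops, 20 held-out volumes, and a 5-seed transfer
comparison at a 120-iteration budget against scratch initialization. The
single-pair overfit check uses base 16 channels. Full-scale defaults
remain available in the config objects.

## Analysis conventions

- **PSNR** `= 10 log10(MAX^2 / MSE)`, MAX = 1; identical inputs report an
  infinity sentinel rather than raising.
- **SSIM** uses the standard covariance form
  `(2 mu_x mu_y + C1)(2 sigma_xy + C2) / ((mu_x^2 + mu_y^2 + C1)(sigma_x^2 + sigma_y^2 + C2))`
  with C1 = (0.01 MAX)^2, C2 = (0.03 MAX)^2. The global-statistics form is
  the tested contract; a windowed mode delegates to scikit-image.
- **Unmixing** solves `epsilon C = PA` per voxel by least squares over
  >= 2 wavelengths (3x3x3 median prefilter and per-wavelength laser-power
  division first; both optional), clamps negative concentrations to zero
  with a flag, and derives `sO2 = C_HbO / (C_HbO + C_HbR)`,
  `HbT = C_HbO + C_HbR`, masking sO2 where HbT is below a floor (default
  1% of the maximum HbT) to avoid 0/0. The shipped extinction table at
  730/756/796/866 nm is linearly interpolated from a standard tabulated
  hemoglobin compilation; every exactness test synthesizes its own
  coefficients so no result depends on the literature values.
- **Vessel density** = segmented vessel area / ROI area, defaulting to an
  Otsu threshold on the ROI histogram (a fixed quantile is selectable);
  a uniform ROI counts fully as vessel. Mean HbT is averaged over the
  segmented voxels. Maximum amplitude projections break depth ties toward
  the shallowest slice.

## Known limitations

- The simulator's physics is deliberately minimal (see above); absolute
  PSNR/SSIM numbers on synthetic pairs do not transfer to hardware data.
- Whether the original system applied G as a spatial mask, a spatial
  convolution, or a frequency mask is unknown; both maintained modes are
  explicit config, and no bit-equivalence with the original is claimed.
- The encoder depth/channel counts of the original model are unpublished;
  the defaults here are declared, not claimed faithful.
- The SSM refiner is unidirectional and single-scan; bidirectional or
  multi-directional scanning is out of scope.
- Training is single-device; no learning-rate schedule (constant lr).
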