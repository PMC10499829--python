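# Methods

`deeptfm` simulates image formation in DEEP-TFM — widefield two-photon
microscopy with temporal focusing and patterned excitation — and trains a
convolutional inverse model to de-scatter the patterned measurements.  This
note records the model, its assumptions, the numerical choices, and what the
synthetic experiments do and do not establish.

## Forward model

A measurement with DMD pattern `H_t` is

```
Y_t(x,y,z) = {((exPSF *3D H_t) ∘ X0) *2D sPSF(z)} *3D emPSF
Ŷ_t(x,y)   = f_EM( Poiss(Y_t(x,y,z_focal)) + Poiss(Ȳ_dark) ) + N(0, σ_read)
```

where `X0` is the fluorophore volume, `∘` elementwise product, `*2D`/`*3D`
plane-wise and volumetric convolution.  The pattern sheet sits at the focal
plane, so plane `z` of the patterned excitation is the 2-D convolution of
`H_t` with the excitation-PSF slice at offset `z − z_focal`: planes away
from the focus see a defocused pattern, and the axial confinement of
temporal focusing is carried entirely by the excitation PSF's axial extent.
Excitation-side scattering is neglected (the long excitation wavelength
scatters weakly); only emission scattering is modeled, plane-by-plane, with
the scattering PSF evaluated at each plane's own depth below the surface.
The training target is the point-scanning (PSTPM-like) image
`(exPSF *3D X0)(z_focal)`.

All convolutions are linear (zero-padded) FFT convolutions with `same`
output via `scipy.signal.fftconvolve`; there is no circular wrap-around.
One reduction is exact and tested against a brute-force direct convolution
at 1e-6 relative error: the simulated PSTPM image equals the direct 3-D
convolution.  Note that the *patterned* frame under a uniform pattern is a
per-plane scaled copy of the object (each plane multiplied by the local
excitation level), not a 3-D convolution of the object — the
delta-reduction identities of the patterned path are tested in that form.

### Point-spread functions

The instrument's PSFs are not part of the contribution, so a standard
separable Gaussian approximation of the diffraction-limited PSF is the
default: lateral `σ_xy = 0.325 λ / (√2 NA^0.91)`, axial
`σ_z = 0.532 λ/√2 · 1/(n − √(n² − NA²))`.  For two-photon excitation the
intensity profile is squared before normalization (excitation ∝ I²), which
sharpens the excitation PSF by √2 in each axis.  Defaults: NA 1.0 water
immersion (n = 1.33), λ_ex = 1.036 μm, λ_em = 0.58 μm (rhodamine-labeled
vasculature).  Grids must be odd-sized so the peak sits on the center
voxel; PSFs are normalized to unit total.  Measured PSF volumes can be
substituted as TIFF stacks; nothing downstream depends on the Gaussian
form.

### Scattering PSF (Monte Carlo)

The sPSF at depth `z0` is the apparent lateral distribution of photon
origins for a point emitter at `z = −z0`, as seen by an objective focused on
that plane through the tissue surface at `z = 0`:

- hop lengths `s = −ln(1 − u)/μ_s` (exponential with mean free path
  `1/μ_s`);
- deflection cosines from the Henyey–Greenstein phase function with
  anisotropy `g` (inverse-CDF sampling; `E[cos θ] = g`); azimuth uniform on
  `[0, 2π)` — the convention of standard tissue photon transport;
- photons launched isotropically over the upper hemisphere (in a
  semi-infinite, absorption-free medium, downward photons of an isotropic
  source never return; the reported acceptance fraction is halved to remain
  per-full-sphere emission).  A `launch="full"` option exists;
- the final hop is truncated exactly at the surface; the exit direction is
  accepted when `sin θ_exit ≤ NA/n_tissue` (cone test in tissue, no
  refraction modeled, matching the model's scope);
- accepted photons are traced straight back along their final direction to
  the launch plane and binned there; off-grid photons are discarded but
  remain in the acceptance denominator.

Defaults: `μ_s = 0.02 /μm` (scattering length 50 μm, the value used to
convert depths to scattering lengths throughout), `g = 0.9` (typical
cortex), 1e6 photons per depth.  Because an unbounded random walk is
transient, photons deeper than `z0 + 20/μ_s` or older than 10⁴ steps are
terminated as lost; both caps are far outside the region that can still
contribute to the within-NA, in-grid histogram, so the induced bias is far
below Monte-Carlo noise at these budgets.

One genuinely model-derived observation: the acceptance fraction *rises*
with depth (from the analytic isotropic value `(1 − cos θ_NA)/2 ≈ 0.17` at
`z0 = 0` to ≈ 0.24 in the diffusive regime), because the angular flux of
diffusely exiting photons at a boundary is cosine-weighted toward the
normal, concentrating it inside the NA cone relative to an isotropic
source.  The tests assert this simulated behavior together with the exact
`z0 = 0` cone fraction.

### EMCCD detection

Detection per pixel: Poisson shot electrons plus Poisson dark electrons
pass through an `N`-stage electron-multiplication register (each stage adds
`Binomial(x, α)` electrons), then Gaussian read noise is added.  The mean
gain is `g_EM = (1 + α)^N` and the excess noise factor

```
F² = 2 (g_EM − 1) g_EM^(−(N+1)/N) + 1/g_EM      (→ 2 at high gain)
```

so mean and variance obey `Ȳ = g_EM (S + D)` and
`σ² = g_EM² F² (S + D) + σ_read²`; both laws are verified empirically
within 3 Monte-Carlo σ (the error budget includes the shared
finite-pool error of the lookup table).

The register is parameterized by `(g_EM, N)` with `α = g_EM^{1/N} − 1`;
defaults `g_EM = 300`, `N = 512` (the register length of common EMCCDs)
give `α ≈ 1.1%`, inside the physically expected 1–2% range.  Dark current
defaults to 0.2 ē/pixel/exposure and read noise to 60 ē, representative of
a back-illuminated EMCCD at video-rate readout; both are plain
configuration values.  Read noise may drive pixels negative; outputs are
not clipped (clipping would bias the mean law), with a display-only clip
flag.

Simulating the cascade per pixel is slow, so the output distribution of
`f_EM` is tabulated once per integer input 0..200 (`lut_max_input`).  Rows
are built from a single pool of single-electron cascade outputs: electrons
traverse the register independently, so `f_EM(x)` is the sum of `x`
independent single-electron outputs, and row `x` is assembled as sums of
`x` picks from the pool — identical in distribution to direct cascading
(verified by two-sample Kolmogorov–Smirnov tests) at a fraction of the
cost.  Inputs beyond the table fall back to the direct cascade.

## Synthetic phantoms

**Beads** — spheres of radius 1.5 px (0.5 μm) and 6 px (2 μm) at the
reference pixel size, base intensities `Normal(1, 0.1)` truncated at zero,
small-bead intensities multiplied by 5.  Placement is collision-free by
rejection sampling; beads may be clipped axially (the sub-volume is a thin
slab of a thicker sample) but not laterally.  Spheres are rasterized with a
linear anti-aliasing ramp over one voxel — a 1.5-px binary sphere would
alias badly.  Counts default to densities of 2 (small) and 1 (large) per
100×100 px² of focal area, putting ~10–30 beads in a 256×256 field of view;
explicit counts override (the 64×64 pipelines use 3 small + 2 large).

**Vessels** — a stand-in generator for downloadable vascular volumes:
persistent random-walk tubes with radii uniform in 1–7 px and per-vessel
intensities that rise with radius, so that the post-render threshold
(default 190/255 of the volume maximum, emulating an 8-bit threshold of
190) preferentially removes the finest, dimmest vessels.  After
thresholding the volume is optionally rescaled by trilinear resampling
(exposed scalar, e.g. 1.09) and normalized to unit maximum.

**Sub-volume extraction** — intensities clipped at 20 (emphasizing fine
structure), an axial window matching the excitation PSF's axial extent slid
with stride 5, and only windows whose mean *strictly exceeds* the clipped
stack's global mean retained (ties excluded).  An empty result is valid.

## Inverse model

A UNet with nine convolution blocks (4 encoder + bottleneck + 4 decoder),
each block two [3×3 conv → batch norm → ReLU] layers; 2×2 max pooling;
bilinear 2× upsampling followed by a 1×1 channel-halving convolution;
skip concatenations; and a concurrent spatial-and-channel
squeeze-and-excitation (scSE) gate after every decoder block — channel gate
(global average pool → 2-layer bottleneck MLP, reduction 2 → sigmoid) and
spatial gate (1×1 conv → sigmoid) combined by elementwise max, the variant
recommended for the scSE block.  A terminal conv + ReLU maps to one
non-negative channel.  Convolutions feeding a batch norm omit their bias
(it is exactly cancelled by mean subtraction).  With the gates forced to 1
the network reduces to the plain UNet (ablation hook, tested).

Channel widths double per level from `base_width` (default 64; the desk
experiments use 16), and input height/width must be divisible by
`2^depth_levels`.

Training uses Adam with `(lr, β1, β2, batch) = (1e-3, 0.9, 0.999, 10)` for
100 epochs by default; the desk-scale experiment trains 20 epochs.  Four
losses are selectable — MSE; RMSLE on `log(1 + x)` of zero-clipped images
(the standard convention, since `log 0` is undefined); elementwise
Smooth-L1 (Huber, quadratic below unit error — the elementwise form is
used; a mean-gated reading of the branch condition appears to be a
typesetting conflation); and KL divergence between the two images each
shifted by 1e-8 and renormalized to probability maps (KL requires
distributions).  KL is the default, the configuration that paired best
with the scSE attention.  Everything is seeded: initialization from the
network seed, shuffling from the training seed; two runs with equal seeds
are bit-identical.

The network and its training loop run on a compact reverse-mode
automatic-differentiation engine written on numpy (`deeptfm.nn`):
im2col-based convolutions, exact adjoint bilinear upsampling, standard
batch-norm backward, Adam.  Every operation's gradient is validated against
central finite differences in the test suite.  The engine is sized for
networks that train in minutes on one CPU core, which is all the desk-scale
experiments need.

Per-stack normalization for learning: measurement stacks are divided by
their own 99.9th percentile and ground truths by their maximum, both
factors stored so reconstructions can be mapped back to physical units.
Networks need bounded inputs and the KL loss needs comparable scales.

## Metrics

SSIM with `C1 = (0.01 L)²`, `C2 = (0.03 L)²`, `L = 1`, averaged over 11×11
Gaussian windows (σ = 1.5) — matching the reference scikit-image
implementation to 1e-6, which the tests assert; uniform-window and
single-window ("global") variants are provided, the latter reducing to the
closed form `(2ab + C1)/(a² + b² + C1)` on constant images.  PSNR is
`10 log10(R²/MSE)` with `R` the reference image's peak by default; cohort
summaries report MSE in 1e-4 units and SSIM in 1e-2 units, the conventional
table scaling.

## Study conditions and problem sizes

The desk-scale learning experiment fixes: bead phantoms of 13×64×64 voxels
(3 small + 2 large beads), depth 4 scattering lengths (200 μm), 8 patterns
at fill 0.5, 100 stacks split 4:1 train:val after holding out 12 test
stacks, scSE-UNet of base width 16, KL loss, 20 epochs.  The photon scale
(`photons_per_unit = 50`) was chosen so the peak expected count in a
noise-free bead frame is ≈ 5 photons — the photon-starved regime widefield
patterned detection actually operates in.  Success is defined as the
trained inverse exceeding the average-of-inputs baseline by ≥ 0.1 mean SSIM
on the held-out stacks; in practice the margin is large (≈ 0.55) because
the EMCCD noise floor makes the naive average very poor at ~5 photons.
Scattering-PSF stacks for dataset simulation use 2×10⁵ photons per depth;
the dedicated width measurements use 10⁶.

The native-scale configuration (32 patterns, 256×256, base width 64,
thousands of stacks, 100 epochs) is exposed by the same code paths and
configuration but is a multi-hour training run, not part of the test
suite.

## What the synthetic experiments do not show

The phantoms emulate the *statistical structure* of the real training data
(bead radii/intensities, vessel radii and thresholding), not real
microscopy stacks: no sample motion, aberrations, depth-dependent
excitation attenuation, refractive-index mismatch, or calibration error of
measured patterns.  Passing the learning acceptance shows the inverse model
can exploit pattern diversity to beat the naive baseline under the stated
forward model; it does not quantify performance on experimentally acquired
measurements, where forward-model mismatch dominates.  The Monte Carlo
model omits absorption, polarization, refraction at the surface, and
heterogeneous media by design.

## Degenerate inputs and tie-breaks

Bead density 0 returns an all-zero volume; a lateral field too small for a
bead raises a placement error.  The vessel threshold keeps only voxels
strictly above the cut, so a threshold at the maximum empties the volume.
`z0 = 0` yields a discrete-delta sPSF and the analytic cone acceptance.
Zero accepted photons raise an error advising more photons or a larger NA.
The sub-volume mean gate excludes ties.  Max-pool gradients follow the
first maximal element; SSIM on identical images is exactly 1; PSNR of
identical images reports +inf.
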