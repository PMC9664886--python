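# Methods

This note records the modelling and numerical choices behind `sfdigan`, the
assumptions they rest on, and what the synthetic experiments do and do not
demonstrate.

## Forward optics

Diffuse reflectance of a semi-infinite turbid medium under spatially
modulated illumination is computed in closed form from the diffusion
approximation.  With transport coefficient µ_tr = µ_a + µ_s′, reduced albedo
a′ = µ_s′/µ_tr and modulated effective attenuation
µ_eff′(f_x) = sqrt(3 µ_a µ_tr + (2π f_x)²),

    Rd(f_x) = 3 A a′ / ((µ_eff′/µ_tr + 1)(µ_eff′/µ_tr + 3A)).

The internal-reflection parameter A comes from the Groenhuis polynomial for
the effective Fresnel coefficient, R_eff = 0.0636 n + 0.668 + 0.710/n −
1.440/n², with A = (1 − R_eff)/(2(1 + R_eff)); at the tissue-like n = 1.43
used throughout, A ≈ 0.1446.  A ray-traced renderer would add stochastic
noise and geometric shading on top of essentially this same response; the
closed form keeps image formation deterministic, monotone and testable,
which is what the learning problem needs.

Assumptions inherited from diffusion theory: µ_s′ ≫ µ_a is not strictly
required, but accuracy degrades in the low-albedo corner, and Rd is *not*
perfectly monotone decreasing in µ_a below µ_s′ ≈ 0.7 mm⁻¹ at the working
frequency 0.2 mm⁻¹ (the (2πf_x)² term dominates µ_eff′ there).  The
monotonicity property tests therefore check the diffusive sub-range
µ_s′ ≥ 0.7 mm⁻¹.  Sub-diffusive high-frequency imaging and anisotropy
beyond the reduced description are out of scope.

## Material parametrisation

Materials are described by Blender-style factors (final, absorption,
scattering) ∈ [0,1]³.  The calibration to physical proxies is a declared
convention, not a measured mapping:

    µ_a  = µ_a_max (1 − final)(1 − absorption),   µ_a_max  = 0.25 mm⁻¹
    µ_s′ = µ_s_max · final · scattering,          µ_s_max  = 2.5 mm⁻¹

This bilinear form is continuous, spans the full property rectangle
boundary-to-boundary, and is monotone in every factor: sweeping the final
factor 0.05 → 0.95 at full component strength (absorption = 0, scattering
= 1) walks the material from absorption-dominated (0.95:0.05) to
scattering-dominated (0.05:0.95), which is the canonical dataset sweep.
The "absorption" factor is a transparency — 0 is fully absorbing — so the
default sweeps fix it at 0, full strength; the factor-grid experiment rows
sweep it over 0.05–0.95 where a range is called for.

## Scene models and dataset enumeration

Five parametric families:

1. *rectangular* — flat, one material;
2. *rect_curved* — two materials along a circular-arc boundary
   (parametrised by chord position and sagitta; zero sagitta degenerates to
   a straight split);
3. *rect_ragged* — three materials along seeded ragged boundaries (a
   cumulative Gaussian random walk, moving-average smoothed, amplitude and
   smoothing width in config);
4. *rect_tumour* — the curved model plus translating/scaling tumour
   spheroids (projected-ellipse footprints);
5. *cylinder* — a hollow lumen with optional polyp hemispheroids scattered
   uniformly in (angle, depth) on the wall.

Datasets are enumerated keyframe-style: each tracked parameter is linearly
interpolated between keyframes across the frame range, so "one base scene +
tracks + start/end frame" fully determines a dataset.  All stochastic
constructions (ragged walks, polyp scatter, splits) derive from recorded
seeds.  Default composition mirrors the study design: four flat models in
equal parts (70/30 train/validation split) and cylinders in a 200:120
plain:polyp ratio (80/20 split).

## Rendering

Flat scenes are telecentric: I(p) = g[Rd(0)/2 + Rd(f_x)/2 · cos(2π f_x u +
φ)] with u the lateral position in mm.  The field of view is 50 mm, giving
an integer number (10) of carrier periods at f_x = 0.2 mm⁻¹ — and also at
the 0.18/0.22 mm⁻¹ robustness frequencies — so windowed demodulation sees
no spectral leakage from the field edges.  The gain g is anchored so the
brightest admissible material (µ_a → 0, µ_s′ = µ_s_max) peaks at 0.95 of
full scale: absolute radiometry is irrelevant after 8-bit quantisation, and
anchoring at the bright extreme guarantees no material ever clips (a
mid-range anchor would saturate the low-absorption corner of the sweep).

The lumen is rendered with a pinhole camera on the axis looking along it
and the projector offset by a small baseline perpendicular to the fringe
planes.  Per pixel the view ray is intersected with the wall (polyps
protrude inward; the intersection uses the footprint height at the
unperturbed hit point — a first-order bump approximation), the projected
sinusoid's phase is evaluated at the 3-D point, the local surface spatial
frequency is estimated by finite differences of that phase along the
surface, and returned power falls off as (R/d)².  This produces the
characteristic dark lumen centre, depth-dependent brightness, bent fringes
at polyps and a spatially varying effective frequency — the features that
break conventional uniform-frequency demodulation.  Because the camera
looks *along* the axis, there is no flat-field limit of this geometry: as
the radius grows at fixed field of view the wall recedes to infinity, so
consistency with the flat renderer is established instead by demodulating
thin wall annuli and recovering the wall properties.

Ground truths are flat-shaded with identical projection geometry: R encodes
µ_a/µ_a_max and G encodes µ_s′/µ_s_max, each remapped linearly into
[0.05, 0.95] and quantised half-up to 8 bits (13…242); B ≡ 0.  Cylinder
background (rays exiting past the far end) is black in both halves.
Optional seeded Poisson–Gaussian noise exists for robustness experiments
and is off by default; the training data are otherwise noise-free, which is
a deliberate property of synthetic supervision, not an accident.

## SSOP baseline

The single-snapshot baseline splits the image along the fringe axis into a
DC component and a single-sideband AC envelope.  Both filters are
Gaussian-shaped in the frequency domain (σ_f = f_x/4 by default, a config
knob): a Gaussian passband has no spatial sidelobes, so boundary artefacts
decay within a few multiples of 1/(2πσ_f) ≈ 3.2 mm instead of ringing
across the field.  The calibrated reflectance pair (2·I_DC/g, 2·|I_AC|/g)
is inverted per pixel through a reflectance lookup table — Rd(0) and
Rd(f_x) tabulated on a 101×101 property grid — by piecewise-linear
interpolation of the scattered inverse map, with out-of-gamut queries
falling back (flagged) to the nearest tabulated node.  The test suite
verifies round-trip recovery on noiseless homogeneous flat renders to
within 5% everywhere away from the borders; applied naively to lumen
images the same baseline errs several-fold worse, which is the motivating
contrast for the learned mapping.

## The conditional GAN

The generator is a U-Net: a stem convolution, L strided encoder levels with
a residual block per level (short skips), and a nearest-neighbour-upsample +
convolution decoder with encoder→decoder concatenation (long skips),
finishing in a tanh head.  Depth scales with input size (L = log2(size) −
3, so 5 levels at 256 px, 3 at 64 px); channel widths double per level,
capped at 64.  The discriminator is the spec'd three-layer patch
classifier: two stride-2 spectrally normalised convolutions and a final
stride-1 score map, leaky-ReLU slope 0.2, conditioned by concatenating the
input image with the candidate property map.  All convolution weights are
initialised N(0, 0.02²) from the run seed.

Losses are least-squares adversarial (real label 1, fake 0) plus λ·L1 with
λ = 60; Adam at 1e-4, constant for the first half of the epochs then
linearly decayed to zero.  The discriminator sees the current batch plus a
batch drawn uniformly from a 64-pair history buffer of previously generated
fakes.  Spectral normalisation uses one power iteration per step with the
full gradient of W/σ.  Numerical safeguards: non-finite losses abort
training with a diagnostic error; inference is deterministic (no dropout,
normalisation statistics are per-image).

Choices the sources leave open, decided here: batch size 1 (more optimiser
updates per epoch measurably dominate raw throughput on this workload);
Adam β = (0.9, 0.999); instance normalisation on generator features
(enabled — the absolute fringe amplitude still reaches the decoder through
the long skips, and normalised interior features condition optimisation far
better in ablation); spectral normalisation on the discriminator only; tanh
output head (a linear head ablated worse).

## Evaluation protocol

NMAE per channel is Σ|p − p_ref| / Σ p_ref over all pixels of a validation
image, reported as a percentage; it is computed on the 8-bit encoded
channels, and since decoding to mm⁻¹ (R/255 · 0.25, G/255 · 2.5) is a
monotone linear rescale the value is identical on either scale.  All pixels
enter the sums, including cylinder background (where the reference is zero
the pixel adds only numerator mass).  Difference maps are per-pixel
percentage errors with zero-reference pixels masked; on a uniform reference
their unmasked mean coincides with the NMAE.  Reports carry per-image
values plus the mean and the maximum ("envelope") per channel.

## Scaled-down study conditions

The full-scale study (256×256 images, 200/320-image datasets, 200 epochs)
is a GPU workload.  The package's reduced reference conditions, chosen for
convergence within a single-CPU run and then frozen, are: 32×32 images
(the 50 mm field keeps 3.2 px per fringe period, above Nyquist), 32 frames
per flat model (128 images, split 90/38), a 60:36 plain:polyp cylinder set
(split 77/19), base channel width 12, batch size 1, and 100–200 epochs
with the same half-constant/half-decayed schedule.  Composition ratios,
splits, losses, learning rate, initialisation and buffer semantics are
unchanged from the full-scale design; 64 and 128 px runs use the identical
code path with deeper generators.

What the reduced runs demonstrate is that the pipeline learns accurate
property maps from single (distorted-)fringe images at the few-percent
NMAE level with the exact mechanism of the full-scale system.  Absolute
NMAE values at this scale are not directly comparable to full-scale
figures, for two structural reasons.  First, boundary-pixel error is
proportionally larger at coarse resolution (a 1-px boundary band is 3% of
a 32-px image but 0.4% of a 256-px one).  Second, the per-image NMAE
*envelope* over a validation set is dominated by the sweep-extreme images
whose reference channel mass approaches the 13-level encoding floor: on
such an image a tight relative envelope requires the 8-bit-rounded
prediction to be within about half a gray level everywhere, a
sub-quantisation accuracy that is reached only deep into training.  The
optimiser-step budget, not the model, is the binding constraint at reduced
scale.

The synthetic data deliberately omit several properties of experimental
SFDI images: sensor and shot noise (available but off), specular
reflections, surface texture, motion artefacts, calibration drift and
multi-spectral response.  Passing tests therefore certify internal
consistency of the forward model, demodulation, learning and metrics — not
performance on experimental data.

## Known limitations

- The factor→property calibration is a convention; only its monotone,
  range-spanning structure is load-bearing.
- The diffusion closed form substitutes for ray tracing; it shares the
  approximation's low-albedo weaknesses and models no lateral transport
  across material boundaries (boundary pixels are rendered, not diffused).
- The lumen projector model (co-axial camera, small baseline) is one of
  several plausible endoscopic geometries; the paper-level conclusion that
  fringe distortion breaks uniform-frequency demodulation is insensitive to
  the exact placement.
- The numpy network trains ~two orders of magnitude more slowly than a GPU
  implementation; reduced-scale envelopes are correspondingly looser.
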