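# Methods

## Measurement model and estimators

The measured plane *g* is modelled as Poisson(*H* ⊗ *f*): fluorescence
imaging noise is dominated by photon-counting statistics, so the
likelihood is Poisson with mean equal to the PSF-blurred true image. The
prior on *f* is Gaussian with a spatially varying (nonstationary) mean
E(*f<sub>s</sub>*); its variance is absorbed into the single relaxation
weight λ. Minimizing the penalized negative log-likelihood

J(f) = Σ [(H⊗f)ₛ − gₛ ln (H⊗f)ₛ] + (λ/2) Σ (fₛ − E(fₛ))²

with the one-step-late device (evaluate the prior gradient at the previous
iterate; use H normalized to unit mass so H_adj ⊗ 1 = 1) yields the
multiplicative update implemented in `solvers`:

f⁺ = f · [H_adj ⊗ (g / (H⊗f))] / (1 + λ (f − Ê(f))).

`lr` (λ = 0), `map_hunt` (Ê = g frozen) and `map_d` (Ê re-estimated from
the current iterate each iteration) share this code path, so the λ = 0
reduction chain is bit-exact by construction.

### Kernel-regression expectation (`expectation`)

Ê(fₛ) = Σ_{i∈Wₛ} K(fₛ, fᵢ) fᵢ / Σ K(fₛ, fᵢ) with K(a, b) = exp(−(a−b)²/β),
over the (2r+1)² window Wₛ (default r = 4, the 81-sample window), with the
center sample included (weight exactly 1, so the denominator never
vanishes). The kernel is purely photometric; locality comes entirely from
the window. Windows are completed at borders by half-sample reflection.
The estimate is a convex combination of window samples, hence bounded by
the window extrema, and for β → ∞ it degenerates to the box mean.

## Parameters

| parameter | default | units / meaning |
|---|---|---|
| λ | 0.2 | prior weight, per unit intensity on the [0, 1] working scale |
| β | 625 | kernel relaxation, quoted on the 0–255 intensity scale (= 25² → a soft 25-level similarity threshold); divided by 255² internally |
| window | 9×9 | kernel-regression support (81 samples) |
| iterations | 50 | fixed count, no early stopping (max relative change is recorded in the trace) |
| eps | 1e-12 | floor for the ratio and prior denominators; floored-pixel counts are recorded in the trace |

**λ units.** In the update denominator 1 + λ(f − Ê), λ carries units of
1/intensity, so its numeric value is tied to the intensity scale. On the
[0, 1] working scale, λ = 0.2 guarantees λ·|f − Ê| < 1, i.e. strictly
positive denominators; rescaling λ by 255 (reading it on the 0–255 scale,
as is done for β) makes the denominator change sign across large
deviations and the iteration diverges. λ is therefore interpreted on the
working scale and not rescaled. β, by contrast, only parametrizes an
intensity-difference comparison and is safely quoted on the 0–255 scale.

**Working scale.** Images are handled as float64 in [0, 1]; integer files
are rescaled by their dtype maximum on read and re-quantized (round
half-up) on write. Coordinates are row-major, 0-based, pixel centers at
integer positions.

## PSF handling (`psf`)

Synthesized Gaussian PSFs are truncated at radius ceil(4σ) (< 1e-4 of mass
discarded) and normalized to unit sum; empirical PSF images are accepted
after flat-background subtraction of their minimum. The adjoint is the
kernel flipped about its center. Convolution is FFT-based with symmetric
(mirror) padding by one kernel radius; a periodic mode exists for the
flux-conservation and adjointness identities used in tests. Before
deconvolution each plane is edge-tapered: within one PSF radius of the
border the image is blended with its own blurred version by a cosine
window that is 0 at the boundary and exactly 1 beyond the margin, so the
interior is bit-identical to the input and FFT border ringing is
suppressed.

## Synthetic scenes (`simulate`)

The generator emulates the statistical character of simulated
fluorescence-stained cell populations rather than cloning any particular
simulator's internals: solver benchmarking needs the right structure
(compartmentalized cells, realistic degradation), not pixel-level parity
with another code base.

Each cell is a Fourier-perturbed ellipse of cytoplasm with a soft
(diffuse) intensity falloff, an interior nucleus, and 4 subcellular
structures whose soft skirts are clipped at the cell outline; cells are
composited by per-pixel maximum, and when overlap is allowed they may be
cut by the frame border (a confluent field). Compartments render to
separate channels (subcellular → red, cytoplasm → green, nuclei → blue),
as in a DAPI/FITC/TRITC triple stain. Degradation per channel: Gaussian
PSF (σ = 4 px) → smooth low-frequency autofluorescence background
(min-max-normalized field scaled to peak amplitude 0.05 of full scale)
→ Poisson photon stage (Poisson(photon_scale·v)/photon_scale) → additive
Gaussian CCD noise (variance 0.001) → clip at 0. A single integer seed
makes the whole scene bit-reproducible.

**Operating-point calibration.** The degradation settings are fixed
(autofluorescence 0.05, CCD 0.001, σ = 4), so the measured-vs-truth SNR,
10·log10(Σt²/Σ(m−t)²) pooled over channels, is set by the scene's signal
energy density, its sharpness (how much energy the blur displaces), and
the photon budget. The defaults — a bright confluent monolayer (mean cell
radius 72 px, coverage factor 3.0, unit peak intensities, boundary
transitions of ~10% of the compartment radius, nuclei at 0.65 of the cell
radius, four large subcellular domains per cell) with photon_scale 5000 —
were chosen once so the scene lands at the ~20.7 dB operating point
(measured: 20.8 dB at 256², 21.0 dB at 800², 5 seeds each) while keeping a
substantial share (~40%) of the measurement error in blur rather than
noise. The blur share matters scientifically: it is the regime in which a
static prior mean Ê = g is biased and the dynamically updated kernel
estimate pays off; in a nearly blur-free scene the measured image itself
is an excellent prior mean and the methods become indistinguishable.
The autofluorescence "energy" parameter is realized as the background
field's peak amplitude on the unit intensity scale: interpreting it as 5%
of the *signal energy* would by itself cap the SNR at 13 dB,
inconsistent with the stated ~20.7 dB operating point.

**What the simulator does not model:** optical vignetting and illumination
gradients, spectral bleed-through between channels, depth-dependent (3-D)
blur, detector gain variation, saturation, and sub-pixel camera sampling.
Passing benchmarks on these scenes therefore demonstrates correct solver
behaviour under the stated noise model, not performance on any particular
instrument's acquisitions.

## Evaluation (`metrics`)

SNR is the energy ratio 10·log10(Σ truth² / Σ(est − truth)²), per plane or
pooled over a stack's channels (one ratio over all pixels); an exact match
reports +inf. Line profiles are bilinear samples along a segment,
normalized by the trace maximum; RMS contrast is std/mean over a region.

## Numerical choices and degenerate inputs

- Denominators (both the LR ratio and the prior term) are floored at
  eps = 1e-12; the per-iteration count of floored pixels is recorded in
  the `IterationTrace` rather than silently discarded. At the default
  parameters the count is zero.
- Exactly `iterations` steps are run (no convergence early-stop); negative
  values are clipped only once, after the final iteration — intermediate
  iterates are positive by construction.
- Initialization is f⁰ = the edge-tapered measurement, the LR convention;
  it makes the λ = 0 pipeline agree step-by-step with standard LR.
- An all-zero reference makes SNR undefined (error raised); an all-zero
  profile trace stays zero instead of being normalized.
- 16-bit multichannel PNG is rejected (writer limitation); TIFF covers
  that case.

## Problem sizes

Unit and property tests run on 5×5–64×64 planes with brute-force oracles
(naive O(N·|W|) expectation, direct-sum convolution) at 1e-12 agreement;
the end-to-end benchmark tests use 256² scenes and the scripted benchmark
five 800² scenes, sizes at which scene statistics (and hence the SNR
operating point) are converged.
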