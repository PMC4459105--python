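# mapdeconv

Maximum a posteriori (MAP) deconvolution of 2-D fluorescence microscopy
images with a **dynamically updated kernel-regression prior** (MAP-D),
together with the classical Richardson–Lucy (LR) and static-prior MAP-Hunt
baselines, a synthetic fluorescence cell-population simulator for
benchmarking, and SNR/contrast/line-profile evaluation tools.

## The problem and the model

A fluorescence microscope blurs the specimen with its point-spread function
*H*, and photon counting makes the measurement Poisson distributed: the
measured image *g* is modelled as

&nbsp;&nbsp;&nbsp;&nbsp;*g* ~ Poisson(*H* ⊗ *f*),

where *f* is the true fluorophore distribution. MAP estimation maximizes
*p*(*f* | *g*) ∝ *p*(*g* | *f*) *p*(*f*) with a Gaussian prior whose mean
E(*f*<sub>s</sub>) varies over pixel sites *s*. Minimizing the negative log
posterior

&nbsp;&nbsp;&nbsp;&nbsp;J(*f*) = Σ<sub>s</sub> [(H⊗f)<sub>s</sub> − g<sub>s</sub> ln (H⊗f)<sub>s</sub>] + (λ/2) Σ<sub>s</sub> (f<sub>s</sub> − E(f<sub>s</sub>))²

by a one-step-late fixed-point iteration gives the multiplicative update

&nbsp;&nbsp;&nbsp;&nbsp;f<sup>j+1</sup> = f<sup>j</sup> · [H<sub>−s</sub> ⊗ (g / (H ⊗ f<sup>j</sup>))] / (1 + λ (f<sup>j</sup> − Ê(f<sup>j</sup>))),

where H<sub>−s</sub> is the adjoint (flipped) PSF. The three solvers differ
only in the prior mean Ê:

| method   | prior mean Ê                                       |
|----------|-----------------------------------------------------|
| `lr`     | none (λ = 0): pure Richardson–Lucy                   |
| `map_hunt` | the measured image *g*, fixed across iterations    |
| `map_d`  | kernel-regression estimate of the **current iterate**, recomputed every iteration |

The MAP-D estimate is a similarity-weighted local mean,

&nbsp;&nbsp;&nbsp;&nbsp;Ê(f<sub>s</sub>) = Σ<sub>i∈W<sub>s</sub></sub> K(f<sub>s</sub>, f<sub>i</sub>) f<sub>i</sub> / Σ<sub>i∈W<sub>s</sub></sub> K(f<sub>s</sub>, f<sub>i</sub>),&nbsp;&nbsp;&nbsp; K(a, b) = exp(−(a−b)²/β),

over a square window W<sub>s</sub> (default 9×9 = 81 samples). Because the
Gaussian kernel down-weights dissimilar intensities, the estimate denoises
without smearing edges, and because it tracks the progressively deblurred
iterate rather than the blurry measurement, it remains a faithful prior
mean where the static choice Ê = *g* is biased.

Default parameters are λ = 0.2, β = 625 (on the conventional 0–255
intensity scale; rescaled internally to the [0, 1] working scale), a
9×9 window, and 50 iterations.

## Worked example

Simulate a 256×256 three-channel stained cell population, deconvolve the
degraded measurement with MAP-D, and evaluate against the ground truth:

```sh
mapdeconv simulate --preset default --seed 1 --out scene/
# scene written to scene/ (measured SNR 20.94 dB)

mapdeconv deconvolve scene/measured.tif --method map-d --psf-sigma 4 --out mapd.tif
# deconvolved image written to mapd.tif

mapdeconv evaluate --truth scene/truth.tif --test scene/measured.tif | grep '"snr_db"' | head -1
#  "snr_db": 21.727326870038084,
mapdeconv evaluate --truth scene/truth.tif --test mapd.tif | grep '"snr_db"' | head -1
#  "snr_db": 25.56146033008622,
```

The simulator degrades the ground truth with a σ = 4 px Gaussian PSF,
a smooth autofluorescence background (peak amplitude 0.05), Poisson photon
statistics and additive CCD read noise (variance 0.001), landing the
measurement near the ~20.7 dB operating point. Fifty MAP-D iterations
recover ≈ 4 dB of SNR on this scene; the per-channel report also shows the
RMS contrast increase (e.g. green channel 0.348 → 0.364). Every command
writes its resolved configuration (YAML) next to its outputs, and identical
(config, seed) pairs reproduce results bit-identically.

The same pipeline is available as a library:

```python
from mapdeconv import SimConfig, simulate_scene, gaussian_psf, DeconvParams, deconvolve, stack_snr_db

scene = simulate_scene(SimConfig(seed=1))
restored, traces = deconvolve(scene.measured, gaussian_psf(4.0), DeconvParams(), method="map_d")
print(stack_snr_db(scene.truth, scene.measured), "->", stack_snr_db(scene.truth, restored))
# 20.94 -> 24.45   (in-memory, without 16-bit file quantization)
```

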