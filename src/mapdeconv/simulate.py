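"""Synthetic fluorescence-stained cell populations and their degraded images.

The generator emulates the statistical character of SIMCEP-class simulators:
each cell is a randomly placed and oriented smooth blob (a Fourier-perturbed
ellipse) of diffuse cytoplasm with an interior nucleus and a handful of
brighter subcellular structures, composited by per-pixel maximum so that
overlapping cells stay bounded. Compartments render into separate channels
(subcellular -> red, cytoplasm -> green, nuclei -> blue by default),
mirroring a DAPI/FITC/TRITC triple-stain acquisition.

The degradation pipeline maps the ground truth to a simulated measurement,
per channel:

1. convolution with a Gaussian PSF (default sigma = 4 px);
2. addition of a smooth low-frequency autofluorescence background whose peak
   amplitude is ``autofluorescence_energy`` on the unit intensity scale;
3. a Poisson photon-counting stage, Poisson(photon_scale * v) / photon_scale;
4. additive zero-mean Gaussian CCD read noise of variance ``ccd_noise_var``;
5. clipping at zero.

Everything is driven by a single integer seed: identical (config, seed)
pairs give bit-identical scenes.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .io_formats import ImageStack, write_image
from .psf import gaussian_psf, apply_psf

__all__ = [
    "SimConfig",
    "SimScene",
    "PlacementError",
    "simulate_population",
    "degrade",
    "simulate_scene",
    "make_fixture",
    "PRESETS",
]


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed within the image bounds."""


@dataclass
class SimConfig:
    """Scene and degradation settings.

    Geometry: ``cell_radius`` is the mean cytoplasm radius in pixels; cell
    shapes are perturbed ellipses with soft (diffuse) intensity falloff at
    their boundary, as fluorescence-stained cytoplasm appears. ``n_cells``
    defaults to a population covering roughly two thirds of the frame.

    Degradation: ``autofluorescence_energy`` (0.05) is the peak amplitude of
    the smooth background field on the unit intensity scale;
    ``ccd_noise_var`` (0.001) the additive Gaussian read-noise variance;
    ``psf_sigma`` (4 px) the optical blur; ``photon_scale`` the expected
    photon count at unit intensity for the Poisson stage (None disables it,
    i.e. the infinite-photon limit).
    """

    height: int = 256
    width: int = 256
    n_cells: int | None = None
    cell_radius: float = 72.0
    radius_jitter: float = 0.15
    allow_overlap: bool = True
    n_subcellular: int = 4
    n_channels: int = 3
    channel_assignment: dict = field(
        default_factory=lambda: {"subcellular": 0, "cytoplasm": 1, "nuclei": 2}
    )
    # per-compartment base intensities on [0, 1], with mild per-cell variation
    cytoplasm_intensity: float = 1.0
    nucleus_intensity: float = 1.0
    subcellular_intensity: float = 1.0
    intensity_variation: float = 0.08
    # diffuse-boundary widths, as fractions of the compartment radius,
    # mimicking the soft falloff of stained compartments in a bright
    # confluent monolayer
    cytoplasm_softness: float = 0.1
    nucleus_softness: float = 0.2
    structure_softness: float = 0.25
    nucleus_radius_ratio: float = 0.65
    structure_radius_range: tuple = (0.4, 0.5)
    coverage: float = 3.0
    autofluorescence_energy: float = 0.05
    ccd_noise_var: float = 0.001
    psf_sigma: float = 4.0
    photon_scale: float | None = 5000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 8 or self.width < 8:
            raise ValueError("image must be at least 8x8")
        if self.n_subcellular < 0:
            raise ValueError("n_subcellular must be >= 0")
        if self.autofluorescence_energy < 0 or self.ccd_noise_var < 0:
            raise ValueError("energies and variances must be >= 0")
        if not 1 <= self.n_channels <= 3:
            raise ValueError("1 to 3 channels supported")
        if self.n_cells is None:
            area = self.height * self.width
            cell_area = math.pi * self.cell_radius**2
            self.n_cells = max(1, round(self.coverage * area / cell_area))
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")

    def resolved(self) -> dict:
        """Plain-dict form, suitable for YAML serialization."""
        return asdict(self)


@dataclass
class SimScene:
    """A ground-truth scene, its measured counterpart, and compartment masks."""

    truth: ImageStack
    measured: ImageStack | None
    masks: dict[str, np.ndarray]
    config: SimConfig
    #: structure label -> owning cell id, for provenance across overlaps
    structure_owner: dict[int, int] = field(default_factory=dict)


def _perturbed_radius(theta, base_r, axis_ratio, phi0, coeffs, rng_phases):
    """Radius of a smoothly perturbed ellipse as a function of polar angle."""
    # ellipse base shape
    ct = np.cos(theta - phi0)
    st = np.sin(theta - phi0)
    r = base_r / np.sqrt(ct**2 + (st / axis_ratio) ** 2)
    # low-order Fourier perturbation keeps the outline smooth and star-shaped
    for k, (a, ph) in enumerate(zip(coeffs, rng_phases), start=2):
        r = r * (1.0 + a * np.cos(k * theta + ph))
    return r


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _inside_cell(sl, cy, cx, cyto_edge) -> np.ndarray:
    """Boolean patch over slices ``sl``: inside the cell's cytoplasm outline."""
    yy, xx = np.mgrid[sl]
    dy = yy - cy
    dx = xx - cx
    return np.hypot(dy, dx) <= cyto_edge(np.arctan2(dy, dx))


def _render_blob(shape, center, edge_fn, softness):
    """Render a soft-edged blob; returns (intensity patch, slices, support).

    ``edge_fn(theta)`` gives the blob radius per polar angle. Intensity ramps
    smoothly from 0 at the outline to 1 at ``softness`` pixels inside it.
    """
    cy, cx = center
    # generous bounding box
    theta_grid = np.linspace(0.0, 2 * np.pi, 128, endpoint=False)
    rmax = float(np.max(edge_fn(theta_grid))) + softness + 2.0
    y0 = max(0, int(np.floor(cy - rmax)))
    y1 = min(shape[0], int(np.ceil(cy + rmax)) + 1)
    x0 = max(0, int(np.floor(cx - rmax)))
    x1 = min(shape[1], int(np.ceil(cx + rmax)) + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy = yy - cy
    dx = xx - cx
    rho = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    edge = edge_fn(theta)
    intensity = _smoothstep((edge - rho) / softness)
    return intensity, (slice(y0, y1), slice(x0, x1)), intensity > 0


def simulate_population(cfg: SimConfig) -> SimScene:
    """Generate the noiseless ground-truth stack and compartment label masks.

    Returns a :class:`SimScene` with ``measured=None``. Masks are int32
    label grids: ``cell`` and ``nucleus`` carry the owning cell id (1-based,
    later cells overwrite earlier ones where populations overlap) and
    ``subcellular`` carries a global structure id; structures are placed
    wholly inside their cell's cytoplasm support.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0]))
    h, w = cfg.height, cfg.width
    channels = [np.zeros((h, w)) for _ in range(cfg.n_channels)]
    masks = {
        "cell": np.zeros((h, w), dtype=np.int32),
        "nucleus": np.zeros((h, w), dtype=np.int32),
        "subcellular": np.zeros((h, w), dtype=np.int32),
    }
    ch = {
        name: idx
        for name, idx in cfg.channel_assignment.items()
        if idx is not None and idx < cfg.n_channels
    }

    if cfg.allow_overlap:
        # confluent field: cells may be cut by the frame edge
        lo_y, hi_y, lo_x, hi_x = 0.0, float(h), 0.0, float(w)
    else:
        margin = cfg.cell_radius * (1 + cfg.radius_jitter) * 1.2
        if 2 * margin >= min(h, w):
            raise PlacementError(
                f"cell radius {cfg.cell_radius} too large for a {h}x{w} image"
            )
        lo_y, hi_y, lo_x, hi_x = margin, h - margin, margin, w - margin

    centers: list[tuple[float, float]] = []
    structure_id = 0
    structure_owner: dict[int, int] = {}
    for cell_id in range(1, cfg.n_cells + 1):
        # --- placement -----------------------------------------------------
        placed = False
        for _ in range(200):
            cy = rng.uniform(lo_y, hi_y)
            cx = rng.uniform(lo_x, hi_x)
            if cfg.allow_overlap or all(
                np.hypot(cy - py, cx - px) > 1.8 * cfg.cell_radius
                for py, px in centers
            ):
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place cell {cell_id} after 200 attempts"
            )
        centers.append((cy, cx))

        # --- cytoplasm -----------------------------------------------------
        base_r = cfg.cell_radius * rng.uniform(
            1 - cfg.radius_jitter, 1 + cfg.radius_jitter
        )
        axis_ratio = rng.uniform(0.75, 1.0)
        phi0 = rng.uniform(0, 2 * np.pi)
        coeffs = rng.normal(0.0, 0.04, size=3) / np.arange(1, 4)
        coeffs = np.clip(coeffs, -0.1, 0.1)
        phases = rng.uniform(0, 2 * np.pi, size=3)
        soft_c = cfg.cytoplasm_softness * base_r

        def cyto_edge(theta):
            return _perturbed_radius(theta, base_r, axis_ratio, phi0, coeffs, phases)

        patch, sl, support = _render_blob((h, w), (cy, cx), cyto_edge, soft_c)
        level = cfg.cytoplasm_intensity * rng.uniform(
            1 - cfg.intensity_variation, 1.0
        )
        if "cytoplasm" in ch:
            plane = channels[ch["cytoplasm"]]
            plane[sl] = np.maximum(plane[sl], level * patch)
        masks["cell"][sl][support] = cell_id

        theta_grid = np.linspace(0.0, 2 * np.pi, 256, endpoint=False)
        min_edge = float(np.min(cyto_edge(theta_grid)))

        # --- nucleus -------------------------------------------------------
        nuc_r = cfg.nucleus_radius_ratio * base_r * rng.uniform(0.9, 1.1)
        off_rho = rng.uniform(0, 0.12 * base_r)
        off_phi = rng.uniform(0, 2 * np.pi)
        ncy = cy + off_rho * np.sin(off_phi)
        ncx = cx + off_rho * np.cos(off_phi)
        nuc_ratio = rng.uniform(0.85, 1.0)
        nuc_phi0 = rng.uniform(0, 2 * np.pi)
        soft_n = cfg.nucleus_softness * nuc_r

        def nuc_edge(theta):
            ct = np.cos(theta - nuc_phi0)
            st = np.sin(theta - nuc_phi0)
            return nuc_r / np.sqrt(ct**2 + (st / nuc_ratio) ** 2)

        npatch, nsl, _ = _render_blob((h, w), (ncy, ncx), nuc_edge, soft_n)
        npatch = npatch * _inside_cell(nsl, cy, cx, cyto_edge)
        nsupport = npatch > 0
        nlevel = cfg.nucleus_intensity * rng.uniform(
            1 - cfg.intensity_variation, 1.0
        )
        if "nuclei" in ch:
            plane = channels[ch["nuclei"]]
            plane[nsl] = np.maximum(plane[nsl], nlevel * npatch)
        masks["nucleus"][nsl][nsupport] = cell_id

        # --- subcellular structures ---------------------------------------
        # structure cores are spread through the cell; their soft skirts are
        # clipped by the cell's own support (fluorophores stop at the membrane)
        placed_spots: list[tuple[float, float]] = []
        for _ in range(cfg.n_subcellular):
            structure_id += 1
            s_r = rng.uniform(*cfg.structure_radius_range) * base_r
            soft_s = cfg.structure_softness * s_r
            reach = max(0.75 * min_edge - 0.5 * s_r, 0.0)
            for _attempt in range(50):
                pos_rho = math.sqrt(rng.uniform(0, 1)) * reach
                pos_phi = rng.uniform(0, 2 * np.pi)
                scy = cy + pos_rho * np.sin(pos_phi)
                scx = cx + pos_rho * np.cos(pos_phi)
                if all(
                    np.hypot(scy - qy, scx - qx) > 0.8 * s_r
                    for qy, qx in placed_spots
                ):
                    break
            placed_spots.append((scy, scx))

            def spot_edge(theta, s_r=s_r):
                return np.full_like(theta, s_r)

            spatch, ssl, _ = _render_blob((h, w), (scy, scx), spot_edge, soft_s)
            spatch = spatch * _inside_cell(ssl, cy, cx, cyto_edge)
            ssupport = spatch > 0
            slevel = cfg.subcellular_intensity * rng.uniform(
                1 - cfg.intensity_variation, 1.0
            )
            if "subcellular" in ch:
                plane = channels[ch["subcellular"]]
                plane[ssl] = np.maximum(plane[ssl], slevel * spatch)
            masks["subcellular"][ssl][ssupport] = structure_id
            structure_owner[structure_id] = cell_id

    names = ["red", "green", "blue"][: cfg.n_channels]
    truth = ImageStack(planes=channels, channel_names=names)
    return SimScene(
        truth=truth,
        measured=None,
        masks=masks,
        config=cfg,
        structure_owner=structure_owner,
    )


def _autofluorescence_field(shape, rng) -> np.ndarray:
    """Smooth low-frequency random field, min-max normalized to [0, 1]."""
    from scipy.ndimage import gaussian_filter

    noise = rng.standard_normal(shape)
    smooth = gaussian_filter(noise, sigma=min(shape) / 8.0, mode="reflect")
    lo, hi = smooth.min(), smooth.max()
    if hi - lo < 1e-30:
        return np.zeros(shape)
    return (smooth - lo) / (hi - lo)


def degrade(
    truth: ImageStack, cfg: SimConfig, rng: np.random.Generator | None = None
) -> ImageStack:
    """Apply the measurement model to a ground-truth stack.

    Blur by the Gaussian PSF, add the autofluorescence background, sample
    the Poisson photon stage, add CCD read noise, clip at zero. Channel-wise
    and deterministic for a fixed (config, seed).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 1]))
    H = gaussian_psf(cfg.psf_sigma) if cfg.psf_sigma > 0 else None
    planes = []
    for p in truth.planes:
        blurred = apply_psf(p, H, boundary="reflect") if H is not None else p
        if cfg.autofluorescence_energy > 0:
            af = cfg.autofluorescence_energy * _autofluorescence_field(
                blurred.shape, rng
            )
            ideal = blurred + af
        else:
            ideal = blurred
        if cfg.photon_scale is not None and np.isfinite(cfg.photon_scale):
            scale = float(cfg.photon_scale)
            measured = rng.poisson(np.clip(ideal, 0, None) * scale) / scale
        else:
            measured = ideal
        if cfg.ccd_noise_var > 0:
            measured = measured + rng.normal(
                0.0, math.sqrt(cfg.ccd_noise_var), size=measured.shape
            )
        planes.append(np.clip(measured, 0.0, None))
    return ImageStack(
        planes=planes,
        channel_names=list(truth.channel_names),
        dtype_origin=truth.dtype_origin,
    )


def simulate_scene(cfg: SimConfig) -> SimScene:
    """Ground truth plus its degraded measurement, from one config + seed."""
    scene = simulate_population(cfg)
    scene.measured = degrade(scene.truth, cfg)
    return scene


#: Named scene presets. ``fullframe`` mirrors a full-frame three-channel
#: acquisition (800 x 800); ``tiny`` is a fast small scene for tests.
PRESETS: dict[str, dict] = {
    "tiny": dict(height=64, width=64, n_cells=3, cell_radius=11.0),
    "default": dict(height=256, width=256),
    "fullframe": dict(height=800, width=800),
}


def make_fixture(name: str, seed: int, out_dir: str | os.PathLike) -> SimScene:
    """Generate a preset scene and write it to disk.

    Writes ``truth.tif`` and ``measured.tif`` (16-bit), the compartment
    label masks (``mask_*.tif``, uint16), and the resolved config as
    ``config.yaml``. Regeneration with the same (preset, seed) is
    byte-identical.
    """
    import tifffile
    import yaml

    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    cfg = SimConfig(**PRESETS[name], seed=seed)
    scene = simulate_scene(cfg)
    out = os.fspath(out_dir)
    os.makedirs(out, exist_ok=True)
    write_image(scene.truth, os.path.join(out, "truth.tif"), bit_depth=16)
    write_image(scene.measured, os.path.join(out, "measured.tif"), bit_depth=16)
    for key, mask in scene.masks.items():
        tifffile.imwrite(
            os.path.join(out, f"mask_{key}.tif"), mask.astype(np.uint16)
        )
    with open(os.path.join(out, "config.yaml"), "w") as fh:
        yaml.safe_dump({"preset": name, **cfg.resolved()}, fh, sort_keys=True)
    return scene
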