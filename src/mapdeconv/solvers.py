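"""Iterative deconvolution engines: Richardson-Lucy, MAP-Hunt, and MAP-D.

All three share the Poisson measurement model g ~ Poisson(H * f) and a
multiplicative one-step-late fixed-point update. Writing
R_j = H_adj * (g / (H * f_j)) for the Richardson-Lucy ratio term:

    LR:        f_{j+1} = f_j R_j
    MAP-Hunt:  f_{j+1} = f_j R_j / (1 + lam (f_j - g))
    MAP-D:     f_{j+1} = f_j R_j / (1 + lam (f_j - E_hat_j))

MAP-Hunt and MAP-D minimize the penalized Poisson negative log-likelihood

    J(f) = sum_s [(H*f)_s - g_s ln (H*f)_s] + (lam/2) sum_s (f_s - E_hat_s)^2

which differ only in the prior mean E_hat: MAP-Hunt freezes it at the
measured image g, while MAP-D re-estimates it from the current iterate with
the kernel-regression estimator (see :mod:`mapdeconv.expectation`), updated
every iteration. With lam = 0 both reduce exactly to Richardson-Lucy.

Denominators are floored at a small eps rather than allowed to vanish; the
number of floored pixels per iteration is recorded in the trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .expectation import KernelConfig, estimate_expectation
from .io_formats import ImageStack
from .psf import PSFKernel, adjoint_psf, apply_psf, taper_edges

__all__ = [
    "DeconvParams",
    "IterationTrace",
    "forward_model",
    "lr_step",
    "maphunt_step",
    "mapd_step",
    "objective",
    "deconvolve",
    "METHODS",
]

METHODS = ("lr", "map_hunt", "map_d")


@dataclass
class DeconvParams:
    """Deconvolution parameters.

    lam: regularization weight lambda of the Gaussian prior (the prior
        variance tau^2 is absorbed into it). lam = 0 disables the prior.
    beta: kernel relaxation parameter for MAP-D, quoted on the conventional
        0-255 intensity scale (default 625 = 25^2); it is rescaled by
        ``intensity_scale**2`` to the [0, 1] working scale internally.
    window_radius: half-width of the kernel-regression window (4 -> the
        81-sample window).
    iterations: number of update steps; no early stopping.
    eps: numeric floor for the ratio and prior denominators.
    boundary: convolution boundary rule, "reflect" or "wrap".
    intensity_scale: full-scale intensity that beta's units refer to. Set
        to 1.0 if beta is already expressed on the working scale.
    """

    lam: float = 0.2
    beta: float = 625.0
    window_radius: int = 4
    iterations: int = 50
    eps: float = 1e-12
    boundary: str = "reflect"
    intensity_scale: float = 255.0

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not self.eps > 0:
            raise ValueError("eps must be > 0")

    @property
    def kernel_config(self) -> KernelConfig:
        """Kernel configuration with beta rescaled to the working scale."""
        return KernelConfig(
            beta=self.beta / self.intensity_scale**2,
            window_radius=self.window_radius,
        )


@dataclass
class IterationTrace:
    """Per-iteration diagnostics of one channel's deconvolution run."""

    objective: list[float] = field(default_factory=list)
    max_rel_change: list[float] = field(default_factory=list)
    floored_pixels: list[int] = field(default_factory=list)


def forward_model(
    f: np.ndarray, H: PSFKernel, boundary: str = "reflect"
) -> np.ndarray:
    """The Poisson mean of the measurement: the PSF-blurred image H * f."""
    return apply_psf(f, H, boundary=boundary)


def _ratio_term(f, g, H, H_adj, eps, boundary):
    """H_adj * (g / max(H*f, eps)); also counts floored denominator pixels."""
    m = apply_psf(f, H, boundary=boundary)
    floored = int(np.count_nonzero(m < eps))
    ratio = g / np.maximum(m, eps)
    return apply_psf(ratio, H_adj, boundary=boundary), floored


def _prior_denom(f, e_hat, lam, eps):
    """max(1 + lam (f - E_hat), eps) with a floored-pixel count."""
    d = 1.0 + lam * (f - e_hat)
    floored = int(np.count_nonzero(d < eps))
    return np.maximum(d, eps), floored


def lr_step(
    f_j: np.ndarray,
    g: np.ndarray,
    H: PSFKernel,
    H_adj: PSFKernel,
    eps: float = 1e-12,
    boundary: str = "reflect",
) -> np.ndarray:
    """One Richardson-Lucy update: f_{j+1} = f_j [H_adj * (g / (H * f_j))].

    Preserves nonnegativity; under a periodic boundary with g > 0 the total
    flux equals sum(g) after every step.
    """
    num, _ = _ratio_term(f_j, g, H, H_adj, eps, boundary)
    return f_j * num


def maphunt_step(
    f_j: np.ndarray,
    g: np.ndarray,
    H: PSFKernel,
    H_adj: PSFKernel,
    lam: float = 0.2,
    eps: float = 1e-12,
    boundary: str = "reflect",
) -> np.ndarray:
    """One MAP update with the static prior mean E_hat = g (Hunt's choice)."""
    num, _ = _ratio_term(f_j, g, H, H_adj, eps, boundary)
    den, _ = _prior_denom(f_j, g, lam, eps)
    return f_j * num / den


def mapd_step(
    f_j: np.ndarray,
    g: np.ndarray,
    H: PSFKernel,
    H_adj: PSFKernel,
    params: DeconvParams,
) -> np.ndarray:
    """One MAP-D update: the prior mean is re-estimated from f_j by kernel
    regression before the multiplicative step."""
    e_hat = estimate_expectation(f_j, params.kernel_config)
    num, _ = _ratio_term(f_j, g, H, H_adj, params.eps, params.boundary)
    den, _ = _prior_denom(f_j, e_hat, params.lam, params.eps)
    return f_j * num / den


def objective(
    f: np.ndarray,
    g: np.ndarray,
    H: PSFKernel,
    lam: float,
    E_hat: np.ndarray | None,
    eps: float = 1e-12,
    boundary: str = "reflect",
) -> float:
    """Penalized Poisson negative log-likelihood (up to a constant in g).

    sum_s [(H*f)_s - g_s ln max((H*f)_s, eps)] + (lam/2) sum_s (f_s - E_hat_s)^2
    """
    m = np.maximum(apply_psf(f, H, boundary=boundary), eps)
    data_term = float(np.sum(m - g * np.log(m)))
    if lam == 0 or E_hat is None:
        return data_term
    d = f - E_hat
    return data_term + 0.5 * lam * float(np.sum(d * d))


def deconvolve(
    stack: ImageStack,
    psfs: PSFKernel | list[PSFKernel],
    params: DeconvParams,
    method: str = "map_d",
) -> tuple[ImageStack, list[IterationTrace]]:
    """Deconvolve every channel of a stack with the chosen method.

    Each channel is processed independently with its own PSF (pass a single
    kernel to share it across channels): the measured plane is edge-tapered
    for border protection, the iteration starts from the tapered measurement,
    runs for exactly ``params.iterations`` multiplicative steps, and any
    residual negative values are clipped at the end.

    Returns the deconvolved stack and one :class:`IterationTrace` per
    channel (objective value, max relative change of the iterate, and count
    of eps-floored denominator pixels, per iteration).
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    if isinstance(psfs, PSFKernel):
        psfs = [psfs] * stack.n_channels
    if len(psfs) != stack.n_channels:
        raise ValueError(
            f"{stack.n_channels} channels but {len(psfs)} PSFs supplied"
        )

    out_planes: list[np.ndarray] = []
    traces: list[IterationTrace] = []
    for plane, H in zip(stack.planes, psfs):
        H_adj = adjoint_psf(H)
        g = taper_edges(plane, H)
        f = g.copy()
        trace = IterationTrace()
        for _ in range(params.iterations):
            if method == "map_d":
                e_hat = estimate_expectation(f, params.kernel_config)
            elif method == "map_hunt":
                e_hat = g
            else:
                e_hat = None
            num, fl_ratio = _ratio_term(
                f, g, H, H_adj, params.eps, params.boundary
            )
            if method == "lr" or params.lam == 0:
                f_new = f * num
                fl_prior = 0
            else:
                den, fl_prior = _prior_denom(f, e_hat, params.lam, params.eps)
                f_new = f * num / den
            scale = max(float(np.max(np.abs(f))), params.eps)
            trace.max_rel_change.append(
                float(np.max(np.abs(f_new - f))) / scale
            )
            trace.floored_pixels.append(fl_ratio + fl_prior)
            lam = 0.0 if method == "lr" else params.lam
            trace.objective.append(
                objective(
                    f_new, g, H, lam, e_hat, params.eps, params.boundary
                )
            )
            f = f_new
        out_planes.append(np.clip(f, 0.0, None))
        traces.append(trace)

    result = ImageStack(
        planes=out_planes,
        channel_names=list(stack.channel_names),
        dtype_origin=stack.dtype_origin,
    )
    return result, traces
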