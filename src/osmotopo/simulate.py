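"""Synthetic impregnation data: images, kinetics and shrinkage.

The generator emulates the three data streams an osmotic-impregnation
study produces, with the statistical structure the downstream analysis
assumes:

* **Images** — boundary-driven Fickian uptake into a square cross
  section (∂C/∂t = D∇²C, Dirichlet boundary C = C_b, initial C = 0),
  integrated by explicit finite differences under the stability bound
  dt = 0.2·dx²/D, rendered as intensity = 255·(1 − C) so stained
  (high-concentration) tissue is dark, plus a smoothed Gaussian texture
  field and per-pixel noise.
* **Kinetics** — Peleg-shaped uptake curves obtained by pushing the
  shrinkage-corrected Fourier number τ*(t) = ∫ D/L(s)² ds through the
  diagonal cube series Ψ(τ*), rescaled by Ψ(0) = 8/15 so Y(0) = 0
  exactly, with optional multiplicative noise.
* **Shrinkage** — monotone exponential decay of the dimensionless
  volume to a plateau: V/V0(t) = v_f + (1 − v_f)·exp(−r·t).

A single :class:`numpy.random.Generator` seeded from ``config.seed``
drives everything; sub-streams for texture and pixel noise are split
deterministically, so identical configs give bit-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .diffusivity import psi_model
from .ecc import GrayImage
from .kinetics import KineticSeries, ShrinkageSeries

__all__ = [
    "SimulationConfig",
    "generate_impregnation_images",
    "generate_kinetics",
    "generate_shrinkage",
]

#: Cube half-edge of the physical study design, metres.
DEFAULT_L0 = 0.00609

#: Courant factor for the explicit diffusion step; 0.2 < 1/4 keeps FTCS
#: stable in 2D and enforces the discrete maximum principle.
_COURANT = 0.2


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generators.

    Defaults reflect the physical experiment this package models:
    apple cubes of half-edge ``L0`` = 6.09 mm impregnated for 810 min
    (48 600 s) with effective diffusivities of order 1e-10 m²/s, and a
    dimensionless volume shrinking to roughly 0.7 of the fresh value.

    Parameters
    ----------
    D_true : float
        Effective diffusivity, m²/s.
    L0 : float
        Characteristic half-length of the cube, m.
    grid_n : int
        Pixels per side of the simulated cross-section (≥ 16).
    t_samples : array-like
        Sampling times in seconds, strictly increasing, nonnegative.
    boundary_value : float
        Dirichlet boundary concentration (dimensionless), default 1.
    noise_sigma : float
        Per-pixel Gaussian noise std, gray levels.
    texture_scale : float
        Correlation length of the Gaussian texture field, pixels.
    texture_amplitude : float
        Std of the smoothed texture field, gray levels.
    shrink_final : float
        Asymptotic V/V0, in (0, 1].
    shrink_rate : float
        Shrinkage rate constant, 1/s.
    kinetic_noise_frac : float
        Relative (multiplicative) noise std on kinetic values.
    seed : int
        RNG seed; fixes every random draw.
    """

    D_true: float = 2.0e-10
    L0: float = DEFAULT_L0
    grid_n: int = 128
    t_samples: tuple[float, ...] = tuple(1800.0 * k for k in range(28))
    boundary_value: float = 1.0
    noise_sigma: float = 2.0
    texture_scale: float = 2.0
    texture_amplitude: float = 20.0
    shrink_final: float = 0.7
    shrink_rate: float = 2.0e-4
    kinetic_noise_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.D_true <= 0:
            raise ValueError("D_true must be positive")
        if not 0 < self.shrink_final <= 1:
            raise ValueError("shrink_final must lie in (0, 1]")
        if self.grid_n < 16:
            raise ValueError("grid_n must be at least 16")
        t = np.asarray(self.t_samples, dtype=float)
        if t.size == 0 or t[0] < 0 or (t.size > 1 and not np.all(np.diff(t) > 0)):
            raise ValueError("t_samples must be strictly increasing and nonnegative")
        object.__setattr__(self, "t_samples", tuple(float(x) for x in t))
        if self.L0 <= 0 or self.boundary_value <= 0:
            raise ValueError("L0 and boundary_value must be positive")
        if self.noise_sigma < 0 or self.texture_amplitude < 0 or self.kinetic_noise_frac < 0:
            raise ValueError("noise amplitudes must be nonnegative")

    def rng_streams(self) -> tuple[np.random.Generator, np.random.Generator]:
        """Deterministically split the (texture, pixel-noise) streams."""
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(2)
        return tuple(np.random.default_rng(c) for c in children)  # type: ignore[return-value]


def _diffusion_fields(config: SimulationConfig) -> list[np.ndarray]:
    """Solve ∂C/∂t = D∇²C on the square by FTCS at the sampling times.

    The domain is the full cross-section of side 2·L0; the boundary ring
    of pixels is held at ``boundary_value``.  The step dt = 0.2·dx²/D
    satisfies the 2D stability bound dt ≤ dx²/(4D), so concentrations
    remain in [0, boundary_value] (discrete maximum principle).
    """
    n = config.grid_n
    dx = 2.0 * config.L0 / (n - 1)  # nodes at 0 .. 2·L0 inclusive
    dt = _COURANT * dx**2 / config.D_true
    if config.D_true * dt / dx**2 > 0.25:
        raise ValueError("unstable FTCS configuration")

    def step(c: np.ndarray, dt_step: float) -> np.ndarray:
        a = config.D_true * dt_step / dx**2
        lap = (
            np.roll(c, 1, 0) + np.roll(c, -1, 0) + np.roll(c, 1, 1) + np.roll(c, -1, 1)
            - 4.0 * c
        )
        c = c + a * lap
        c[0, :] = c[-1, :] = c[:, 0] = c[:, -1] = config.boundary_value
        return c

    c = np.zeros((n, n))
    c[0, :] = c[-1, :] = c[:, 0] = c[:, -1] = config.boundary_value
    fields = []
    t_now = 0.0
    for t_target in config.t_samples:
        remaining = t_target - t_now
        n_full = int(remaining / dt)
        for _ in range(n_full):
            c = step(c, dt)
        t_rem = remaining - n_full * dt
        if t_rem > 1e-9 * dt:
            c = step(c, t_rem)  # shorter final step, still stable
        t_now = t_target
        fields.append(c.copy())
    return fields


def _texture_field(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Smoothed Gaussian texture, normalized to ``texture_amplitude`` std."""
    white = rng.standard_normal((config.grid_n, config.grid_n))
    smooth = ndimage.gaussian_filter(white, sigma=config.texture_scale, mode="reflect")
    std = smooth.std()
    if std == 0:
        return np.zeros_like(smooth)
    return smooth / std * config.texture_amplitude


def generate_impregnation_images(config: SimulationConfig) -> list[GrayImage]:
    """Render the staining field at every sampling time.

    Intensity is ``round(255·(1 − C))`` clipped to [0, 255]: untouched
    tissue is bright, fully impregnated tissue dark.  One frozen texture
    field (tissue structure does not change between shots) plus
    independent per-frame pixel noise are added before rounding.  The
    mask is all-foreground.
    """
    rng_texture, rng_pixel = config.rng_streams()
    texture = _texture_field(config, rng_texture)
    images = []
    for c in _diffusion_fields(config):
        intensity = 255.0 * (1.0 - c) + texture
        if config.noise_sigma > 0:
            intensity = intensity + rng_pixel.normal(
                0.0, config.noise_sigma, size=c.shape
            )
        pixels = np.clip(np.rint(intensity), 0, 255).astype(np.int64)
        images.append(GrayImage(pixels=pixels))
    return images


def generate_shrinkage(config: SimulationConfig) -> ShrinkageSeries:
    """V/V0(t) = v_f + (1 − v_f)·exp(−r·t) evaluated at the sampling times."""
    t = np.asarray(config.t_samples)
    v = config.shrink_final + (1.0 - config.shrink_final) * np.exp(
        -config.shrink_rate * t
    )
    return ShrinkageSeries(times=t, v_ratio=v)


def tau_star_exact(config: SimulationConfig, times: np.ndarray) -> np.ndarray:
    """τ*(t) = ∫₀ᵗ D/L(s)² ds along the exact exponential shrinkage path.

    Evaluated by dense trapezoidal quadrature (the integrand is smooth);
    with ``shrink_final = 1`` this reduces to D·t/L0².
    """
    times = np.asarray(times, dtype=float)
    if config.shrink_final == 1.0:
        return config.D_true * times / config.L0**2
    t_hi = float(times.max()) if times.size else 0.0
    t_dense = np.unique(np.concatenate([np.linspace(0.0, t_hi, 20001), times]))
    v = config.shrink_final + (1.0 - config.shrink_final) * np.exp(
        -config.shrink_rate * t_dense
    )
    integrand = config.D_true / (config.L0 * v ** (1.0 / 3.0)) ** 2
    from scipy.integrate import cumulative_trapezoid

    tau_dense = cumulative_trapezoid(integrand, t_dense, initial=0.0)
    return np.interp(times, t_dense, tau_dense)


def generate_kinetics(
    config: SimulationConfig, Y_e: float, substance_label: str
) -> KineticSeries:
    """Forward-model a Peleg-shaped uptake curve from the diffusion model.

    Y(t) = Y_e·(1 − Ψ(τ*(t))/Ψ(0)): the diagonal cube series evaluated
    along the shrinkage-corrected Fourier number, rescaled by
    Ψ(0) = 8/15 so that Y(0) = 0 exactly (the printed series does not
    sum to 1 at τ* = 0).  Multiplicative Gaussian noise of relative std
    ``kinetic_noise_frac`` is applied when requested.
    """
    if Y_e <= 0:
        raise ValueError("Y_e must be positive")
    # noise stream keyed by (seed, substance) so substances decorrelate
    label_key = zlib.crc32(substance_label.encode())
    rng_kin = np.random.default_rng(np.random.SeedSequence([config.seed, 2, label_key]))
    t = np.asarray(config.t_samples)
    tau = tau_star_exact(config, t)
    psi = np.asarray(psi_model(tau))
    psi0 = psi_model(0.0)
    y = Y_e * (1.0 - psi / psi0)
    if config.kinetic_noise_frac > 0:
        y = y * (1.0 + rng_kin.normal(0.0, config.kinetic_noise_frac, size=y.shape))
        y = np.clip(y, 0.0, None)
        if t[0] == 0:
            y[0] = 0.0
    return KineticSeries(substance=substance_label, times=t, values=y)
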