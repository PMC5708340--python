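"""Seeded synthetic-data generators.

Emulates the statistical structure of the experimental data so every
analysis stage is testable without instrument files: Hertzian and
Hertz-then-linear force curves with cantilever-deflection coupling and
additive Gaussian force noise, hexagonal-lattice topographs, and Gaussian
particle-size populations.  Every generator is a pure function of its
arguments including the seed.

Defaults mirror the measurement conditions: cantilever 350 pN/nm with a
20 nm tip, sample Poisson coefficient 0.5, Young's modulus 0.59 MPa,
particle spring constant 20 pN/nm, force capped at 1 nN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .curves import CantileverSpec, ForceCurve
from .imaging import Topograph
from .mechanics import hertz_force

__all__ = [
    "GeneratorConfig",
    "DEFAULT_CANTILEVER",
    "gen_hertz_curve",
    "gen_composite_curve",
    "gen_lattice_topograph",
    "gen_particle_population",
]

#: Bruker-style probe: k = 0.35 N/m = 350 pN/nm, R_tip = 20 nm,
#: silicon nitride tip (130 GPa, nu 0.3).
DEFAULT_CANTILEVER = CantileverSpec(k_cantilever=350.0, R_tip=20.0, E_tip=1.3e5, nu_tip=0.3)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the force-curve generators.

    ``noise_sd`` is additive Gaussian force noise (pN); ``n_points`` the
    number of post-contact samples; ``z_0`` the contact distance (nm);
    ``regime_switch_force`` the force (pN) at which the composite curve
    hands over from Hertzian contact to linear particle compression;
    ``max_force`` the truncation force (1 nN as in the measurements);
    ``baseline_span`` the pre-contact approach length (nm).
    """

    seed: int = 0
    noise_sd: float = 2.0
    n_points: int = 400
    z_0: float = 50.0
    regime_switch_force: float = 50.0
    max_force: float = 1000.0
    baseline_span: float = 20.0
    n_baseline: int = 120

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_points < 10 or self.n_baseline < 5:
            raise ValueError("need >= 10 contact and >= 5 baseline samples")
        if not 0 < self.regime_switch_force <= self.max_force:
            raise ValueError("regime_switch_force must lie in (0, max_force]")
        if self.baseline_span <= 0 or self.z_0 < self.baseline_span:
            raise ValueError("need z_0 >= baseline_span > 0")


def _assemble_curve(
    cfg: GeneratorConfig,
    d: np.ndarray,
    F: np.ndarray,
    cantilever: CantileverSpec,
    curve_id: str,
) -> ForceCurve:
    """Map (d, F) to piezo space, prepend baseline, add noise."""
    z_contact = cfg.z_0 + d + F / cantilever.k_cantilever
    z_base = np.linspace(cfg.z_0 - cfg.baseline_span, cfg.z_0, cfg.n_baseline, endpoint=False)
    z = np.concatenate([z_base, z_contact])
    f = np.concatenate([np.zeros(cfg.n_baseline), F])
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        f = f + rng.normal(0.0, cfg.noise_sd, size=f.size)
    return ForceCurve(z, f, curve_id=curve_id, cantilever=cantilever)


def gen_hertz_curve(
    cfg: GeneratorConfig,
    E: float = 0.59,
    nu: float = 0.5,
    cantilever: CantileverSpec = DEFAULT_CANTILEVER,
) -> ForceCurve:
    """Pure Hertzian approach curve.

    Builds force on a uniform indentation grid via the Hertz relation,
    maps to piezo displacement ``z_p = z_0 + d + F/k_cantilever``,
    prepends a zero-force baseline, adds Gaussian force noise and
    truncates at ``max_force``.
    """
    c = hertz_force(1.0, E, nu, cantilever.R_tip)
    d_max = (cfg.max_force / c) ** (2.0 / 3.0)
    d = np.linspace(0.0, d_max, cfg.n_points)
    F = hertz_force(d, E, nu, cantilever.R_tip)
    return _assemble_curve(cfg, d, F, cantilever, f"hertz_E{E:g}_seed{cfg.seed}")


def gen_composite_curve(
    cfg: GeneratorConfig,
    E: float = 0.59,
    k_CB: float = 20.0,
    nu: float = 0.5,
    cantilever: CantileverSpec = DEFAULT_CANTILEVER,
) -> ForceCurve:
    """Hertz-then-linear approach curve.

    Hertzian contact up to ``regime_switch_force``, then linear particle
    compression of stiffness ``k_CB`` (continuous at the switch), the
    regime sequence seen on shell-bounded particles: an initial nonlinear
    tip-indentation response followed by quasi-linear whole-particle
    deformation.  In piezo space the linear branch shows the series slope
    ``k_cantilever * k_CB / (k_cantilever + k_CB)``.
    """
    if k_CB <= 0:
        raise ValueError("k_CB must be > 0")
    c = hertz_force(1.0, E, nu, cantilever.R_tip)
    f_sw = min(cfg.regime_switch_force, cfg.max_force)
    d_sw = (f_sw / c) ** (2.0 / 3.0)
    d_max = d_sw + max(cfg.max_force - f_sw, 0.0) / k_CB
    d = np.linspace(0.0, d_max, cfg.n_points)
    F = np.where(d <= d_sw, hertz_force(d, E, nu, cantilever.R_tip), f_sw + k_CB * (d - d_sw))
    return _assemble_curve(cfg, d, F, cantilever, f"composite_E{E:g}_k{k_CB:g}_seed{cfg.seed}")


def gen_lattice_topograph(
    spacing: float,
    amplitude: float,
    pixel_size: float,
    size: int,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Topograph:
    """Hexagonal lattice of Gaussian bumps, as a shell-protein array.

    Bump centers sit on a hexagonal lattice of the given center-to-center
    ``spacing`` (nm), with one lattice row through the grid center so a
    horizontal mid-line profile crosses bump centers.  Gaussian height
    noise of SD ``noise_sd`` is added.
    """
    if spacing <= 2.0 * pixel_size:
        raise ValueError("Nyquist violation: spacing must exceed 2 x pixel_size")
    if size < 8:
        raise ValueError("size must be >= 8 pixels")
    extent = (size - 1) * pixel_size
    coords = np.arange(size) * pixel_size
    X, Y = np.meshgrid(coords, coords)
    sigma = spacing / 5.0
    row_step = spacing * np.sqrt(3.0) / 2.0
    cy0, cx0 = extent / 2.0, extent / 2.0
    heights = np.zeros((size, size))
    j_range = int(np.ceil(extent / row_step)) + 1
    i_range = int(np.ceil(extent / spacing)) + 1
    for j in range(-j_range, j_range + 1):
        cy = cy0 + j * row_step
        if not -3 * sigma <= cy <= extent + 3 * sigma:
            continue
        x_off = (j % 2) * spacing / 2.0
        for i in range(-i_range, i_range + 1):
            cx = cx0 + x_off + i * spacing
            if not -3 * sigma <= cx <= extent + 3 * sigma:
                continue
            heights += amplitude * np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * sigma**2))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        heights = heights + rng.normal(0.0, noise_sd, size=heights.shape)
    frame_id = f"lattice_s{spacing:g}_a{amplitude:g}_seed{seed}"
    return Topograph(heights, pixel_size, frame_id=frame_id)


def gen_particle_population(mean: float, sd: float, n: int, seed: int = 0) -> np.ndarray:
    """Gaussian particle-size draws truncated to mean +/- 4 SD."""
    if sd < 0 or n < 1:
        raise ValueError("need sd >= 0 and n >= 1")
    if sd == 0:
        return np.full(n, float(mean))
    rng = np.random.default_rng(seed)
    dist = stats.truncnorm(-4.0, 4.0, loc=mean, scale=sd)
    return dist.rvs(size=n, random_state=rng)
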