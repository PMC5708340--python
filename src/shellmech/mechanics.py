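"""Mechanical models for nanoindentation of protein shells.

Three standard models connect an approach curve to particle mechanics:

1. **Springs in series** — on the linear part of the force–displacement
   curve the cantilever (``k_cantilever``) and particle (``k_p``) deform
   together, so the measured slope ``k_total`` satisfies
   ``1/k_total = 1/k_cantilever + 1/k_p``, i.e.
   ``k_p = k_cantilever * k_total / (k_cantilever - k_total)``.

2. **Thin-shell elasticity** — for a spherical shell of radius ``R`` and
   wall thickness ``h``, the shell Young's modulus is
   ``E_S = alpha * k_p * R / h**2`` with geometry factor ``alpha``
   (taken as 1 for quasi-spherical capsids).

3. **Hertzian contact** — for a paraboloid tip of radius ``R_tip`` on a
   soft half-space, ``F = (4/3) * E/(1 - nu**2) * sqrt(R_tip) * d**1.5``;
   fitted on the shallow-indentation window this yields ``E_H``.

Units: nm, pN, MPa throughout (1 pN/nm^2 = 1 MPa).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize

from .curves import CantileverSpec, ForceCurve, IndentationCurve

__all__ = [
    "ShellSpec",
    "LinearFitResult",
    "HertzFitResult",
    "BracketResult",
    "StiffnessFitError",
    "HertzFitError",
    "CARBOXYSOME_SHELL",
    "P22_SHELL",
    "series_spring",
    "series_total",
    "fit_linear_stiffness",
    "thin_shell_modulus",
    "hertz_force",
    "fit_hertz",
    "simulate_hertz_curve",
    "bracket_modulus",
    "aggregate_particle_fits",
]


class StiffnessFitError(RuntimeError):
    """Linear (series-spring) fit failed or is invalid."""


class HertzFitError(RuntimeError):
    """Hertz fit failed to converge or produced a non-physical modulus."""


@dataclass(frozen=True)
class ShellSpec:
    """Geometry of a thin spherical protein shell.

    ``R`` particle radius (nm), ``h`` wall thickness (nm), ``alpha``
    the geometry-dependent proportionality factor of the thin-shell
    relation, ``nu_sample`` the sample Poisson coefficient.
    """

    R: float
    h: float
    alpha: float = 1.0
    nu_sample: float = 0.5

    def __post_init__(self) -> None:
        if not (self.R > self.h > 0):
            raise ValueError("need R > h > 0")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not 0.0 <= self.nu_sample <= 0.5:
            raise ValueError("nu_sample must lie in [0, 0.5]")


#: Beta-carboxysome defaults: R ~ 75 nm, single-hexamer shell ~ 4.5 nm thick.
CARBOXYSOME_SHELL = ShellSpec(R=75.0, h=4.5, alpha=1.0, nu_sample=0.5)
#: Bacteriophage P22 comparison shell.
P22_SHELL = ShellSpec(R=30.0, h=7.5, alpha=1.0, nu_sample=0.5)


@dataclass(frozen=True)
class LinearFitResult:
    k_total: float            # measured slope on the particle, pN/nm
    k_particle: float         # series-corrected particle stiffness, pN/nm
    window: Tuple[float, float]  # force window used, pN
    r_squared: float
    n_points: int
    curve_id: str = ""
    E_shell: Optional[float] = None  # MPa, filled by thin-shell step


@dataclass(frozen=True)
class HertzFitResult:
    E_hertz: float            # MPa
    z_0_refined: float        # nm
    window: Tuple[float, float]  # indentation window, nm
    rms_residual: float       # pN
    n_points: int
    curve_id: str = ""


@dataclass(frozen=True)
class BracketResult:
    """Adjacent grid moduli whose simulated curves bound an experiment."""

    E_low: Optional[float]
    E_high: Optional[float]
    open_low: bool = False
    open_high: bool = False
    residuals: Optional[Tuple[float, ...]] = None  # signed, per grid modulus

    @property
    def is_open(self) -> bool:
        return self.open_low or self.open_high


# ---------------------------------------------------------------------------
# Springs in series
# ---------------------------------------------------------------------------

def series_spring(k_total: float, k_cantilever: float) -> float:
    """Particle stiffness from the measured series slope."""
    if not 0 < k_total < k_cantilever:
        raise StiffnessFitError(
            "particle stiffer than cantilever — series model invalid"
            if k_total >= k_cantilever
            else "non-positive slope"
        )
    return k_cantilever * k_total / (k_cantilever - k_total)


def series_total(k_particle: float, k_cantilever: float) -> float:
    """Forward series combination (slope observed for a given particle)."""
    return k_cantilever * k_particle / (k_cantilever + k_particle)


def fit_linear_stiffness(
    curve: ForceCurve,
    cantilever: Optional[CantileverSpec] = None,
    force_window: Tuple[float, float] = (50.0, 150.0),
) -> LinearFitResult:
    """Fit the series-spring (linear) model on a force window of the curve.

    ``k_total`` is the least-squares slope of F vs z_p restricted to
    samples with force inside ``force_window`` (default 50–150 pN, the
    quasi-linear particle-compression regime); the particle spring constant
    follows from the series inversion.
    """
    cantilever = cantilever or curve.cantilever
    if cantilever is None:
        raise ValueError("no cantilever spec available")
    lo, hi = force_window
    if not lo < hi:
        raise ValueError("force_window must be ordered (low, high)")
    mask = (curve.F >= lo) & (curve.F <= hi)
    if mask.sum() < 5:
        raise StiffnessFitError(
            f"too few points ({int(mask.sum())}) inside force window {force_window}"
        )
    z, f = curve.z_p[mask], curve.F[mask]
    slope, intercept = np.polyfit(z, f, 1)
    pred = slope * z + intercept
    ss_res = float(np.sum((f - pred) ** 2))
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    k_particle = series_spring(float(slope), cantilever.k_cantilever)
    return LinearFitResult(
        k_total=float(slope),
        k_particle=k_particle,
        window=(lo, hi),
        r_squared=r2,
        n_points=int(mask.sum()),
        curve_id=curve.curve_id,
    )


# ---------------------------------------------------------------------------
# Thin shell
# ---------------------------------------------------------------------------

def thin_shell_modulus(k_particle: float, shell: ShellSpec) -> float:
    """Thin-shell Young's modulus E_S = alpha * k * R / h**2 in MPa."""
    if k_particle <= 0:
        raise ValueError("k_particle must be > 0")
    return shell.alpha * k_particle * shell.R / shell.h**2


# ---------------------------------------------------------------------------
# Hertzian contact
# ---------------------------------------------------------------------------

def hertz_force(
    d: Union[float, np.ndarray], E: float, nu: float, R_tip: float
) -> Union[float, np.ndarray]:
    """Rigid-tip Hertz force (pN) at indentation ``d`` (nm), ``E`` in MPa."""
    d = np.asarray(d, dtype=float)
    out = (4.0 / 3.0) * (E / (1.0 - nu**2)) * np.sqrt(R_tip) * d**1.5
    return float(out) if out.ndim == 0 else out


def fit_hertz(
    ind: IndentationCurve,
    cantilever: CantileverSpec,
    shell: ShellSpec = CARBOXYSOME_SHELL,
    depth_window: Tuple[float, float] = (0.0, 10.0),
    refine_z0: bool = True,
) -> HertzFitResult:
    """Least-squares Hertz fit on an indentation window.

    Fits ``F = (4/3) E/(1-nu^2) sqrt(R_tip) d^1.5`` over ``depth_window``
    (default 0–10 nm, the shallow regime where half-space contact holds).
    With ``refine_z0`` the contact distance is co-fitted as a shift
    ``delta`` on the indentation axis (``d -> d - delta``), the dominant
    nuisance parameter in shallow-indentation fits.
    """
    lo, hi = depth_window
    if not lo < hi:
        raise ValueError("depth_window must be ordered (low, high)")
    mask = (ind.d >= lo) & (ind.d <= hi)
    n = int(mask.sum())
    if n < 8:
        raise HertzFitError(f"insufficient support: {n} samples inside window {depth_window}")
    d, f = ind.d[mask], ind.F[mask]
    nu = shell.nu_sample
    pref = (4.0 / 3.0) / (1.0 - nu**2) * np.sqrt(cantilever.R_tip)

    deep = d > max(0.25 * min(hi, float(d.max())), 1e-3)
    if not np.any(deep) or np.max(f[deep]) <= 0:
        raise HertzFitError("insufficient support: no positive force at depth")
    E0 = float(np.median(f[deep] / (pref * d[deep] ** 1.5)))
    if not np.isfinite(E0) or E0 <= 0:
        E0 = 1.0

    params = Parameters()
    params.add("E", value=E0, min=1e-9)
    params.add("delta", value=0.0, min=-5.0, max=5.0, vary=refine_z0)

    def residual(p):
        d_eff = np.maximum(d - p["delta"].value, 0.0)
        return pref * p["E"].value * d_eff**1.5 - f

    out = minimize(residual, params, method="leastsq")
    if not out.success:
        raise HertzFitError(f"Hertz fit did not converge: {out.message}")
    E_fit = float(out.params["E"].value)
    delta = float(out.params["delta"].value)
    if E_fit <= 0 or not np.isfinite(E_fit):
        raise HertzFitError(f"non-physical modulus {E_fit}")
    rms = float(np.sqrt(np.mean(out.residual**2)))
    return HertzFitResult(
        E_hertz=E_fit,
        z_0_refined=ind.z_0 + delta,
        window=(lo, hi),
        rms_residual=rms,
        n_points=n,
        curve_id=ind.source,
    )


def simulate_hertz_curve(
    E_sample: float,
    nu_sample: float,
    cantilever: CantileverSpec,
    d_grid: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray]:
    """Forward Hertz simulation with the two-material reduced modulus.

    ``1/E* = (1 - nu_s^2)/E_s + (1 - nu_t^2)/E_t`` and
    ``F = (4/3) E* sqrt(R_tip) d^1.5``.  For a stiff tip
    (E_t ~ 130 GPa) this is indistinguishable from the rigid-tip formula
    for soft biological samples.
    """
    d = np.asarray(d_grid, dtype=float)
    if np.any(d < 0):
        raise ValueError("indentation grid must be non-negative")
    if E_sample <= 0:
        raise ValueError("E_sample must be > 0")
    inv_estar = (1.0 - nu_sample**2) / E_sample + (
        1.0 - cantilever.nu_tip**2
    ) / cantilever.E_tip
    F = (4.0 / 3.0) / inv_estar * np.sqrt(cantilever.R_tip) * d**1.5
    return d, F


def bracket_modulus(
    ind: IndentationCurve,
    cantilever: CantileverSpec,
    nu_sample: float,
    E_grid: Sequence[float],
    depth_window: Optional[Tuple[float, float]] = None,
) -> BracketResult:
    """Bound an experimental curve between simulated Hertz curves.

    Simulated curves at each grid modulus are compared with the
    experimental curve over the shared indentation range by the
    trapezoid-integrated signed residual ``∫ (F_exp - F_sim) dd``; since
    the simulated force is strictly increasing in E at every depth, the
    residual decreases monotonically along the grid and the sign change
    identifies the adjacent bounding pair.  An experimental curve exactly
    on a grid modulus brackets to (that modulus, next higher).  Curves
    softer than the lowest or stiffer than the highest grid modulus are
    flagged as open brackets.
    """
    E_grid = list(E_grid)
    if len(E_grid) < 2:
        raise ValueError("E_grid needs at least 2 moduli")
    if any(b <= a for a, b in zip(E_grid, E_grid[1:])):
        raise ValueError("E_grid must be sorted strictly ascending")
    if depth_window is not None:
        lo, hi = depth_window
        mask = (ind.d >= lo) & (ind.d <= hi)
    else:
        mask = np.ones(len(ind), dtype=bool)
    d, f = ind.d[mask], ind.F[mask]
    if d.size < 2:
        raise ValueError("too few samples in the comparison range")

    resid = []
    for E in E_grid:
        _, f_sim = simulate_hertz_curve(E, nu_sample, cantilever, d)
        resid.append(float(np.trapezoid(f - f_sim, d)))

    if resid[0] < 0:
        return BracketResult(None, E_grid[0], open_low=True, residuals=tuple(resid))
    for i in range(len(E_grid) - 1):
        if resid[i] >= 0 > resid[i + 1]:
            return BracketResult(E_grid[i], E_grid[i + 1], residuals=tuple(resid))
    return BracketResult(E_grid[-1], None, open_high=True, residuals=tuple(resid))


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def aggregate_particle_fits(results: Sequence[dict]) -> pd.DataFrame:
    """Mean, sample SD and n per quantity over per-particle fit records.

    ``results`` is a sequence of mappings quantity -> value (non-numeric
    entries are ignored).  SD uses the n-1 denominator; a quantity with a
    single observation reports SD 0 and is flagged ``single_observation``.
    """
    if len(results) == 0:
        raise ValueError("no results to aggregate")
    frame = pd.DataFrame(list(results))
    num = frame.select_dtypes(include=[np.number])
    rows = []
    for col in num.columns:
        vals = num[col].dropna()
        n = int(vals.size)
        if n == 0:
            continue
        sd = float(vals.std(ddof=1)) if n > 1 else 0.0
        rows.append(
            {
                "quantity": col,
                "mean": float(vals.mean()),
                "sd": sd,
                "n": n,
                "single_observation": n == 1,
            }
        )
    return pd.DataFrame(rows).set_index("quantity")
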