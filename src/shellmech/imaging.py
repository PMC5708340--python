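"""Topograph and cross-section profile analysis.

Measurements read off AFM/TEM height data: line profiles across a 2-D
height grid, lattice periodicity of shell hexamers or Rubisco arrays,
particle heights over a local background, and layered shell features
(wall thickness and the low-density gap between shell and cargo).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Tuple, Union

import numpy as np
from lmfit.models import ConstantModel, GaussianModel
from scipy import ndimage, signal

__all__ = [
    "Topograph",
    "Profile",
    "AperiodicProfileError",
    "ProfileFeatureError",
    "read_topograph",
    "write_topograph",
    "extract_profile",
    "estimate_periodicity",
    "particle_height",
    "diameter_from_vertices",
    "shell_profile_features",
]

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ~2.3548


class AperiodicProfileError(RuntimeError):
    """No significant periodicity found in a profile."""


class ProfileFeatureError(RuntimeError):
    """Profile lacks the peaks needed for a layer measurement."""


@dataclass(frozen=True)
class Topograph:
    """2-D height grid (nm) with physical pixel size (nm/pixel).

    Heights sit at pixel centers; physical coordinates are
    ``index * pixel_size`` with (x, y) = (column, row), 0-based.
    """

    heights: np.ndarray
    pixel_size: float
    frame_id: str = ""

    def __post_init__(self) -> None:
        h = np.asarray(self.heights, dtype=float)
        object.__setattr__(self, "heights", h)
        if h.ndim != 2 or min(h.shape) < 8:
            raise ValueError("heights must be a 2-D grid of at least 8x8 pixels")
        if not np.all(np.isfinite(h)):
            raise ValueError("non-finite heights")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def extent(self) -> Tuple[float, float]:
        """Physical (x, y) extent in nm, pixel centers."""
        ny, nx = self.heights.shape
        return (nx - 1) * self.pixel_size, (ny - 1) * self.pixel_size


@dataclass(frozen=True)
class Profile:
    """Height cross-section: monotone distance (nm) vs height (nm)."""

    distance: np.ndarray
    height: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distance, dtype=float)
        h = np.asarray(self.height, dtype=float)
        object.__setattr__(self, "distance", d)
        object.__setattr__(self, "height", h)
        if d.size != h.size or d.ndim != 1 or d.size < 2:
            raise ValueError("distance and height must be equal-length 1-D arrays (>= 2)")
        if not np.all(np.diff(d) > 0):
            raise ValueError("distance must strictly increase")


# ---------------------------------------------------------------------------
# I/O: plain-text matrix with '#key=value' header
# ---------------------------------------------------------------------------

def read_topograph(path: Union[str, Path]) -> Topograph:
    header: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if line.startswith("#") and "=" in line:
            key, _, val = line.lstrip("#").partition("=")
            header[key.strip()] = val.strip()
        elif line.strip() and not line.startswith("#"):
            break
    if "pixel_size" not in header:
        raise ValueError(f"{path}: missing '#pixel_size=' header")
    heights = np.loadtxt(path, comments="#")
    return Topograph(heights, float(header["pixel_size"]), frame_id=header.get("frame_id", ""))


def write_topograph(topo: Topograph, path: Union[str, Path]) -> None:
    header = f"pixel_size={topo.pixel_size:.9g}"
    if topo.frame_id:
        header += f"\nframe_id={topo.frame_id}"
    np.savetxt(path, topo.heights, fmt="%.6g", header=header)


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

def extract_profile(
    topo: Topograph, p0: Tuple[float, float], p1: Tuple[float, float]
) -> Profile:
    """Bilinear line profile between two (x, y) points in nm.

    Samples at steps no coarser than half a pixel; distance starts at 0.
    """
    ext_x, ext_y = topo.extent
    for x, y in (p0, p1):
        if not (0 <= x <= ext_x and 0 <= y <= ext_y):
            raise ValueError(f"endpoint ({x}, {y}) nm outside grid extent ({ext_x}, {ext_y})")
    length = float(np.hypot(p1[0] - p0[0], p1[1] - p0[1]))
    n = max(int(np.ceil(length / (topo.pixel_size / 2.0))) + 1, 2)
    t = np.linspace(0.0, 1.0, n)
    xs = (p0[0] + t * (p1[0] - p0[0])) / topo.pixel_size  # column coords
    ys = (p0[1] + t * (p1[1] - p0[1])) / topo.pixel_size  # row coords
    values = ndimage.map_coordinates(topo.heights, [ys, xs], order=1, mode="nearest")
    return Profile(distance=t * length, height=values)


def estimate_periodicity(profile: Profile, threshold_multiple: float = 3.0) -> float:
    """Dominant spacing (nm) of a quasi-periodic profile.

    The profile is linearly detrended and its normalised autocorrelation
    computed; the first positive-lag local maximum, refined by parabolic
    interpolation, gives the spacing.  The peak must exceed
    ``threshold_multiple / sqrt(n)`` (the white-noise autocorrelation
    scale), otherwise the profile is declared aperiodic.
    """
    n = len(profile.distance)
    if n < 16:
        raise ValueError("profile too short for periodicity analysis (need >= 16 samples)")
    steps = np.diff(profile.distance)
    step = float(np.mean(steps))
    x = profile.height.astype(float)
    if np.ptp(steps) > 1e-6 * step:  # non-uniform sampling: resample
        grid = np.arange(profile.distance[0], profile.distance[-1] + step / 2, step)
        x = np.interp(grid, profile.distance, x)
        n = x.size
    x = signal.detrend(x, type="linear")
    denom = float(np.dot(x, x))
    if denom == 0:
        raise AperiodicProfileError("aperiodic: flat profile")
    ac = np.correlate(x, x, mode="full")[n - 1:] / denom
    max_lag = n - 4
    ac = ac[: max_lag + 1]

    peaks, _ = signal.find_peaks(ac[1:])
    if peaks.size == 0:
        raise AperiodicProfileError("aperiodic: no autocorrelation peak")
    k = int(peaks[0]) + 1
    noise_floor = 1.0 / np.sqrt(n - k) if n > k else 1.0
    if ac[k] < threshold_multiple * noise_floor:
        raise AperiodicProfileError(
            f"aperiodic: peak {ac[k]:.3f} below {threshold_multiple:g} x noise floor {noise_floor:.3f}"
        )
    # parabolic sub-sample refinement on (k-1, k, k+1)
    if 1 <= k < max_lag:
        y0, y1, y2 = ac[k - 1], ac[k], ac[k + 1]
        denom2 = y0 - 2 * y1 + y2
        shift = 0.5 * (y0 - y2) / denom2 if denom2 != 0 else 0.0
        shift = float(np.clip(shift, -0.5, 0.5))
    else:
        shift = 0.0
    return (k + shift) * step


# ---------------------------------------------------------------------------
# Particle measurements
# ---------------------------------------------------------------------------

def particle_height(topo: Topograph, region: Tuple[int, int, int, int]) -> float:
    """Particle apex height over local background within a pixel region.

    ``region`` is (row0, row1, col0, col1), half-open pixel indices.
    Returns max height inside the region minus the median of the region's
    1-pixel border ring (the local background).  A region touching the
    grid edge warns and uses the available border sides.
    """
    r0, r1, c0, c1 = region
    ny, nx = topo.heights.shape
    if not (0 <= r0 < r1 <= ny and 0 <= c0 < c1 <= nx):
        raise ValueError("region outside grid")
    if (r1 - r0) * (c1 - c0) < 25:
        raise ValueError("region must contain at least 25 pixels")
    block = topo.heights[r0:r1, c0:c1]
    border = np.ones(block.shape, dtype=bool)
    border[1:-1, 1:-1] = False
    if r0 == 0 or r1 == ny or c0 == 0 or c1 == nx:
        warnings.warn("region touches grid edge; background from available border sides")
    return float(block.max() - np.median(block[border]))


def diameter_from_vertices(m1: float, m2: float, m3: float) -> float:
    """Particle diameter as the mean of three vertex-to-vertex measurements."""
    vals = (m1, m2, m3)
    if any(v <= 0 for v in vals):
        raise ValueError("measurements must be > 0")
    return float(np.mean(vals))


def shell_profile_features(profile: Profile) -> dict[str, float]:
    """Shell thickness and shell–cargo gap from a wall-crossing profile.

    The two outermost density/height peaks (shell wall, then the first
    cargo layer) are decomposed as Gaussians; the shell thickness is the
    FWHM of the outermost peak and the inner gap the distance from its
    inner half-maximum to the next peak's outer half-maximum.  Gaussian
    decomposition rather than raw half-maximum crossings keeps both
    measures well-defined when the peaks overlap.
    """
    x, y = profile.distance, profile.height
    span = float(np.ptp(y))
    if span == 0:
        raise ProfileFeatureError("flat profile: need at least 2 peaks")
    peaks, props = signal.find_peaks(y, prominence=0.2 * span)
    if peaks.size < 2:
        raise ProfileFeatureError(f"need at least 2 peaks, found {peaks.size}")
    order = np.argsort(x[peaks])
    p1, p2 = peaks[order[0]], peaks[order[1]]
    widths = signal.peak_widths(y, np.array([p1, p2]), rel_height=0.5)[0]
    step = float(np.mean(np.diff(x)))

    model = ConstantModel(prefix="bg_") + GaussianModel(prefix="g1_") + GaussianModel(prefix="g2_")
    params = model.make_params(
        bg_c=float(np.min(y)),
        g1_center=float(x[p1]),
        g1_sigma=max(widths[0] * step / FWHM_PER_SIGMA, step),
        g1_amplitude=float((y[p1] - np.min(y)) * widths[0] * step),
        g2_center=float(x[p2]),
        g2_sigma=max(widths[1] * step / FWHM_PER_SIGMA, step),
        g2_amplitude=float((y[p2] - np.min(y)) * widths[1] * step),
    )
    for prefix in ("g1_", "g2_"):
        params[f"{prefix}sigma"].set(min=step / 4)
        params[f"{prefix}amplitude"].set(min=0)
    fit = model.fit(y, params, x=x)
    c1 = float(fit.params["g1_center"].value)
    c2 = float(fit.params["g2_center"].value)
    fwhm1 = float(fit.params["g1_sigma"].value) * FWHM_PER_SIGMA
    fwhm2 = float(fit.params["g2_sigma"].value) * FWHM_PER_SIGMA
    if c2 < c1:
        c1, c2, fwhm1, fwhm2 = c2, c1, fwhm2, fwhm1
    return {
        "shell_thickness": fwhm1,
        "inner_gap": (c2 - fwhm2 / 2.0) - (c1 + fwhm1 / 2.0),
    }
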