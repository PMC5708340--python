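"""Force–displacement curve containers, text I/O, and pre-processing.

AFM nanoindentation records cantilever force ``F`` against piezo-scanner
displacement ``z_p`` while the tip approaches and presses into a particle.
Before any mechanical model can be fitted the raw approach curve must be
baseline-corrected, the tip–sample contact point ``z_0`` located, and the
curve re-expressed as force vs tip–sample indentation

    d = z_p - z_0 - F / k_cantilever,

where ``F / k_cantilever`` is the cantilever deflection against a hard wall.

Internal units are fixed: nanometres for lengths, piconewtons for forces,
so spring constants are pN/nm and elastic moduli emerge in MPa
(1 pN/nm^2 = 1 MPa) without conversion factors.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np

__all__ = [
    "CantileverSpec",
    "ForceCurve",
    "IndentationCurve",
    "ForceCurveParseError",
    "NoContactError",
    "parse_force_curve",
    "write_force_curve",
    "baseline_correct",
    "detect_contact_point",
    "to_indentation",
]


class ForceCurveParseError(ValueError):
    """Raised when a force-curve text file violates the dialect."""


class NoContactError(RuntimeError):
    """Raised when no tip–sample contact can be located on a curve."""


@dataclass(frozen=True)
class CantileverSpec:
    """AFM cantilever and tip parameters.

    Parameters
    ----------
    k_cantilever : float
        Cantilever spring constant in pN/nm (0.35 N/m = 350 pN/nm).
    R_tip : float
        Tip apex radius in nm.
    E_tip : float
        Tip Young's modulus in MPa (silicon nitride ~ 1.3e5 MPa).
    nu_tip : float
        Tip Poisson coefficient, in [0, 0.5].
    """

    k_cantilever: float
    R_tip: float = 20.0
    E_tip: float = 1.3e5
    nu_tip: float = 0.3

    def __post_init__(self) -> None:
        for name in ("k_cantilever", "R_tip", "E_tip"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be finite and > 0")
        if not 0.0 <= self.nu_tip <= 0.5:
            raise ValueError("nu_tip must lie in [0, 0.5]")


@dataclass(frozen=True)
class ForceCurve:
    """Approach segment of a force–displacement curve.

    ``z_p`` is piezo displacement in nm, increasing toward the sample;
    ``F`` is force in pN, positive in compression.
    """

    z_p: np.ndarray
    F: np.ndarray
    curve_id: str = ""
    cantilever: Optional[CantileverSpec] = None
    speed: Optional[float] = None  # nm/s, metadata only

    def __post_init__(self) -> None:
        z = np.asarray(self.z_p, dtype=float)
        f = np.asarray(self.F, dtype=float)
        object.__setattr__(self, "z_p", z)
        object.__setattr__(self, "F", f)
        if z.ndim != 1 or f.ndim != 1 or z.size != f.size:
            raise ValueError("z_p and F must be 1-D arrays of equal length")
        if z.size < 2:
            raise ValueError("force curve needs at least 2 samples")
        if not (np.all(np.isfinite(z)) and np.all(np.isfinite(f))):
            raise ValueError("non-finite values in force curve")
        if not np.all(np.diff(z) > 0):
            raise ValueError("non-monotonic displacement: z_p must strictly increase")

    def __len__(self) -> int:
        return int(self.z_p.size)


@dataclass(frozen=True)
class IndentationCurve:
    """Force vs tip–sample indentation after contact-point correction.

    ``d`` is indentation in nm (clipped at >= 0), ``F`` force in pN, ``z_0``
    the contact distance used for the transformation.  ``n_clipped`` counts
    samples whose raw indentation was negative (noise around contact).
    """

    d: np.ndarray
    F: np.ndarray
    z_0: float
    source: str = ""
    n_clipped: int = 0

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        f = np.asarray(self.F, dtype=float)
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "F", f)
        if d.size != f.size or d.ndim != 1:
            raise ValueError("d and F must be 1-D arrays of equal length")
        if d.size < 2:
            raise ValueError("indentation curve needs at least 2 samples")
        if np.any(d < 0):
            raise ValueError("indentation must be non-negative")

    def __len__(self) -> int:
        return int(self.d.size)


# ---------------------------------------------------------------------------
# Text dialect
# ---------------------------------------------------------------------------

_Z_UNITS = {"nm": 1.0, "um": 1e3, "µm": 1e3, "μm": 1e3}
_F_UNITS = {"pn": 1.0, "nn": 1e3, "pN": 1.0, "nN": 1e3}
_K_UNITS = {"pn/nm": 1.0, "n/m": 1e3, "nn/nm": 1e3}


def parse_force_curve(path_or_text: Union[str, Path]) -> ForceCurve:
    """Parse a force curve from the plain-text dialect.

    The dialect is UTF-8 text: ``#`` header lines holding ``key=value``
    pairs (``k_cantilever`` mandatory; optional ``z_unit``, ``f_unit``,
    ``k_unit``, ``R_tip``, ``curve_id``, ``speed``), followed by two
    whitespace- or comma-separated columns ``z_p F``.  Units are
    normalised to nm / pN / pN-per-nm on read.
    """
    if isinstance(path_or_text, Path) or (
        isinstance(path_or_text, str)
        and "\n" not in path_or_text
        and Path(path_or_text).exists()
    ):
        text = Path(path_or_text).read_text(encoding="utf-8")
        name = str(path_or_text)
    else:
        text = str(path_or_text)
        name = "<text>"

    header: dict[str, str] = {}
    rows: list[tuple[float, float]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                header[key.strip()] = val.strip()
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            raise ForceCurveParseError(f"{name}:{lineno}: expected 2 columns, got {len(parts)}")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise ForceCurveParseError(f"{name}:{lineno}: non-numeric row: {line!r}") from exc

    if "k_cantilever" not in header:
        raise ForceCurveParseError(f"{name}: missing header key 'k_cantilever'")
    if len(rows) < 2:
        raise ForceCurveParseError(f"{name}: fewer than 2 data rows")

    z_scale = _lookup_unit(header.get("z_unit", "nm"), _Z_UNITS, "z_unit", name)
    f_scale = _lookup_unit(header.get("f_unit", "pN"), _F_UNITS, "f_unit", name)
    k_scale = _lookup_unit(header.get("k_unit", "pN/nm"), _K_UNITS, "k_unit", name)

    try:
        k = float(header["k_cantilever"]) * k_scale
    except ValueError as exc:
        raise ForceCurveParseError(f"{name}: non-numeric k_cantilever") from exc
    spec_kwargs: dict[str, float] = {"k_cantilever": k}
    if "R_tip" in header:
        spec_kwargs["R_tip"] = float(header["R_tip"]) * z_scale
    cantilever = CantileverSpec(**spec_kwargs)

    data = np.asarray(rows, dtype=float)
    z = data[:, 0] * z_scale
    f = data[:, 1] * f_scale
    if not np.all(np.diff(z) > 0):
        raise ForceCurveParseError(f"{name}: non-monotonic displacement")
    speed = float(header["speed"]) if "speed" in header else None
    return ForceCurve(z, f, curve_id=header.get("curve_id", ""), cantilever=cantilever, speed=speed)


def _lookup_unit(token: str, table: dict, key: str, name: str) -> float:
    t = token.strip()
    if t in table:
        return table[t]
    if t.lower() in table:
        return table[t.lower()]
    raise ForceCurveParseError(f"{name}: unknown {key} {token!r}")


def write_force_curve(curve: ForceCurve, path: Union[str, Path]) -> None:
    """Write a curve in the text dialect (nm / pN), bit-stably."""
    buf = io.StringIO()
    if curve.curve_id:
        buf.write(f"# curve_id={curve.curve_id}\n")
    buf.write("# z_unit=nm\n# f_unit=pN\n# k_unit=pN/nm\n")
    if curve.cantilever is not None:
        buf.write(f"# k_cantilever={curve.cantilever.k_cantilever:.9g}\n")
        buf.write(f"# R_tip={curve.cantilever.R_tip:.9g}\n")
    if curve.speed is not None:
        buf.write(f"# speed={curve.speed:.9g}\n")
    for z, f in zip(curve.z_p, curve.F):
        buf.write(f"{z:.9g} {f:.9g}\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# Pre-processing
# ---------------------------------------------------------------------------

def baseline_correct(curve: ForceCurve, pre_contact_fraction: float = 0.2) -> ForceCurve:
    """Remove offset and linear tilt fitted on the pre-contact window.

    A straight line is least-squares fitted to the first
    ``pre_contact_fraction`` of samples (assumed to lie before contact) and
    subtracted from the whole curve, zeroing the free-air baseline.
    Idempotent to numerical precision.
    """
    if not 0.0 < pre_contact_fraction <= 0.9:
        raise ValueError("pre_contact_fraction must be in (0, 0.9]")
    n_win = int(round(pre_contact_fraction * len(curve)))
    if n_win < 5:
        raise ValueError("pre-contact window shorter than 5 samples")
    z, f = curve.z_p, curve.F
    coeff = np.polyfit(z[:n_win], f[:n_win], 1)
    return replace(curve, F=f - np.polyval(coeff, z))


def estimate_noise_sd(curve: ForceCurve, pre_contact_fraction: float = 0.2) -> float:
    """Force noise SD (pN) from the detrended pre-contact window."""
    n_win = max(5, int(round(pre_contact_fraction * len(curve))))
    z, f = curve.z_p[:n_win], curve.F[:n_win]
    resid = f - np.polyval(np.polyfit(z, f, 1), z)
    return float(np.std(resid, ddof=2))


def detect_contact_point(
    curve: ForceCurve,
    noise_sd: Optional[float] = None,
    threshold_multiple: float = 3.0,
    sustain: int = 3,
    refine: bool = True,
    pre_contact_fraction: float = 0.2,
) -> float:
    """Locate the contact distance ``z_0`` on a baseline-corrected curve.

    The crossing point is the first ``z_p`` where ``F`` exceeds
    ``threshold_multiple * noise_sd`` and stays above it for ``sustain``
    consecutive samples.  With ``refine=True`` (default) the estimate is
    sharpened by the Hertz linearisation: near contact ``F^(2/3)`` is linear
    in ``z_p - F/k_cantilever``, so a line fitted on the shallow-force
    region extrapolates to zero force at ``z_0``.  The refinement removes
    the systematic late bias of the threshold crossing (the tip is already
    indenting when force clears the noise floor); it falls back to the raw
    crossing whenever the local fit is ill-conditioned (e.g. a force step).
    """
    if noise_sd is None:
        noise_sd = estimate_noise_sd(curve, pre_contact_fraction)
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    threshold = max(threshold_multiple * noise_sd, 1e-9)

    above = curve.F > threshold
    idx = _first_sustained(above, sustain)
    if idx is None:
        raise NoContactError("no contact detected")
    z_cross = float(curve.z_p[idx])
    if not refine:
        return z_cross

    k = curve.cantilever.k_cantilever if curve.cantilever is not None else None
    cap = 8.0 * threshold
    sel = np.zeros(len(curve), dtype=bool)
    sel[idx:] = True
    window = sel & (curve.F <= cap)
    if window.sum() < 4:  # noiseless or near-step curve: take first few contacts
        window = sel.copy()
        window[min(idx + 10, len(curve)):] = False
    F_w = curve.F[window]
    x = curve.z_p[window] - (F_w / k if k else 0.0)
    y = np.cbrt(np.maximum(F_w, 0.0) ** 2)  # F^(2/3), safe at 0
    if x.size < 3 or np.ptp(x) == 0:
        return z_cross
    slope, intercept = np.polyfit(x, y, 1)
    if slope <= 0:
        return z_cross
    z_0 = float(-intercept / slope)
    # sanity: refinement must stay near (and not after) the crossing
    if not z_cross - 5.0 <= z_0 <= z_cross:
        return z_cross
    return z_0


def _first_sustained(mask: np.ndarray, sustain: int) -> Optional[int]:
    if sustain <= 1:
        hits = np.flatnonzero(mask)
        return int(hits[0]) if hits.size else None
    run = np.convolve(mask.astype(int), np.ones(sustain, dtype=int), mode="valid")
    hits = np.flatnonzero(run == sustain)
    return int(hits[0]) if hits.size else None


def to_indentation(curve: ForceCurve, z_0: float) -> IndentationCurve:
    """Transform a force–displacement curve to force–indentation.

    Post-contact samples (``z_p >= z_0``) are kept and mapped through
    ``d = z_p - z_0 - F/k_cantilever``; negative ``d`` (noise) is clipped
    to zero and counted.
    """
    if curve.cantilever is None or curve.cantilever.k_cantilever <= 0:
        raise ValueError("to_indentation requires a cantilever with k_cantilever > 0")
    if not curve.z_p[0] <= z_0 <= curve.z_p[-1]:
        raise ValueError("z_0 outside the sampled displacement range")
    k = curve.cantilever.k_cantilever
    mask = curve.z_p >= z_0
    d_raw = curve.z_p[mask] - z_0 - curve.F[mask] / k
    n_clipped = int(np.sum(d_raw < 0))
    return IndentationCurve(
        d=np.maximum(d_raw, 0.0),
        F=curve.F[mask].copy(),
        z_0=float(z_0),
        source=curve.curve_id,
        n_clipped=n_clipped,
    )
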