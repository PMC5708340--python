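"""Per-curve analysis pipeline and run-level report assembly.

Chains the processing a single nanoindentation curve goes through —
baseline correction, contact-point detection, indentation transform,
series-spring fit, thin-shell modulus, Hertz fit — and aggregates
per-particle results into a summary table (mean, SD, n per quantity).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import pandas as pd

from . import mechanics
from .curves import (
    ForceCurve,
    baseline_correct,
    detect_contact_point,
    estimate_noise_sd,
    parse_force_curve,
    to_indentation,
)
from .mechanics import CARBOXYSOME_SHELL, ShellSpec, aggregate_particle_fits

__all__ = ["RunConfig", "analyze_curve", "run_analyze"]

log = logging.getLogger("shellmech")

#: Forces above this are analysed unchanged but noted: intact shells showed
#: no rupture events up to the 1 nN force cap.
HIGH_FORCE_NOTE_PN = 300.0


@dataclass
class RunConfig:
    """Configuration of an analysis run (file inputs + model windows)."""

    input_paths: Sequence[Path] = field(default_factory=list)
    output_dir: Optional[Path] = None
    force_window: Tuple[float, float] = (50.0, 150.0)
    depth_window: Tuple[float, float] = (0.0, 10.0)
    shell: ShellSpec = CARBOXYSOME_SHELL
    pre_contact_fraction: float = 0.2
    refine_z0: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.force_window, self.depth_window):
            if not lo < hi:
                raise ValueError("windows must be ordered (low, high)")


def analyze_curve(
    curve: ForceCurve,
    shell: ShellSpec = CARBOXYSOME_SHELL,
    force_window: Tuple[float, float] = (50.0, 150.0),
    depth_window: Tuple[float, float] = (0.0, 10.0),
    pre_contact_fraction: float = 0.2,
    refine_z0: bool = True,
) -> dict:
    """Run the full model chain on one approach curve.

    Returns a flat record with the contact point, series-spring stiffness
    ``k_total`` / particle spring constant ``k_CB``, thin-shell modulus
    ``E_S``, Hertzian modulus ``E_H`` and diagnostics.
    """
    if curve.cantilever is None:
        raise ValueError("curve has no cantilever metadata")
    corrected = baseline_correct(curve, pre_contact_fraction)
    noise_sd = estimate_noise_sd(corrected, pre_contact_fraction)
    z_0 = detect_contact_point(
        corrected, noise_sd=max(noise_sd, 1e-12), pre_contact_fraction=pre_contact_fraction
    )
    ind = to_indentation(corrected, z_0)

    linear = mechanics.fit_linear_stiffness(corrected, curve.cantilever, force_window)
    e_shell = mechanics.thin_shell_modulus(linear.k_particle, shell)
    hertz = mechanics.fit_hertz(
        ind, curve.cantilever, shell, depth_window, refine_z0=refine_z0
    )

    notes = []
    if float(corrected.F.max()) > HIGH_FORCE_NOTE_PN:
        notes.append(f"peak force exceeds {HIGH_FORCE_NOTE_PN:g} pN (no rupture model applied)")
    return {
        "curve_id": curve.curve_id,
        "z_0": z_0,
        "z_0_refined": hertz.z_0_refined,
        "noise_sd": noise_sd,
        "k_total": linear.k_total,
        "k_CB": linear.k_particle,
        "E_S": e_shell,
        "E_H": hertz.E_hertz,
        "r_squared_linear": linear.r_squared,
        "rms_residual_hertz": hertz.rms_residual,
        "force_window": list(force_window),
        "depth_window": list(depth_window),
        "n_points_linear": linear.n_points,
        "n_points_hertz": hertz.n_points,
        "notes": notes,
    }


def run_analyze(cfg: RunConfig) -> dict:
    """Analyse every parsable curve in ``cfg.input_paths`` and aggregate.

    Failing curves are logged and skipped; their count is reported.
    Writes ``per_curve.json`` and ``summary.csv`` to ``cfg.output_dir``
    when set.  Deterministic: identical inputs give byte-identical output.
    """
    paths = [Path(p) for p in cfg.input_paths]
    if not paths:
        raise ValueError("no input curves")
    records, failed = [], 0
    for path in sorted(paths):
        try:
            curve = parse_force_curve(path)
            records.append(
                analyze_curve(
                    curve,
                    shell=cfg.shell,
                    force_window=cfg.force_window,
                    depth_window=cfg.depth_window,
                    pre_contact_fraction=cfg.pre_contact_fraction,
                    refine_z0=cfg.refine_z0,
                )
            )
        except Exception as exc:  # noqa: BLE001 — per-curve isolation
            failed += 1
            log.warning("skipping %s: %s", path, exc)
    if not records:
        raise RuntimeError(f"all {failed} input curves failed to analyse")

    summary = aggregate_particle_fits(
        [{k: r[k] for k in ("k_total", "k_CB", "E_S", "E_H")} for r in records]
    )
    report = {
        "n_curves": len(records),
        "n_failed": failed,
        "per_curve": records,
        "summary": {
            q: {"mean": row["mean"], "sd": row["sd"], "n": int(row["n"])}
            for q, row in summary.iterrows()
        },
    }
    if cfg.output_dir is not None:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "per_curve.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        _summary_csv(summary).to_csv(out / "summary.csv")
    return report


def _summary_csv(summary: pd.DataFrame) -> pd.DataFrame:
    units = {"k_total": "pN/nm", "k_CB": "pN/nm", "E_S": "MPa", "E_H": "MPa"}
    method = {
        "k_total": "measured slope",
        "k_CB": "series-spring (linear model)",
        "E_S": "thin-shell model",
        "E_H": "Hertzian model",
    }
    out = summary.copy()
    out["unit"] = [units.get(q, "") for q in out.index]
    out["method"] = [method.get(q, "") for q in out.index]
    return out[["mean", "sd", "n", "unit", "method"]]
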