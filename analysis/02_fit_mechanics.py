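#!/usr/bin/env python
"""Fit the three mechanical models to the synthetic indentation campaign.

For every curve from 01_generate_dataset.py: baseline correction, contact
detection, indentation transform, series-spring fit (50-150 pN window),
thin-shell modulus (R = 75 nm, h = 4.5 nm, alpha = 1) and Hertz fit
(0-10 nm window, co-fitted contact point).  Also brackets one curve
against forward Hertz simulations at {0.5, 1, 5, 50, 500} MPa.

Writes results/mechanics/: per_curve.json, summary.csv, bracket.json.
With ground truth E = 0.59 MPa and k_CB = 20 pN/nm the summary means
should land within ~10%; the bracket should report (0.5, 1) MPa.
"""

import argparse
import json
from pathlib import Path

from shellmech import RunConfig, bracket_modulus, run_analyze
from shellmech.curves import baseline_correct, detect_contact_point, parse_force_curve, to_indentation

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--data", type=Path, default=ROOT / "scratch" / "data" / "curves")
    args = parser.parse_args()

    paths = sorted(args.data.glob("*.txt"))
    if not paths:
        raise SystemExit("no curves found — run analysis/01_generate_dataset.py first")
    out = ROOT / "results" / "mechanics"
    report = run_analyze(RunConfig(input_paths=paths, output_dir=out))
    print(f"analysed {report['n_curves']} curves ({report['n_failed']} failed)")
    for q, row in report["summary"].items():
        unit = "MPa" if q.startswith("E") else "pN/nm"
        print(f"  {q:8s} {row['mean']:8.2f} +/- {row['sd']:.2f} {unit} (n={row['n']})")

    curve = parse_force_curve(paths[0])
    corrected = baseline_correct(curve)
    ind = to_indentation(corrected, detect_contact_point(corrected))
    # compare over the shallow window where Hertz contact holds; at depth the
    # composite curve is in whole-particle linear compression
    bracket = bracket_modulus(ind, curve.cantilever, 0.5, [0.5, 1.0, 5.0, 50.0, 500.0],
                              depth_window=(0.0, 10.0))
    (out / "bracket.json").write_text(json.dumps({
        "curve_id": curve.curve_id, "E_low_MPa": bracket.E_low, "E_high_MPa": bracket.E_high,
        "open_bracket": bracket.is_open,
    }, indent=2, sort_keys=True) + "\n")
    print(f"modulus bracket for {curve.curve_id}: ({bracket.E_low}, {bracket.E_high}) MPa")


if __name__ == "__main__":
    main()
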