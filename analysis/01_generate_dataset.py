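#!/usr/bin/env python
"""Generate the synthetic measurement campaign.

Writes to scratch/data/: 25 Hertz-then-linear nanoindentation curves
(E = 0.59 MPa, k_CB = 20 pN/nm, 2 pN force noise, 350 pN/nm cantilever,
force capped at 1 nN), hexagonal-lattice topographs at 9.0 and 9.5 nm
center spacing, and a particle-size population (149.90 +/- 13.78 nm,
n = 90).  These mirror the measured study conditions so the downstream
fits have known ground truth.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from shellmech import (
    GeneratorConfig,
    gen_composite_curve,
    gen_lattice_topograph,
    gen_particle_population,
    write_force_curve,
)
from shellmech.imaging import write_topograph

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--n-curves", type=int, default=25)
    args = parser.parse_args()

    out = ROOT / "scratch" / "data"
    (out / "curves").mkdir(parents=True, exist_ok=True)
    (out / "topographs").mkdir(parents=True, exist_ok=True)

    for i in range(args.n_curves):
        cfg = GeneratorConfig(seed=args.seed + i, noise_sd=2.0)
        curve = gen_composite_curve(cfg, E=0.59, k_CB=20.0)
        write_force_curve(curve, out / "curves" / f"{curve.curve_id}.txt")
    print(f"wrote {args.n_curves} composite curves (E=0.59 MPa, k_CB=20 pN/nm) to {out/'curves'}")

    for spacing in (9.0, 9.5):
        topo = gen_lattice_topograph(spacing, amplitude=2.0, pixel_size=0.5, size=128,
                                     noise_sd=0.1, seed=args.seed)
        write_topograph(topo, out / "topographs" / f"lattice_{spacing:g}nm.txt")
    print(f"wrote lattice topographs (9.0 and 9.5 nm spacing) to {out/'topographs'}")

    sizes = gen_particle_population(149.90, 13.78, n=90, seed=args.seed)
    np.savetxt(out / "diameters_nm.txt", sizes, fmt="%.4f",
               header="synthetic particle diameters (nm), Normal(149.90, 13.78) truncated at 4 SD")
    (out / "generation.json").write_text(json.dumps({
        "seed": args.seed, "n_curves": args.n_curves,
        "E_MPa": 0.59, "k_CB_pN_per_nm": 20.0, "noise_sd_pN": 2.0,
        "lattice_spacings_nm": [9.0, 9.5], "population": [149.90, 13.78, 90],
    }, indent=2) + "\n")
    print(f"population of 90 diameters: mean {sizes.mean():.2f} nm, SD {sizes.std(ddof=1):.2f} nm")


if __name__ == "__main__":
    main()
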