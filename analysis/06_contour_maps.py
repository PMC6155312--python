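#!/usr/bin/env python
"""StDev*Coeff contour maps for the top model of the field scan.

Refits the best field combination on the synthetic series from 03, maps
each field's per-column sigma x coefficient back onto the lattice, extracts
favorable/unfavorable regions at the 80th/20th percentiles, and exports
OpenDX grids (plus one Gaussian cube) under results/contours/.
"""

from pathlib import Path

import numpy as np

from comsiakit import (ActivityTable, build_grid, compute_all_fields,
                       extract_contours, read_structures, stdev_coeff,
                       write_cube, write_dx)
from comsiakit.pls import fit_combo

ROOT = Path(__file__).resolve().parents[1]
SERIES = ROOT / "results" / "synthetic_series"
OUT = ROOT / "results" / "contours"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    mols = read_structures(SERIES / "structures.sdf",
                           properties_csv=SERIES / "atom_properties.csv")
    table = ActivityTable.from_csv(SERIES / "activities.csv")
    grid = build_grid(mols)
    blocks = compute_all_fields(mols, grid)
    train = table.subset("train")
    ids = list(train.ids)
    tb = {k: b.rows(ids) for k, b in blocks.items()}
    row, model = fit_combo(tb, train.pec50(), ("S", "A"), block_scale=True)
    print(f"model S+A: q2={row['q2']:.3f}, N={int(row['N'])}, "
          f"contributions S={row['contrib_S']:.2f} A={row['contrib_A']:.2f}")

    for kind in "SA":
        values = stdev_coeff(model, blocks[kind])
        cmap = extract_contours(values, 80, 20, kind=kind)
        write_dx(values, grid, OUT / f"stdev_coeff_{kind}.dx")
        peak = grid.points()[np.argmax(np.abs(values))]
        print(f"  field {kind}: favorable {cmap.favorable_mask.sum()} pts, "
              f"unfavorable {cmap.unfavorable_mask.sum()} pts, "
              f"|peak| at ({peak[0]:.0f}, {peak[1]:.0f}, {peak[2]:.0f})")
    write_cube(stdev_coeff(model, blocks["A"]), grid,
               OUT / "stdev_coeff_A.cube", molecule=mols[0])
    print(f"wrote OpenDX/cube grids to {OUT}")


if __name__ == "__main__":
    main()
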