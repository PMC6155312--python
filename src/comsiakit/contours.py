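"""StDev*Coeff contour maps from a fitted field model, with grid export.

The display convention of similarity-field QSAR: for each grid column j the
product of the column's training standard deviation and its PLS coefficient,
σ_j·c_j, measures how much local field variation drives predicted activity.
Contouring the upper/lower percentiles of that quantity marks favorable and
unfavorable regions around the series.  Maps export as OpenDX grids (and
Gaussian cube) for molecular viewers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .chem_data import Molecule
from .fields import FieldBlock, GridSpec
from .pls import PLSModel

logger = logging.getLogger(__name__)


class ContourError(ValueError):
    pass


def stdev_coeff(model: PLSModel, block: FieldBlock) -> np.ndarray:
    """Per-grid-point σ·coefficient values for one field of a fitted model.

    Columns removed by the filter carry 0 (no variation ⇒ no display).
    Returns an array over the block's full grid in lattice column order.
    """
    if model.column_field is None or model.column_grid_index is None:
        raise ContourError("model lacks column metadata; fit it through the field scan")
    in_model = model.column_field == block.kind
    if not in_model.any():
        raise ContourError(f"field {block.kind!r} is not part of the fitted combination")
    values = np.zeros(block.grid.n_points)
    idx = model.column_grid_index[in_model]
    values[idx] = model.x_sigma[in_model] * model.coef[in_model]
    return values


@dataclass(frozen=True)
class ContourMap:
    """Favorable/unfavorable grid regions for one property field."""

    kind: str
    values: np.ndarray
    favorable_mask: np.ndarray
    unfavorable_mask: np.ndarray
    thresholds: tuple[float, float]   # (upper percentile, lower percentile)

    def __post_init__(self):
        if np.any(self.favorable_mask & self.unfavorable_mask):
            raise ContourError("favorable and unfavorable masks overlap")


def extract_contours(values: np.ndarray, upper_pct: float = 80.0,
                     lower_pct: float = 20.0, kind: str = "?") -> ContourMap:
    """Percentile-threshold contours on the signed nonzero value distribution.

    Favorable points sit at or above the upper percentile, unfavorable at or
    below the lower percentile.  An all-zero field yields empty masks with a
    warning.  Masks are invariant under positive rescaling of the values.
    """
    if not (0 < lower_pct < upper_pct < 100):
        raise ContourError("percentiles must satisfy 0 < lower < upper < 100")
    values = np.asarray(values, dtype=float)
    nonzero = values[values != 0]
    if nonzero.size == 0:
        warnings.warn("all-zero field: empty contour masks", stacklevel=2)
        empty = np.zeros(values.shape, dtype=bool)
        return ContourMap(kind, values, empty, empty.copy(), (np.nan, np.nan))
    hi = float(np.percentile(nonzero, upper_pct))
    lo = float(np.percentile(nonzero, lower_pct))
    fav = (values != 0) & (values >= hi)
    unfav = (values != 0) & (values <= lo) & ~fav
    return ContourMap(kind, values, fav, unfav, (hi, lo))


# ---------------------------------------------------------------------------
# grid export (OpenDX scalar field / Gaussian cube)


def write_dx(values: np.ndarray, grid: GridSpec, path) -> None:
    """Write grid values as an OpenDX regular scalar field (z-fastest order)."""
    values = np.asarray(values, dtype=float)
    if values.size != grid.n_points:
        raise ContourError(f"{values.size} values for a {grid.n_points}-point grid")
    nx, ny, nz = grid.dims
    ox, oy, oz = grid.origin
    d = grid.spacing
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {ox:.6f} {oy:.6f} {oz:.6f}\n")
        fh.write(f"delta {d:.6f} 0.000000 0.000000\n")
        fh.write(f"delta 0.000000 {d:.6f} 0.000000\n")
        fh.write(f"delta 0.000000 0.000000 {d:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items {values.size} data follows\n")
        flat = values.ravel()
        for i in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.7e}" for v in flat[i:i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')


def read_dx(path):
    """Read an OpenDX regular scalar field back as ``(values, GridSpec)``."""
    counts = origin = None
    deltas = []
    data: list[float] = []
    n_items = None
    with open(path) as fh:
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            if tok[:4] == ["object", "1", "class", "gridpositions"]:
                counts = tuple(int(v) for v in tok[-3:])
            elif tok[0] == "origin":
                origin = tuple(float(v) for v in tok[1:4])
            elif tok[0] == "delta":
                deltas.append([float(v) for v in tok[1:4]])
            elif tok[:4] == ["object", "3", "class", "array"]:
                n_items = int(tok[tok.index("items") + 1])
            elif n_items is not None and len(data) < n_items:
                try:
                    data.extend(float(v) for v in tok)
                except ValueError:
                    continue
    if counts is None or origin is None or n_items is None:
        raise ContourError(f"{path}: not a regular OpenDX scalar field")
    spacing = deltas[0][0]
    grid = GridSpec(origin=origin, spacing=spacing, dims=counts)
    values = np.array(data[:n_items])
    if values.size != grid.n_points:
        raise ContourError(f"{path}: {values.size} values for {grid.n_points} points")
    return values, grid


_CUBE_Z = {"H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "P": 15, "S": 16,
           "Cl": 17, "Br": 35, "I": 53}
_BOHR = 1.0 / 0.529177210903


def write_cube(values: np.ndarray, grid: GridSpec, path,
               molecule: Molecule | None = None) -> None:
    """Write grid values as a Gaussian cube file (lengths in bohr).

    Pseudo-atoms with unrecognised element symbols are written as carbon.
    """
    values = np.asarray(values, dtype=float)
    if values.size != grid.n_points:
        raise ContourError(f"{values.size} values for a {grid.n_points}-point grid")
    nx, ny, nz = grid.dims
    natoms = molecule.n_atoms if molecule is not None else 0
    with open(path, "w") as fh:
        fh.write("similarity-field contour map\n")
        fh.write("StDev*Coeff values on a regular lattice\n")
        o = np.asarray(grid.origin) * _BOHR
        d = grid.spacing * _BOHR
        fh.write(f"{natoms:5d} {o[0]:12.6f} {o[1]:12.6f} {o[2]:12.6f}\n")
        fh.write(f"{nx:5d} {d:12.6f} {0.0:12.6f} {0.0:12.6f}\n")
        fh.write(f"{ny:5d} {0.0:12.6f} {d:12.6f} {0.0:12.6f}\n")
        fh.write(f"{nz:5d} {0.0:12.6f} {0.0:12.6f} {d:12.6f}\n")
        if molecule is not None:
            for el, (x, y, z) in zip(molecule.elements, molecule.xyz * _BOHR):
                zn = _CUBE_Z.get(str(el), 6)
                fh.write(f"{zn:5d} {0.0:12.6f} {x:12.6f} {y:12.6f} {z:12.6f}\n")
        flat = values.ravel()
        for i in range(0, flat.size, 6):
            fh.write("".join(f"{v:13.5e}" for v in flat[i:i + 6]) + "\n")
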