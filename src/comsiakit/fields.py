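"""Gaussian similarity-index fields on a 3D lattice.

Aligned molecules are embedded in a cubic lattice (default 2 Å spacing).  For
each of five physicochemical properties — steric (S), electrostatic (E),
hydrophobic (H), hydrogen-bond donor (D) and acceptor (A) — the similarity
index between a probe atom at grid point q and molecule j is

    A_q(j) = − Σ_i  w_probe · w_i · exp(−α · r_iq²)

summed over all atoms i (no distance cutoff; the Gaussian attenuation with
α = 0.3 Å⁻² makes remote atoms negligible).  The leading minus is the sign
convention of the similarity-index literature: similarity to the probe is
reported as an attractive (negative) value.  Atom weights w_i are property
dependent: cubed vdW radius (S), partial charge (E), tabulated atomic
hydrophobicity (H) and binary donor/acceptor flags (D/A).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .chem_data import Molecule
from .datasets import load_atom_params

logger = logging.getLogger(__name__)

FIELD_KINDS = ("S", "E", "H", "D", "A")
FIELD_NAMES = {
    "S": "steric",
    "E": "electrostatic",
    "H": "hydrophobic",
    "D": "donor",
    "A": "acceptor",
}


class FieldError(ValueError):
    """Invalid field computation request."""


@dataclass(frozen=True)
class ProbeSpec:
    """Probe atom properties and the Gaussian attenuation factor.

    Standard settings: charge +1.0 e, radius 1.0 Å, hydrophobicity +1.0,
    donor +1.0, acceptor +1.0, attenuation α = 0.3 Å⁻².
    """

    charge: float = 1.0
    radius: float = 1.0
    hydrophobicity: float = 1.0
    donor: float = 1.0
    acceptor: float = 1.0
    alpha: float = 0.3

    def __post_init__(self):
        for name in ("charge", "radius", "hydrophobicity", "donor", "acceptor", "alpha"):
            if getattr(self, name) <= 0:
                raise FieldError(f"probe {name} must be positive")

    def weight(self, kind: str) -> float:
        return {
            "S": self.radius ** 3,
            "E": self.charge,
            "H": self.hydrophobicity,
            "D": self.donor,
            "A": self.acceptor,
        }[kind]


@dataclass(frozen=True)
class GridSpec:
    """Cubic lattice: origin, spacing and point counts per axis.

    Grid points are scanned z-fastest (x outer, y middle, z inner), which
    fixes the column order of every field block built on the grid.
    """

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self):
        if self.spacing <= 0:
            raise FieldError("grid spacing must be positive")
        if any(d < 1 for d in self.dims):
            raise FieldError("grid dims must be >= 1")

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def points(self) -> np.ndarray:
        """All lattice coordinates, shape (n_points, 3), z-fastest order."""
        nx, ny, nz = self.dims
        ax = [np.asarray(self.origin)[i] + self.spacing * np.arange(n)
              for i, n in enumerate(self.dims)]
        g = np.meshgrid(ax[0], ax[1], ax[2], indexing="ij")
        return np.stack([a.ravel() for a in g], axis=1)

    @property
    def upper_corner(self) -> np.ndarray:
        return np.asarray(self.origin) + self.spacing * (np.asarray(self.dims) - 1)


def build_grid(molecules: Sequence[Molecule], spacing: float = 2.0,
               margin: float = 4.0) -> GridSpec:
    """Lattice enclosing every atom of every aligned molecule plus a margin.

    The origin is snapped down to integer multiples of the spacing (anchor at
    the global origin) so identical inputs always produce identical columns.
    """
    if not molecules:
        raise FieldError("cannot build a grid for an empty molecule set")
    coords = np.vstack([m.xyz for m in molecules])
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    lo_idx = np.floor(lo / spacing + 1e-9).astype(int)
    hi_idx = np.ceil(hi / spacing - 1e-9).astype(int)
    origin = lo_idx * spacing
    dims = hi_idx - lo_idx + 1
    return GridSpec(origin=tuple(float(v) for v in origin), spacing=float(spacing),
                    dims=tuple(int(v) for v in dims))


_DEFAULT_PARAMS: dict | None = None


def _atom_params() -> dict:
    global _DEFAULT_PARAMS
    if _DEFAULT_PARAMS is None:
        _DEFAULT_PARAMS = load_atom_params()
    return _DEFAULT_PARAMS


def assign_atom_weights(molecule: Molecule, kind: str | None = None,
                        params: dict | None = None) -> Molecule:
    """Fill per-atom field weights from the element rule tables (in place).

    Steric weight is the cubed vdW radius; electrostatic weight is the
    supplied partial charge (not touched here); hydrophobic weights come from
    the per-element contribution table; donor flag marks N/O bearing at least
    one hydrogen (the weight sits on the heavy atom); acceptor flag marks
    N/O that are not positively charged, excluding pyrrole-like aromatic N-H.
    Already-assigned arrays (e.g. explicit pseudo-atom weights) are kept.
    """
    params = params or _atom_params()
    kinds = FIELD_KINDS if kind is None else (kind,)
    el = molecule.elements

    def lookup(table: Mapping[str, float], what: str) -> np.ndarray:
        missing = sorted({str(e) for e in el} - set(table))
        if missing:
            raise FieldError(f"{molecule.name}: no {what} parameter for element(s) {missing}")
        return np.array([table[str(e)] for e in el], dtype=float)

    if "S" in kinds and molecule.vdw_radius is None:
        molecule.vdw_radius = lookup(params["vdw_radius"], "vdW radius")
    if "H" in kinds and molecule.hydrophobic_w is None:
        molecule.hydrophobic_w = lookup(params["hydrophobic"], "hydrophobicity")
    if ("D" in kinds and molecule.donor_w is None) or ("A" in kinds and molecule.acceptor_w is None):
        if molecule.n_h is None or molecule.formal_charge is None:
            raise FieldError(
                f"{molecule.name}: donor/acceptor rules need connectivity info "
                "(n_h, formal_charge); read via read_structures or set weights explicitly")
        is_no = np.isin(el.astype(str), ("N", "O"))
        donor = (is_no & (molecule.n_h >= 1)).astype(float)
        aromatic = molecule.aromatic if molecule.aromatic is not None else np.zeros(len(el), bool)
        pyrrole_like = (el.astype(str) == "N") & aromatic & (molecule.n_h >= 1)
        acceptor = (is_no & (molecule.formal_charge <= 0) & ~pyrrole_like).astype(float)
        if molecule.donor_w is None:
            molecule.donor_w = donor
        if molecule.acceptor_w is None:
            molecule.acceptor_w = acceptor
    return molecule


def atom_weights(molecule: Molecule, kind: str) -> np.ndarray:
    """Per-atom weight vector for one field kind; errors if unassigned."""
    if kind not in FIELD_KINDS:
        raise FieldError(f"unknown field kind {kind!r}")
    arr = {
        "S": None if molecule.vdw_radius is None else molecule.vdw_radius ** 3,
        "E": molecule.charge,
        "H": molecule.hydrophobic_w,
        "D": molecule.donor_w,
        "A": molecule.acceptor_w,
    }[kind]
    if arr is None or np.any(~np.isfinite(np.asarray(arr, dtype=float))):
        raise FieldError(
            f"{molecule.name}: {FIELD_NAMES[kind]} atom weights unassigned; "
            "call assign_atom_weights or supply them explicitly")
    return np.asarray(arr, dtype=float)


def similarity_field(molecule: Molecule, points, kind: str,
                     probe: ProbeSpec = ProbeSpec()) -> np.ndarray:
    """Similarity-index values of one molecule at arbitrary 3D points.

    ``points`` may be a GridSpec or an (m, 3) coordinate array.  Returns the
    length-m vector −w_probe · Σ_i w_i · exp(−α r_iq²).
    """
    pts = points.points() if isinstance(points, GridSpec) else np.asarray(points, dtype=float)
    w = atom_weights(molecule, kind)
    d2 = cdist(pts, molecule.xyz, metric="sqeuclidean")
    return -probe.weight(kind) * (np.exp(-probe.alpha * d2) @ w)


@dataclass(frozen=True)
class FieldBlock:
    """Molecules × grid-points matrix of similarity indices for one field."""

    kind: str
    X: np.ndarray                 # (n_molecules, n_points)
    grid: GridSpec
    molecule_names: tuple[str, ...]

    def __post_init__(self):
        if self.kind not in FIELD_KINDS:
            raise FieldError(f"unknown field kind {self.kind!r}")
        if self.X.shape != (len(self.molecule_names), self.grid.n_points):
            raise FieldError("field block shape mismatch with grid/molecules")
        if not np.all(np.isfinite(self.X)):
            raise FieldError("field block contains non-finite values")

    @property
    def column_coords(self) -> np.ndarray:
        return self.grid.points()

    def rows(self, names: Sequence[str]) -> np.ndarray:
        idx = [self.molecule_names.index(n) for n in names]
        return self.X[idx]


def compute_field_block(molecules: Sequence[Molecule], grid: GridSpec, kind: str,
                        probe: ProbeSpec = ProbeSpec()) -> FieldBlock:
    pts = grid.points()
    X = np.vstack([similarity_field(m, pts, kind, probe) for m in molecules])
    return FieldBlock(kind=kind, X=X, grid=grid,
                      molecule_names=tuple(m.name for m in molecules))


def compute_all_fields(molecules: Sequence[Molecule], grid: GridSpec,
                       probe: ProbeSpec = ProbeSpec(),
                       kinds: Sequence[str] = FIELD_KINDS) -> dict[str, FieldBlock]:
    return {k: compute_field_block(molecules, grid, k, probe) for k in kinds}


def column_filter(X_train: np.ndarray, threshold: float = 2.0,
                  mode: str = "range") -> np.ndarray:
    """Boolean mask of grid columns with enough variation over training rows.

    ``range`` mode (default) keeps column j iff max−min ≥ threshold, the ≥
    making the boundary inclusive; ``sigma`` mode uses the population
    standard deviation instead.  The mask must be derived on the training
    block only and reused unchanged for the test block.
    """
    X_train = np.asarray(X_train, dtype=float)
    if X_train.ndim != 2 or X_train.shape[0] < 2:
        raise FieldError("column filter needs >= 2 training rows")
    if mode == "range":
        spread = X_train.max(axis=0) - X_train.min(axis=0)
    elif mode == "sigma":
        spread = X_train.std(axis=0)
    else:
        raise FieldError(f"unknown column filter mode {mode!r}")
    mask = spread >= threshold
    if not mask.any():
        warnings.warn(f"column filter ({mode} >= {threshold}) removed every column",
                      stacklevel=2)
    return mask
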