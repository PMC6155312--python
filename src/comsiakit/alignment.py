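"""Rigid-body atom-fit superposition onto a reference scaffold.

Congeneric series share a common core (here a phenylethanolamine nucleus);
each molecule is superposed onto a chosen reference by unweighted
least-squares fitting of user-mapped scaffold atoms (the Kabsch algorithm).
Reflections are forbidden so stereochemistry is preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem_data import Molecule

logger = logging.getLogger(__name__)


class AlignmentError(ValueError):
    """Degenerate or invalid superposition problem."""


@dataclass(frozen=True)
class ScaffoldMap:
    """Atom-index pairing (reference_idx, molecule_idx), 0-based.

    At least 3 pairs are required and the mapped reference atoms must not be
    collinear, otherwise the rotation is underdetermined.
    """

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if len(self.pairs) < 3:
            raise AlignmentError(f"scaffold map needs >= 3 atom pairs, got {len(self.pairs)}")
        if any(i < 0 or j < 0 for i, j in self.pairs):
            raise AlignmentError("scaffold map indices must be non-negative")

    @property
    def ref_idx(self) -> np.ndarray:
        return np.array([p[0] for p in self.pairs])

    @property
    def mol_idx(self) -> np.ndarray:
        return np.array([p[1] for p in self.pairs])


def _check_not_collinear(points: np.ndarray) -> None:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= 1e-8 * max(s[0], 1.0):
        raise AlignmentError("mapped reference atoms are collinear; rotation underdetermined")


def kabsch_superpose(ref_xyz: np.ndarray, mov_xyz: np.ndarray):
    """Proper-rotation least-squares superposition of mov onto ref.

    Returns ``(rotation, translation, rmsd)`` with ``x' = R x + t``
    minimising the RMSD over the mapped atoms, det(R) = +1 enforced
    (no reflections).
    """
    ref = np.asarray(ref_xyz, dtype=float)
    mov = np.asarray(mov_xyz, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise AlignmentError(f"point sets must share shape (N, 3); got {ref.shape} vs {mov.shape}")
    if ref.shape[0] < 3:
        raise AlignmentError("superposition needs at least 3 mapped atoms")
    _check_not_collinear(ref)

    cr = ref.mean(axis=0)
    cm = mov.mean(axis=0)
    h = (mov - cm).T @ (ref - cr)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cr - rot @ cm
    moved = mov @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return rot, trans, rmsd


def align_set(molecules: Sequence[Molecule], reference_id: str,
              scaffold_maps: Mapping[str, ScaffoldMap]):
    """Superpose every molecule onto the named reference via its scaffold map.

    The reference molecule itself is returned unchanged.  Returns
    ``(aligned_molecules, rmsd_report)`` where the report is a DataFrame of
    per-molecule scaffold RMSDs (Angstrom).
    """
    by_name = {m.name: m for m in molecules}
    if reference_id not in by_name:
        raise KeyError(f"reference molecule {reference_id!r} not in set")
    ref = by_name[reference_id]

    aligned: list[Molecule] = []
    rows = []
    for mol in molecules:
        if mol.name == reference_id:
            aligned.append(mol.copy())
            rows.append({"molecule": mol.name, "scaffold_rmsd": 0.0})
            continue
        if mol.name not in scaffold_maps:
            raise KeyError(f"no scaffold map for molecule {mol.name!r}")
        smap = scaffold_maps[mol.name]
        rot, trans, rmsd = kabsch_superpose(ref.xyz[smap.ref_idx], mol.xyz[smap.mol_idx])
        aligned.append(mol.transformed(rot, trans))
        rows.append({"molecule": mol.name, "scaffold_rmsd": rmsd})
        logger.debug("aligned %s onto %s: scaffold rmsd %.4f A", mol.name, reference_id, rmsd)
    return aligned, pd.DataFrame(rows)


def read_scaffold_maps(path) -> dict[str, ScaffoldMap]:
    """Read scaffold maps from CSV (molecule_id, ref_atom_idx, mol_atom_idx; 0-based)."""
    df = pd.read_csv(path, dtype={"molecule_id": str})
    required = {"molecule_id", "ref_atom_idx", "mol_atom_idx"}
    if required - set(df.columns):
        raise ValueError(f"{path}: scaffold map CSV needs columns {sorted(required)}")
    out: dict[str, ScaffoldMap] = {}
    for mid, sub in df.groupby("molecule_id", sort=False):
        out[mid] = ScaffoldMap(tuple(zip(sub["ref_atom_idx"].astype(int),
                                         sub["mol_atom_idx"].astype(int))))
    return out


def write_scaffold_maps(maps: Mapping[str, ScaffoldMap], path) -> None:
    rows = [{"molecule_id": mid, "ref_atom_idx": i, "mol_atom_idx": j}
            for mid, smap in maps.items() for i, j in smap.pairs]
    pd.DataFrame(rows).to_csv(path, index=False)
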