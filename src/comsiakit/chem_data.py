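"""Compound, activity and 3D-structure data model with I/O.

Activities are half-maximal effective concentrations (EC50, nM) measured per
beta-adrenergic receptor subtype; modelling happens on the pEC50 scale
(−log10 of the molar EC50).  Structures are consumed pre-minimised and
pre-charged: no 2D→3D generation, charge calculation or conformer search
happens here.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ROLE_TRAIN = "train"
ROLE_TEST = "test"


class ActivityError(ValueError):
    """Invalid activity value (non-positive or non-finite EC50)."""


class StructureFormatError(ValueError):
    """Structure file unreadable or missing required information."""


def pec50_from_ec50(ec50_nM):
    """Convert EC50 in nM to pEC50 = −log10(EC50 in molar).

    Accepts a scalar or array; raises :class:`ActivityError` on non-positive
    or non-finite input.  Values are returned at full precision; round to
    3 decimals only for table display.
    """
    arr = np.asarray(ec50_nM, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ActivityError(f"EC50 must be positive and finite, got {ec50_nM!r}")
    out = -np.log10(arr * 1e-9)
    return float(out) if np.isscalar(ec50_nM) or arr.ndim == 0 else out


def selectivity_ratio(ec50_other_nM, ec50_b3_nM):
    """Subtype-selectivity index EC50(other)/EC50(beta3), dimensionless.

    Display convention is 1 decimal; full precision is returned.
    """
    if not (math.isfinite(ec50_other_nM) and math.isfinite(ec50_b3_nM)):
        raise ActivityError("selectivity requires finite EC50 values")
    if ec50_other_nM <= 0 or ec50_b3_nM <= 0:
        raise ActivityError("selectivity requires positive EC50 values")
    return ec50_other_nM / ec50_b3_nM


@dataclass(frozen=True)
class CompoundRecord:
    """One compound's activity bookkeeping entry."""

    id: str
    ec50_b1_nM: float
    ec50_b2_nM: float
    ec50_b3_nM: float
    role: str

    def __post_init__(self):
        for v in (self.ec50_b1_nM, self.ec50_b2_nM, self.ec50_b3_nM):
            if not (math.isfinite(v) and v > 0):
                raise ActivityError(f"compound {self.id}: EC50 must be > 0, got {v}")
        if self.role not in (ROLE_TRAIN, ROLE_TEST):
            raise ValueError(f"compound {self.id}: role must be train|test, got {self.role!r}")

    @property
    def pec50_b3(self) -> float:
        return pec50_from_ec50(self.ec50_b3_nM)

    def selectivity(self, subtype: str) -> float:
        ec50 = {"b1": self.ec50_b1_nM, "b2": self.ec50_b2_nM}[subtype]
        return selectivity_ratio(ec50, self.ec50_b3_nM)


@dataclass(frozen=True)
class ActivityTable:
    """Ordered collection of compound records with train/test bookkeeping."""

    records: tuple[CompoundRecord, ...]

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate compound ids: {dupes}")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.records)

    @property
    def n_train(self) -> int:
        return sum(r.role == ROLE_TRAIN for r in self.records)

    @property
    def n_test(self) -> int:
        return sum(r.role == ROLE_TEST for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, cid: str) -> CompoundRecord:
        for r in self.records:
            if r.id == cid:
                return r
        raise KeyError(cid)

    def subset(self, role: str) -> "ActivityTable":
        return ActivityTable(tuple(r for r in self.records if r.role == role))

    def pec50(self) -> np.ndarray:
        return np.array([r.pec50_b3 for r in self.records])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "ec50_b1_nM": [r.ec50_b1_nM for r in self.records],
                "ec50_b2_nM": [r.ec50_b2_nM for r in self.records],
                "ec50_b3_nM": [r.ec50_b3_nM for r in self.records],
                "pec50_b3": self.pec50(),
                "role": [r.role for r in self.records],
            }
        )

    @classmethod
    def from_csv(cls, path) -> "ActivityTable":
        df = pd.read_csv(path, dtype={"id": str})
        required = {"id", "ec50_b1_nM", "ec50_b2_nM", "ec50_b3_nM", "role"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing activity columns {sorted(missing)}")
        recs = tuple(
            CompoundRecord(
                id=row.id,
                ec50_b1_nM=float(row.ec50_b1_nM),
                ec50_b2_nM=float(row.ec50_b2_nM),
                ec50_b3_nM=float(row.ec50_b3_nM),
                role=str(row.role),
            )
            for row in df.itertuples()
        )
        return cls(recs)

    def to_csv(self, path) -> None:
        self.to_frame().drop(columns="pec50_b3").to_csv(path, index=False)


def split_train_test(table: ActivityTable, test_ids: Iterable[str]):
    """Partition a table into (train, test) by explicit test ids.

    Input order is preserved within each partition.  An empty training set is
    rejected; unknown ids raise ``KeyError``.
    """
    test_ids = set(test_ids)
    unknown = test_ids - set(table.ids)
    if unknown:
        raise KeyError(f"unknown compound ids in test set: {sorted(unknown)}")
    train = tuple(r for r in table.records if r.id not in test_ids)
    test = tuple(r for r in table.records if r.id in test_ids)
    if not train:
        raise ValueError("test set covers every compound; training set is empty")
    logger.info(
        "split: %d train (%.0f%%) / %d test (%.0f%%)",
        len(train), 100 * len(train) / len(table),
        len(test), 100 * len(test) / len(table),
    )
    return ActivityTable(train), ActivityTable(test)


# ---------------------------------------------------------------------------
# 3D structures


@dataclass
class Molecule:
    """A 3D molecule as flat per-atom arrays.

    ``charge`` is the partial charge in elementary charge units (supplied,
    never computed here).  The five per-field weights (steric via
    ``vdw_radius``, electrostatic via ``charge``, plus ``hydrophobic_w``,
    ``donor_w``, ``acceptor_w``) may be unset (None) until assigned by the
    field module's rule tables, or supplied explicitly for pseudo-atom
    (synthetic) molecules.  ``n_h``/``formal_charge``/``aromatic`` carry the
    connectivity facts the donor/acceptor rules need.
    """

    name: str
    elements: np.ndarray          # (n,) of str symbols
    xyz: np.ndarray               # (n, 3) Angstrom
    charge: np.ndarray            # (n,) partial charge, e
    n_h: np.ndarray | None = None         # attached hydrogens per heavy atom
    formal_charge: np.ndarray | None = None
    aromatic: np.ndarray | None = None
    vdw_radius: np.ndarray | None = None  # Angstrom, > 0
    hydrophobic_w: np.ndarray | None = None
    donor_w: np.ndarray | None = None
    acceptor_w: np.ndarray | None = None

    def __post_init__(self):
        self.elements = np.asarray(self.elements, dtype=object)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.charge = np.asarray(self.charge, dtype=float)
        n = len(self.elements)
        if n < 1:
            raise ValueError(f"{self.name}: molecule needs at least one atom")
        if self.xyz.shape != (n, 3) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"{self.name}: coordinates must be a finite ({n}, 3) array")
        if self.vdw_radius is not None:
            self.vdw_radius = np.asarray(self.vdw_radius, dtype=float)
            if np.any(self.vdw_radius <= 0):
                raise ValueError(f"{self.name}: vdW radii must be positive")
        if np.allclose(self.xyz[:, 2], 0.0) and n > 3:
            logger.warning("%s: all z coordinates are 0 (2D-looking structure); accepted", self.name)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def copy(self) -> "Molecule":
        return Molecule(
            name=self.name,
            elements=self.elements.copy(),
            xyz=self.xyz.copy(),
            charge=self.charge.copy(),
            n_h=None if self.n_h is None else np.array(self.n_h),
            formal_charge=None if self.formal_charge is None else np.array(self.formal_charge),
            aromatic=None if self.aromatic is None else np.array(self.aromatic),
            vdw_radius=None if self.vdw_radius is None else self.vdw_radius.copy(),
            hydrophobic_w=None if self.hydrophobic_w is None else np.array(self.hydrophobic_w, dtype=float),
            donor_w=None if self.donor_w is None else np.array(self.donor_w, dtype=float),
            acceptor_w=None if self.acceptor_w is None else np.array(self.acceptor_w, dtype=float),
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Molecule":
        """Return a rigidly moved copy: x' = R x + t."""
        out = self.copy()
        out.xyz = self.xyz @ np.asarray(rotation).T + np.asarray(translation)
        return out


def _molecule_from_rdkit(mol, name: str, charges: np.ndarray | None) -> Molecule:
    from rdkit import Chem

    conf = mol.GetConformer()
    n = mol.GetNumAtoms()
    xyz = np.array([[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y,
                     conf.GetAtomPosition(i).z] for i in range(n)])
    elements = np.array([a.GetSymbol() for a in mol.GetAtoms()], dtype=object)
    if charges is None:
        charges = np.array([a.GetDoubleProp("_TriposPartialCharge")
                            if a.HasProp("_TriposPartialCharge") else np.nan
                            for a in mol.GetAtoms()])
    n_h = np.array([a.GetTotalNumHs(includeNeighbors=True) for a in mol.GetAtoms()])
    formal = np.array([a.GetFormalCharge() for a in mol.GetAtoms()])
    aromatic = np.array([a.GetIsAromatic() for a in mol.GetAtoms()])
    return Molecule(name=name, elements=elements, xyz=xyz, charge=charges,
                    n_h=n_h, formal_charge=formal, aromatic=aromatic)


def _read_sidecar(path, column: str) -> dict[str, dict[int, float]]:
    """Read a (molecule, atom_index, value) sidecar CSV, 0-based indices."""
    out: dict[str, dict[int, float]] = {}
    df = pd.read_csv(path, dtype={"molecule": str}, float_precision="round_trip")
    for col in ("molecule", "atom_index", column):
        if col not in df.columns:
            raise ValueError(f"{path}: sidecar needs columns molecule, atom_index, {column}")
    for row in df.itertuples():
        out.setdefault(row.molecule, {})[int(row.atom_index)] = float(getattr(row, column))
    return out


def read_structures(path, fmt: str | None = None, charges_csv=None,
                    properties_csv=None) -> list[Molecule]:
    """Read 3D structures from an SD file (V2000) or a Tripos MOL2 file.

    MOL2 carries partial charges inline; SDF requires a ``charges_csv``
    sidecar (columns molecule, atom_index (0-based), charge).  An optional
    ``properties_csv`` sidecar (molecule, atom_index, vdw_radius,
    hydrophobic_w, donor_w, acceptor_w) supplies explicit per-atom field
    weights, e.g. for pseudo-atom synthetic series.
    """
    from rdkit import Chem

    path = Path(path)
    if fmt is None:
        fmt = {".sdf": "sdf", ".sd": "sdf", ".mol2": "mol2"}.get(path.suffix.lower())
        if fmt is None:
            raise StructureFormatError(f"cannot infer format of {path}; pass fmt=")

    mols: list[Molecule] = []
    if fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
        raw = [(m, (m.GetProp("_Name") if m is not None and m.HasProp("_Name") else "")) for m in supplier]
        charge_map = _read_sidecar(charges_csv, "charge") if charges_csv else None
        for i, (m, name) in enumerate(raw):
            if m is None:
                raise StructureFormatError(f"{path}: record {i} unparsable")
            if m.GetNumConformers() == 0:
                raise StructureFormatError(f"{path}: record {i} has no coordinates")
            try:
                Chem.SanitizeMol(m)
            except Exception:
                logger.warning("%s: record %d failed sanitisation; kept raw", path, i)
            name = name or f"mol_{i}"
            if charge_map is not None:
                per = charge_map.get(name)
                if per is None:
                    raise StructureFormatError(f"{path}: no charges for molecule {name!r} in sidecar")
                charges = np.array([per[j] for j in range(m.GetNumAtoms())])
            else:
                charges = None
            mol = _molecule_from_rdkit(m, name, charges)
            if charge_map is None:
                mol.charge = np.full(mol.n_atoms, np.nan)
            mols.append(mol)
        if charges_csv is None and properties_csv is None:
            raise StructureFormatError(
                f"{path}: SD files carry no partial charges; supply charges_csv "
                "(or properties_csv for pseudo-atom series)")
    elif fmt == "mol2":
        text = path.read_text()
        blocks = ["@<TRIPOS>MOLECULE" + b for b in text.split("@<TRIPOS>MOLECULE") if b.strip()]
        for i, block in enumerate(blocks):
            m = Chem.MolFromMol2Block(block, sanitize=False, removeHs=False)
            if m is None:
                raise StructureFormatError(f"{path}: MOL2 record {i} unparsable")
            name = m.GetProp("_Name") if m.HasProp("_Name") else f"mol_{i}"
            mol = _molecule_from_rdkit(m, name, None)
            if np.any(~np.isfinite(mol.charge)):
                raise StructureFormatError(f"{path}: molecule {name!r} lacks partial charges")
            mols.append(mol)
    else:
        raise StructureFormatError(f"unknown structure format {fmt!r}")

    if properties_csv is not None:
        props = pd.read_csv(properties_csv, dtype={"molecule": str},
                            float_precision="round_trip")
        for mol in mols:
            sub = props[props["molecule"] == mol.name].sort_values("atom_index")
            if len(sub) != mol.n_atoms:
                raise StructureFormatError(
                    f"properties sidecar has {len(sub)} rows for {mol.name!r}, "
                    f"molecule has {mol.n_atoms} atoms")
            mol.charge = sub["charge"].to_numpy(dtype=float)
            mol.vdw_radius = sub["vdw_radius"].to_numpy(dtype=float)
            mol.hydrophobic_w = sub["hydrophobic_w"].to_numpy(dtype=float)
            mol.donor_w = sub["donor_w"].to_numpy(dtype=float)
            mol.acceptor_w = sub["acceptor_w"].to_numpy(dtype=float)
    return mols


def write_sdf(molecules: Sequence[Molecule], path, properties_csv=None) -> None:
    """Write molecules as a V2000 SD file (coordinates + elements only).

    Bonds and charges are not represented in the SD records; when
    ``properties_csv`` is given, per-atom charges and field weights are
    written to that sidecar so :func:`read_structures` round-trips pseudo-atom
    series exactly.
    """
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for mol in molecules:
            rw = Chem.RWMol()
            for el in mol.elements:
                a = Chem.Atom(str(el) if str(el) in _KNOWN_ELEMENTS else "C")
                a.SetNoImplicit(True)
                rw.AddAtom(a)
            conf = Chem.Conformer(mol.n_atoms)
            for i, (x, y, z) in enumerate(mol.xyz):
                conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
            rw.AddConformer(conf)
            m = rw.GetMol()
            m.SetProp("_Name", mol.name)
            writer.write(m)
    finally:
        writer.close()

    if properties_csv is not None:
        rows = []
        for mol in molecules:
            for i in range(mol.n_atoms):
                rows.append({
                    "molecule": mol.name,
                    "atom_index": i,
                    "charge": mol.charge[i],
                    "vdw_radius": mol.vdw_radius[i],
                    "hydrophobic_w": mol.hydrophobic_w[i],
                    "donor_w": mol.donor_w[i],
                    "acceptor_w": mol.acceptor_w[i],
                })
        # %.17g so pseudo-atom weights round-trip bit-exactly
        pd.DataFrame(rows).to_csv(properties_csv, index=False, float_format="%.17g")


_KNOWN_ELEMENTS = {"H", "C", "N", "O", "F", "P", "S", "Cl", "Br", "I"}
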