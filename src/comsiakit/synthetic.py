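"""Seeded synthetic congeneric series with known ground truth.

The real series (25 indole-alkylamine beta3 agonists) exists only as printed
tables, so every pipeline stage is exercised on generated data instead: a
fixed pseudo-atom scaffold shared by all molecules (pre-aligned), a menu of
pseudo-substituents at a few attachment sites, and activities that are by
construction a linear function of the molecules' own similarity-field values
at per-site probe points, plus Gaussian noise.  The generator stores the
planted field weights, the noiseless activities and the true poses, so
recovery experiments (field scan, alignment, PLS) have an exact oracle.

Substituent atoms are simplified pseudo-atoms carrying explicit property
weights rather than real chemistry: the tests target the statistics, not
force fields.  Donor/acceptor substituents stack several unit-weight atoms
so their grid columns clear the standard 2.0 column-filter threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import ScaffoldMap, write_scaffold_maps
from .chem_data import ActivityTable, CompoundRecord, Molecule, write_sdf
from .fields import FIELD_KINDS, ProbeSpec, similarity_field

logger = logging.getLogger(__name__)

# --- fixed scaffold: phenyl ring + ethanolamine-like chain (pseudo-atoms) ---
_RING = [(1.39 * np.cos(np.deg2rad(60 * k)), 1.39 * np.sin(np.deg2rad(60 * k)), 0.0)
         for k in range(6)]
#               element  xyz                    q     r      hyd   D    A
_SCAFFOLD = [
    ("C", _RING[0], -0.05, 1.70, 0.5, 0, 0),
    ("C", _RING[1], -0.05, 1.70, 0.5, 0, 0),
    ("C", _RING[2], -0.05, 1.70, 0.5, 0, 0),
    ("C", _RING[3], -0.05, 1.70, 0.5, 0, 0),
    ("C", _RING[4], -0.05, 1.70, 0.5, 0, 0),
    ("C", _RING[5], -0.05, 1.70, 0.5, 0, 0),
    ("C", (2.60, 0.00, 0.40), 0.10, 1.70, 0.5, 0, 0),   # C-alpha
    ("O", (3.10, 1.20, 0.90), -0.40, 1.52, -0.5, 1, 1),  # beta-hydroxyl
    ("N", (3.90, -0.80, 0.00), -0.30, 1.55, -0.5, 1, 1),  # amine
    ("C", (5.20, -0.20, 0.50), 0.05, 1.70, 0.5, 0, 0),   # C-beta
]
SCAFFOLD_SIZE = len(_SCAFFOLD)

# attachment sites: (base point index into scaffold, outward unit direction)
_SITES = [
    (3, np.array([-1.0, 0.0, 0.0])),           # para position of the ring
    (1, np.array([0.5, np.sqrt(3) / 2, 0.0])),  # ortho/meta region
    (9, np.array([1.0, 0.3, 0.2]) / np.linalg.norm([1.0, 0.3, 0.2])),  # chain end
    (8, np.array([0.0, -1.0, 0.3]) / np.linalg.norm([0.0, -1.0, 0.3])),  # near amine
]

# pseudo-substituents are sampled, not drawn from a fixed menu, so that the
# five properties vary independently of one another (size continuous,
# polarity categorical, hydrophobicity and charge independent): planted
# field dependencies stay identifiable instead of being aliased through a
# shared substituent identity.
_ATOM_OFFSETS = [(0.0, 0.0), (0.9, 0.45), (0.9, -0.45), (1.8, 0.0)]  # (along, sideways), Å


@dataclass(frozen=True)
class Substituent:
    """One sampled pseudo-substituent: up to 4 atoms sharing size/polarity."""

    n_atoms: int                  # 0..4
    polarity: str                 # apolar | donor | acceptor
    radius: float                 # vdW radius shared by the atoms, Å
    hydrophobic: float            # shared hydrophobicity weight
    charges: tuple[float, ...]    # per-atom partial charges, e


def _sample_substituent(rng: np.random.Generator) -> Substituent:
    # polar functional groups are multi-atom (amide/sulfonamide-like), so
    # donor/acceptor substituents carry 3-4 flagged atoms; apolar ones vary
    # freely in size.  Size, hydrophobicity and charge are sampled
    # independently of polarity so no field aliases another.
    kind = str(rng.choice(["empty", "apolar", "donor", "acceptor"],
                          p=[0.3, 0.3, 0.2, 0.2]))
    if kind == "empty":
        n_atoms, polarity = 0, "apolar"
    elif kind == "apolar":
        n_atoms, polarity = int(rng.choice([2, 3, 4])), "apolar"
    else:
        n_atoms, polarity = int(rng.choice([3, 4])), kind
    radius = float(rng.uniform(1.5, 2.0))
    hydrophobic = float(rng.uniform(-1.0, 1.0))
    charges = tuple(float(c) for c in rng.uniform(-0.6, 0.6, size=n_atoms))
    return Substituent(n_atoms=n_atoms, polarity=polarity, radius=radius,
                       hydrophobic=hydrophobic, charges=charges)

#: default planted dependence: steric + acceptor, the study's best model
#: family.  Weights balance the two fields' activity contributions (steric
#: field values are ~8x larger in magnitude than acceptor ones) and, with
#: the default intercept, span pEC50 ~6.7-9.8 like the real series.
DEFAULT_PLANTED: dict[str, float] = {"S": -0.04, "A": -0.25}


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for a generated congeneric series."""

    n_molecules: int = 25
    planted_weights: Mapping[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_PLANTED))
    noise_sd: float = 0.3          # activity noise, log units
    intercept: float = 4.6         # baseline pEC50 before field contributions
    test_fraction: float = 0.24    # 6 of 25 -> the 19/6 study split
    seed: int = 0

    def __post_init__(self):
        if self.n_molecules < 8:
            raise ValueError("need at least 8 molecules")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        bad = set(self.planted_weights) - set(FIELD_KINDS)
        if bad:
            raise ValueError(f"unknown planted field kinds {sorted(bad)}")
        if not self.planted_weights:
            raise ValueError("at least one planted field required")


@dataclass
class GroundTruth:
    """Everything needed to reconstruct the noiseless activities exactly."""

    planted_weights: dict[str, float]
    intercept: float
    probe_points: np.ndarray            # (n_sites, 3)
    substituent_choices: list[tuple]   # per molecule, per site Substituent
    noiseless: np.ndarray
    pec50: np.ndarray
    poses: list[tuple[np.ndarray, np.ndarray]]   # (R, t) per molecule
    seed: int

    def recompute_noiseless(self, molecules: Sequence[Molecule],
                            probe: ProbeSpec = ProbeSpec()) -> np.ndarray:
        """Closure check: planted weights + structures => noiseless activities."""
        return np.array([
            self.intercept + sum(
                w * float(similarity_field(m, self.probe_points, kind, probe).sum())
                for kind, w in self.planted_weights.items())
            for m in molecules])


@dataclass
class SyntheticSeries:
    molecules: list[Molecule]
    table: ActivityTable
    ground_truth: GroundTruth
    scaffold_maps: dict[str, ScaffoldMap]

    def export(self, outdir) -> dict[str, Path]:
        """Write the series in the dialects the real pipeline consumes."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "structures": outdir / "structures.sdf",
            "properties": outdir / "atom_properties.csv",
            "activities": outdir / "activities.csv",
            "scaffold_map": outdir / "scaffold_map.csv",
        }
        write_sdf(self.molecules, paths["structures"], properties_csv=paths["properties"])
        self.table.to_csv(paths["activities"])
        write_scaffold_maps(self.scaffold_maps, paths["scaffold_map"])
        return paths


def _build_molecule(name: str, choices: Sequence[Substituent]) -> Molecule:
    rows = [(el, np.asarray(xyz, float), q, r, h, d, a)
            for el, xyz, q, r, h, d, a in _SCAFFOLD]
    anchors = _probe_points()
    for (site, (_, direction)), sub in zip(enumerate(_SITES), choices):
        # substituents grow outward from the site's lattice probe point, so
        # the first atom sits on a grid node and carries full field weight
        anchor = anchors[site]
        perp = np.cross(direction, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.array([1.0, 0.0, 0.0])
        perp = perp / np.linalg.norm(perp)
        d = 1.0 if sub.polarity == "donor" else 0.0
        a = 1.0 if sub.polarity == "acceptor" else 0.0
        for (along, sideways), q in zip(_ATOM_OFFSETS[:sub.n_atoms], sub.charges):
            pos = anchor + along * direction + sideways * perp
            rows.append(("C", pos, q, sub.radius, sub.hydrophobic, d, a))
    return Molecule(
        name=name,
        elements=np.array([r[0] for r in rows], dtype=object),
        xyz=np.vstack([r[1] for r in rows]),
        charge=np.array([r[2] for r in rows], float),
        vdw_radius=np.array([r[3] for r in rows], float),
        hydrophobic_w=np.array([r[4] for r in rows], float),
        donor_w=np.array([r[5] for r in rows], float),
        acceptor_w=np.array([r[6] for r in rows], float),
    )


def _probe_points(spacing: float = 2.0) -> np.ndarray:
    """Per-site probe points, snapped to the standard lattice.

    Snapping puts each probe on a grid node (the lattice origin is anchored
    to spacing multiples), so the planted activities are exactly linear in
    field-block columns and recovery experiments have a sharp target.
    """
    raw = np.vstack([np.asarray(_SCAFFOLD[i][1], float) + 1.5 * d for i, d in _SITES])
    return np.round(raw / spacing) * spacing


def generate_series(spec: SyntheticSpec = SyntheticSpec(),
                    probe: ProbeSpec = ProbeSpec()) -> SyntheticSeries:
    """Generate a pre-aligned pseudo-atom congeneric series with planted signal.

    Activity of molecule m: intercept + Σ_f w_f · Σ_sites field_f(m, probe
    point) + N(0, noise_sd), where the sum runs over the planted fields.
    Identical seeds give bit-identical output.  Train/test roles follow an
    activity-stratified assignment (test compounds spread over the activity
    range, emulating a diverse held-out set at the study's 76/24 ratio).
    """
    rng = np.random.default_rng(spec.seed)
    probes = _probe_points()

    molecules, choices = [], []
    for i in range(spec.n_molecules):
        picks = tuple(_sample_substituent(rng) for _ in _SITES)
        choices.append(picks)
        molecules.append(_build_molecule(f"cmpd_{i + 1:02d}", picks))

    weights = dict(spec.planted_weights)
    noiseless = np.array([
        spec.intercept + sum(
            w * float(similarity_field(m, probes, kind, probe).sum())
            for kind, w in weights.items())
        for m in molecules])
    pec50 = noiseless + rng.normal(0.0, spec.noise_sd, size=spec.n_molecules)

    n_test = int(round(spec.test_fraction * spec.n_molecules))
    order = np.argsort(noiseless, kind="stable")
    test_ranks = np.round(np.linspace(1, spec.n_molecules - 2, n_test)).astype(int) \
        if n_test else np.array([], dtype=int)
    test_idx = set(order[test_ranks].tolist())

    records = []
    for i, m in enumerate(molecules):
        ec50_b3 = 10.0 ** (9.0 - pec50[i])
        sel1 = 10.0 ** rng.normal(1.0, 0.5)
        sel2 = 10.0 ** rng.normal(1.3, 0.5)
        records.append(CompoundRecord(
            id=m.name, ec50_b1_nM=ec50_b3 * sel1, ec50_b2_nM=ec50_b3 * sel2,
            ec50_b3_nM=ec50_b3, role="test" if i in test_idx else "train"))

    identity = [(np.eye(3), np.zeros(3)) for _ in molecules]
    gt = GroundTruth(planted_weights=weights, intercept=spec.intercept,
                     probe_points=probes, substituent_choices=choices,
                     noiseless=noiseless, pec50=pec50, poses=identity,
                     seed=spec.seed)
    scaffold_pairs = tuple((j, j) for j in range(SCAFFOLD_SIZE))
    maps = {m.name: ScaffoldMap(scaffold_pairs) for m in molecules}
    return SyntheticSeries(molecules=molecules, table=ActivityTable(tuple(records)),
                           ground_truth=gt, scaffold_maps=maps)


def random_rigid_transform(rng: np.random.Generator):
    """A uniformly random proper rotation (quaternion method) and translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    trans = rng.uniform(-10.0, 10.0, size=3)
    return rot, trans


def scramble_poses(molecules: Sequence[Molecule], seed: int):
    """Apply seeded random rigid moves; returns (moved molecules, true poses)."""
    rng = np.random.default_rng(seed)
    moved, poses = [], []
    for m in molecules:
        rot, trans = random_rigid_transform(rng)
        moved.append(m.transformed(rot, trans))
        poses.append((rot, trans))
    return moved, poses


def generate_hansch_table(n: int = 21, coefficients=None, noise_sd: float = 0.0,
                          seed: int = 0):
    """Random descriptor table + activities from a descriptor equation.

    Descriptors: CMR ~ U[8,16], S ~ Bernoulli(0.8), πx, πy ~ U[−1,2].
    ``coefficients`` is a HanschModel (default: the frozen published
    equation); activities are its predictions plus N(0, noise_sd).
    Returns ``(descriptor DataFrame, activities)``.
    """
    from .hansch import EQ1

    if n < 8:
        raise ValueError("need at least 8 compounds")
    model = EQ1 if coefficients is None else coefficients
    rng = np.random.default_rng(seed)
    s = rng.binomial(1, 0.8, n)
    while s.min() == s.max():   # both fragment classes must occur, else the
        s = rng.binomial(1, 0.8, n)  # indicator aliases the intercept
    df = pd.DataFrame({
        "id": [f"h{i + 1:02d}" for i in range(n)],
        "CMR": rng.uniform(8.0, 16.0, n),
        "S": s.astype(float),
        "pi_x": rng.uniform(-1.0, 2.0, n),
        "pi_y": rng.uniform(-1.0, 2.0, n),
    })
    y = model.predict(df) + rng.normal(0.0, noise_sd, n)
    return df, y
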