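import numpy as np
import pytest

from comsiakit import (GridSpec, ProbeSpec, assign_atom_weights, build_grid,
                       column_filter, compute_field_block, similarity_field)
from comsiakit.chem_data import Molecule
from comsiakit.fields import FieldError, atom_weights


def _atom(xyz=(0.0, 0.0, 0.0), **kw):
    defaults = dict(vdw_radius=[1.7], hydrophobic_w=[0.5], donor_w=[1.0],
                    acceptor_w=[1.0])
    defaults.update(kw)
    return Molecule(name="a", elements=np.array(["C"], dtype=object),
                    xyz=np.array([xyz], dtype=float), charge=np.array([0.1]),
                    **{k: np.asarray(v, float) for k, v in defaults.items()})


class TestBuildGrid:
    def test_single_atom_arithmetic(self):
        grid = build_grid([_atom()], spacing=2.0, margin=4.0)
        assert grid.dims == (5, 5, 5)
        assert grid.origin == (-4.0, -4.0, -4.0)

    def test_extent_covers_atoms_plus_margin(self):
        m = Molecule(name="pair", elements=np.array(["C", "C"], dtype=object),
                     xyz=np.array([[0.0, 0, 0], [10.0, 0, 0]]), charge=np.zeros(2),
                     vdw_radius=np.array([1.7, 1.7]))
        grid = build_grid([m], spacing=2.0, margin=4.0)
        assert grid.upper_corner[0] - grid.origin[0] >= 18.0

    def test_series_contained(self, default_series):
        grid = build_grid(default_series.molecules)
        lo = np.asarray(grid.origin)
        hi = grid.upper_corner
        for m in default_series.molecules:
            assert np.all(m.xyz >= lo) and np.all(m.xyz <= hi)

    def test_empty_set_rejected(self):
        with pytest.raises(FieldError):
            build_grid([])


class TestSimilarityField:
    def test_donor_atom_on_grid_point(self):
        val = similarity_field(_atom(), np.zeros((1, 3)), "D")
        assert val[0] == pytest.approx(-1.0)

    def test_gaussian_attenuation_closed_form(self):
        val = similarity_field(_atom(), np.array([[2.0, 0, 0]]), "D")
        assert val[0] == pytest.approx(-np.exp(-0.3 * 4.0), abs=1e-9)

    def test_additive_over_atoms(self):
        two = Molecule(name="two", elements=np.array(["C", "C"], dtype=object),
                       xyz=np.zeros((2, 3)), charge=np.zeros(2),
                       donor_w=np.array([1.0, 1.0]))
        pts = np.array([[0.5, 0.5, 0.5]])
        one = similarity_field(_atom(), pts, "D")
        assert similarity_field(two, pts, "D")[0] == pytest.approx(2 * one[0])

    def test_rigid_invariance(self, default_series):
        from scipy.spatial.transform import Rotation

        m = default_series.molecules[0]
        pts = np.array([[1.0, 2, 3], [-2.0, 0, 1]])
        R = Rotation.from_euler("xyz", [10, 40, 70], degrees=True).as_matrix()
        t = np.array([3.0, -1.0, 2.0])
        before = similarity_field(m, pts, "S")
        after = similarity_field(m.transformed(R, t), pts @ R.T + t, "S")
        np.testing.assert_allclose(after, before, atol=1e-9)

    def test_bounded_by_weight_sum(self, default_series):
        for m in default_series.molecules[:3]:
            block = similarity_field(m, np.array([[0.0, 0, 0], [4.0, 4, 4]]), "S")
            assert np.all(np.abs(block) <= np.sum(np.abs(m.vdw_radius ** 3)) + 1e-12)

    def test_halved_spacing_refines_grid(self, default_series):
        mols = default_series.molecules[:3]
        coarse = build_grid(mols, spacing=2.0, margin=4.0)
        fine = GridSpec(origin=coarse.origin, spacing=1.0,
                        dims=tuple(2 * (d - 1) + 1 for d in coarse.dims))
        assert fine.n_points > 6 * coarse.n_points  # ~8x columns (edge effects)
        bc = compute_field_block(mols, coarse, "S")
        bf = compute_field_block(mols, fine, "S")
        pc, pf = coarse.points(), fine.points()
        # shared lattice points carry bit-identical values
        key_c = {tuple(p): i for i, p in enumerate(pc)}
        shared = [(i, key_c[tuple(p)]) for i, p in enumerate(pf) if tuple(p) in key_c]
        assert len(shared) == coarse.n_points
        fi, ci = zip(*shared)
        # identical to a few ulps (SIMD batching can flip the last bit)
        np.testing.assert_allclose(bf.X[:, list(fi)], bc.X[:, list(ci)],
                                   rtol=1e-12, atol=0)

    def test_unassigned_weights_error_names_molecule(self):
        bare = Molecule(name="bare", elements=np.array(["C"], dtype=object),
                        xyz=np.zeros((1, 3)), charge=np.zeros(1))
        with pytest.raises(FieldError, match="bare"):
            similarity_field(bare, np.zeros((1, 3)), "D")


class TestAtomWeights:
    def _mol(self, elements, n_h, formal, aromatic=None):
        n = len(elements)
        return Molecule(name="m", elements=np.array(elements, dtype=object),
                        xyz=np.random.default_rng(0).normal(size=(n, 3)),
                        charge=np.zeros(n), n_h=np.array(n_h),
                        formal_charge=np.array(formal),
                        aromatic=np.array(aromatic if aromatic is not None else [False] * n))

    def test_steric_weight_is_cubed_radius(self):
        m = self._mol(["C"], [0], [0])
        assign_atom_weights(m)
        assert atom_weights(m, "S")[0] == pytest.approx(1.70 ** 3)  # 4.913

    def test_carbonyl_oxygen_is_acceptor_not_donor(self):
        m = self._mol(["O"], [0], [0])
        assign_atom_weights(m)
        assert m.acceptor_w[0] == 1 and m.donor_w[0] == 0

    def test_protonated_amine_is_donor_not_acceptor(self):
        m = self._mol(["N"], [3], [1])
        assign_atom_weights(m)
        assert m.donor_w[0] == 1 and m.acceptor_w[0] == 0

    def test_pyrrole_like_nh_excluded_from_acceptors(self):
        m = self._mol(["N"], [1], [0], aromatic=[True])
        assign_atom_weights(m)
        assert m.donor_w[0] == 1 and m.acceptor_w[0] == 0

    def test_unknown_element_rejected(self):
        m = self._mol(["Xx"], [0], [0])
        with pytest.raises(FieldError, match="Xx"):
            assign_atom_weights(m)

    def test_explicit_weights_kept(self, default_series):
        m = default_series.molecules[0].copy()
        before = m.donor_w.copy()
        assign_atom_weights(m)
        np.testing.assert_array_equal(m.donor_w, before)


class TestColumnFilter:
    def test_constant_column_dropped_boundary_kept(self):
        X = np.array([[0.0, 0.0, 0.0], [0.0, 2.0, 1.9]])
        mask = column_filter(X, threshold=2.0)
        assert mask.tolist() == [False, True, False]

    def test_planted_variance_strata(self):
        rng = np.random.default_rng(4)
        low = rng.uniform(0, 0.5, size=(10, 7))
        high = rng.uniform(0, 0.5, size=(10, 3)) + np.linspace(0, 5, 10)[:, None]
        X = np.hstack([low, high])
        mask = column_filter(X, threshold=2.0)
        assert mask.tolist() == [False] * 7 + [True] * 3

    def test_sigma_mode(self):
        X = np.array([[0.0, 0.0], [4.0, 0.1]])
        assert column_filter(X, threshold=1.0, mode="sigma").tolist() == [True, False]

    def test_all_removed_warns(self):
        with pytest.warns(UserWarning, match="every column"):
            mask = column_filter(np.zeros((3, 4)), threshold=2.0)
        assert not mask.any()


def test_probe_spec_validation():
    with pytest.raises(FieldError):
        ProbeSpec(alpha=0.0)
    assert ProbeSpec().weight("S") == 1.0  # radius 1 A probe
    assert ProbeSpec(radius=2.0).weight("S") == 8.0
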