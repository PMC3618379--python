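"""Dihedrals, the circular order parameter, Kabsch superposition and
clustering."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from nmrval.ensemble_analysis import (DihedralSet, angular_order_parameter,
                                      cluster_and_represent,
                                      compute_backbone_dihedrals,
                                      dihedral_angle, kabsch_superpose,
                                      order_parameters, pairwise_rmsd_matrix)
from nmrval.model_io import Ensemble, Model
from nmrval.synthetic_fixtures import FixtureSpec, make_ensemble


def _dset(values_by_angle, n_models):
    return DihedralSet(n_models=n_models,
                       angles={("A", 1): values_by_angle})


class TestBackboneDihedrals:
    def test_ideal_helix_recovers_target_angles(self):
        data = make_ensemble(FixtureSpec(seed=0, n_models=2,
                                         noise_sigma_A=0.0))
        dset = compute_backbone_dihedrals(data.ensemble)
        for res in range(2, data.spec.n_residues):
            angles = dset.residue_angles("A", res)
            for model_value in angles["phi"]:
                assert model_value == pytest.approx(-57.0, abs=1e-6)
            for model_value in angles["psi"]:
                assert model_value == pytest.approx(-47.0, abs=1e-6)

    def test_terminal_residues_omit_flanking_angles(self):
        data = make_ensemble(FixtureSpec(seed=0, n_models=1))
        dset = compute_backbone_dihedrals(data.ensemble)
        first = dset.residue_angles("A", 1)
        last = dset.residue_angles("A", data.spec.n_residues)
        assert "phi" not in first and "psi" in first
        assert "psi" not in last and "phi" in last

    def test_collinear_atoms_give_undefined_angle(self):
        pts = [np.array([float(i), 0.0, 0.0]) for i in range(4)]
        assert dihedral_angle(*pts) is None

    def test_nucleic_backbone_angles_on_hand_built_chain(self):
        # two "nucleotides" with backbone atoms placed so that every torsion
        # equals the value checked against an independent computation below
        rng = np.random.default_rng(8)
        names = ["P", "O5'", "C5'", "C4'", "C3'", "O3'"]
        atoms = {}
        coords = []
        pos = np.zeros(3)
        for i in (1, 2):
            for name in names:
                pos = pos + rng.normal(size=3)
                atoms[("X", i, name)] = pos.copy()
                coords.append(pos.copy())
        ens = Ensemble(models=[Model(model_id=1, atoms=atoms)],
                       sequence={"X": [(1, "A"), (2, "A")]},
                       polymer_type={"X": "nucleic"})
        dset = compute_backbone_dihedrals(ens)
        res1 = dset.residue_angles("X", 1)
        res2 = dset.residue_angles("X", 2)
        # interior angles present where flanking atoms exist
        assert set(res1) == {"beta", "gamma", "delta", "epsilon", "zeta"}
        assert set(res2) == {"alpha", "beta", "gamma", "delta"}
        # cross-check one angle against the raw four-point torsion
        expect = dihedral_angle(atoms[("X", 1, "P")], atoms[("X", 1, "O5'")],
                                atoms[("X", 1, "C5'")], atoms[("X", 1, "C4'")])
        assert res1["beta"][0] == pytest.approx(expect)


class TestOrderParameter:
    def test_identical_models_give_unity(self):
        dset = _dset({"phi": [-57.0] * 5, "psi": [-47.0] * 5}, 5)
        assert angular_order_parameter(dset, "A", 1) == pytest.approx(1.0)

    def test_fourfold_symmetric_angles_give_zero(self):
        dset = _dset({"phi": [0.0, 90.0, 180.0, -90.0]}, 4)
        assert angular_order_parameter(dset, "A", 1) == pytest.approx(0.0,
                                                                      abs=1e-12)

    def test_two_model_plus_minus_ten(self):
        dset = _dset({"phi": [-10.0, 10.0]}, 2)
        expected = np.cos(np.radians(10.0)) ** 2
        assert angular_order_parameter(dset, "A", 1) == pytest.approx(
            expected, abs=1e-9)

    def test_incomplete_angle_types_are_skipped(self):
        dset = _dset({"phi": [-57.0, None], "psi": [10.0, 30.0]}, 2)
        only_psi = _dset({"psi": [10.0, 30.0]}, 2)
        assert angular_order_parameter(dset, "A", 1) == pytest.approx(
            angular_order_parameter(only_psi, "A", 1))

    def test_undefined_when_nothing_complete(self):
        dset = _dset({"phi": [None, None]}, 2)
        assert angular_order_parameter(dset, "A", 1) is None

    def test_single_conformer_returns_one(self):
        dset = _dset({"phi": [123.0]}, 1)
        assert angular_order_parameter(dset, "A", 1) == 1.0

    @given(st.lists(st.floats(min_value=-179.99, max_value=180.0),
                    min_size=2, max_size=12),
           st.lists(st.floats(min_value=-179.99, max_value=180.0),
                    min_size=2, max_size=12))
    def test_bounded_and_copy_invariant(self, phis, psis):
        n = min(len(phis), len(psis))
        phis, psis = phis[:n], psis[:n]
        s2 = angular_order_parameter(
            _dset({"phi": phis, "psi": psis}, n), "A", 1)
        assert 0.0 <= s2 <= 1.0
        # duplicating every conformer leaves S2 unchanged
        s2_dup = angular_order_parameter(
            _dset({"phi": phis * 2, "psi": psis * 2}, 2 * n), "A", 1)
        assert s2_dup == pytest.approx(s2, abs=1e-12)

    def test_invariant_under_global_rotation(self):
        data = make_ensemble(FixtureSpec(seed=6, n_models=4,
                                         noise_sigma_A=0.3))
        s2 = order_parameters(data.ensemble)
        R = Rotation.from_euler("xyz", [20, -40, 75], degrees=True).as_matrix()
        rotated = Ensemble(
            models=[Model(model_id=m.model_id,
                          atoms={k: R @ v for k, v in m.atoms.items()})
                    for m in data.ensemble.models],
            sequence=data.ensemble.sequence,
            polymer_type=data.ensemble.polymer_type)
        s2_rot = order_parameters(rotated)
        for key, val in s2.items():
            assert s2_rot[key] == pytest.approx(val, abs=1e-9)


class TestKabsch:
    def test_identity_on_equal_clouds(self):
        A = np.random.default_rng(0).normal(size=(8, 3))
        res = kabsch_superpose(A, A)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-12)

    def test_rigid_motion_recovered(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(10, 3))
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        B = (A @ R.T) + np.array([1.0, -2.0, 3.0])
        res = kabsch_superpose(A, B)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(res.rotation @ B.T + res.translation[:, None],
                                   A.T, atol=1e-9)

    def test_matches_numerical_minimizer_with_noise(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(10, 3))
        R = Rotation.from_euler("xyz", [10, 40, -30], degrees=True).as_matrix()
        B = (A @ R.T) + rng.normal(0.0, 0.1, size=(10, 3)) + 2.0

        def rmsd_of(rotvec):
            Rm = Rotation.from_rotvec(rotvec).as_matrix()
            Bc = B - B.mean(axis=0)
            Ac = A - A.mean(axis=0)
            return np.sqrt(np.mean(np.sum((Bc @ Rm.T - Ac) ** 2, axis=1)))

        best = min(
            (minimize(rmsd_of, x0, method="Nelder-Mead",
                      options={"xatol": 1e-10, "fatol": 1e-12,
                               "maxiter": 20000})
             for x0 in (np.zeros(3), np.array([0.2, 0.7, -0.5]),
                        np.array([-1.0, 0.3, 1.2]))),
            key=lambda r: r.fun)
        res = kabsch_superpose(A, B)
        assert res.rmsd == pytest.approx(best.fun, abs=1e-6)

    def test_reflection_is_corrected(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(6, 3))
        B = A * np.array([1.0, 1.0, -1.0])  # mirrored cloud
        res = kabsch_superpose(A, B)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_or_collinear_points_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)


class TestClustering:
    def test_identical_models_form_one_cluster_rep_model_1(self):
        data = make_ensemble(FixtureSpec(seed=0, n_models=20,
                                         noise_sigma_A=0.0))
        result = cluster_and_represent(data.ensemble)
        assert [sorted(c) for c in result.clusters] == [list(range(1, 21))]
        assert result.overall_representative == 1

    def test_two_conformations_split_into_two_clusters(self, clustered_data):
        result = cluster_and_represent(clustered_data.ensemble)
        sizes = sorted(len(c) for c in result.clusters)
        assert sizes == [10, 10]
        groups = [sorted(c) for c in result.clusters]
        assert sorted(groups) == [list(range(1, 11)), list(range(11, 21))]

    def test_medoids_match_brute_force(self, clustered_data):
        result = cluster_and_represent(clustered_data.ensemble)
        mat = result.rmsd_matrix
        for members, rep in zip(result.clusters, result.representatives):
            idx = [m - 1 for m in sorted(members)]
            sums = mat[np.ix_(idx, idx)].sum(axis=1)
            best = sorted(members)[int(np.argmin(sums))]
            assert rep == best
            assert rep in members

    def test_three_model_matrix_equals_brute_force(self):
        data = make_ensemble(FixtureSpec(seed=9, n_models=3,
                                         noise_sigma_A=0.4))
        mat = pairwise_rmsd_matrix(data.ensemble)
        assert mat.shape == (3, 3)
        np.testing.assert_allclose(mat, mat.T, atol=0)
        np.testing.assert_allclose(np.diag(mat), 0.0)
        from nmrval.ensemble_analysis import (BACKBONE_SELECTION,
                                              _selection_coords)
        coords = [_selection_coords(data.ensemble, m, BACKBONE_SELECTION)
                  for m in data.ensemble.models]
        for i in range(3):
            for j in range(3):
                if i != j:
                    expect = kabsch_superpose(coords[i], coords[j]).rmsd
                    assert mat[i, j] == pytest.approx(expect, abs=1e-12)

    def test_single_model_trivial_cluster(self):
        data = make_ensemble(FixtureSpec(seed=0, n_models=1))
        result = cluster_and_represent(data.ensemble)
        assert result.clusters == [[1]]
        assert result.overall_representative == 1
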