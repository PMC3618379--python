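"""Chemical-shift validation: environments, offsets, Z-scores, colors."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nmrval.config import ValidationConfig, nucleus_class
from nmrval.model_io import ChemicalShiftRecord, Model
from nmrval.shift_validation import (aromatic_proximity, all_offsets,
                                     referencing_offset, residue_environments,
                                     shift_zscores, shrake_rupley_asa,
                                     ss_from_phi_psi, zscore_color)
from nmrval.synthetic_fixtures import (FixtureSpec, generate, make_ensemble,
                                       preset_spec, simulate_shifts)


class TestSecondaryStructure:
    def test_helix_window(self):
        assert ss_from_phi_psi(-57.0, -47.0) == "H"

    def test_sheet_window(self):
        assert ss_from_phi_psi(-120.0, 130.0) == "E"
        assert ss_from_phi_psi(-120.0, -160.0) == "E"

    def test_termini_and_other_are_coil(self):
        assert ss_from_phi_psi(None, -47.0) == "C"
        assert ss_from_phi_psi(60.0, 40.0) == "C"

    def test_ideal_helix_fixture_interior_is_H(self, basic_data):
        envs = residue_environments(basic_data.ensemble, 1)
        n = basic_data.spec.n_residues
        for res in range(2, n):
            assert envs[("A", res)].ss == "H"
        assert envs[("A", 1)].ss == "C"  # phi undefined at the N-terminus


class TestAccessibility:
    def test_isolated_residue_fully_exposed(self):
        # one alanine alone in space: nothing occludes it
        data = make_ensemble(FixtureSpec(seed=0, n_models=1,
                                         noise_sigma_A=0.0, n_residues=5))
        model = data.ensemble.models[0]
        lone = Model(model_id=1,
                     atoms={k: v for k, v in model.atoms.items()
                            if k[1] == 1})
        asa = shrake_rupley_asa(lone)
        # a lone Gly-X-Gly-normalized alanine exceeds its tripeptide maximum
        assert asa[("A", 1)] / 129.0 > 0.9

    def test_two_sphere_case_matches_analytic_cap_area(self):
        # lone carbon pair: accessible area has a closed spherical-cap form
        probe = 1.4
        r = 1.70 + probe
        d = 2.0
        model = Model(model_id=1, atoms={
            ("A", 1, "CA"): np.zeros(3),
            ("A", 2, "CA"): np.array([d, 0.0, 0.0])})
        asa = shrake_rupley_asa(model, probe_radius=probe, n_points=1024)
        cos_cap = (r * r + d * d - r * r) / (2 * r * d)
        expected = 4 * np.pi * r * r - 2 * np.pi * r * r * (1 - cos_cap)
        assert asa[("A", 1)] == pytest.approx(expected, rel=0.05)
        assert asa[("A", 2)] == pytest.approx(expected, rel=0.05)

    def test_residue_buried_by_dense_shell(self):
        # surround one alanine with a shell of dummy carbons: near-zero ASA
        data = make_ensemble(FixtureSpec(seed=0, n_models=1, n_residues=5,
                                         noise_sigma_A=0.0))
        model = data.ensemble.models[0]
        atoms = {k: v for k, v in model.atoms.items() if k[1] == 3}
        center = np.mean(list(atoms.values()), axis=0)
        rng = np.random.default_rng(1)
        for i in range(400):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            atoms[("Z", 100 + i, "C")] = center + direction * rng.uniform(5.0,
                                                                          7.0)
        asa = shrake_rupley_asa(Model(model_id=1, atoms=atoms))
        assert asa[("A", 3)] / 129.0 < 0.20

    def test_hydrogens_do_not_contribute(self):
        model = Model(model_id=1, atoms={("A", 1, "CA"): np.zeros(3),
                                         ("A", 1, "HA"): np.ones(3)})
        asa = shrake_rupley_asa(model)
        r = 1.70 + 1.4
        assert asa[("A", 1)] == pytest.approx(4 * np.pi * r * r, rel=1e-6)


def _simple_setup(offset_ppm=0.0, n_residues=20, seed=0, noise=0.0,
                  n_outliers=0):
    spec = FixtureSpec(seed=seed, n_residues=n_residues, n_models=3,
                       noise_sigma_A=0.0,
                       shift_offsets_ppm={"13C_aliphatic": offset_ppm}
                       if offset_ppm else {},
                       shift_noise_scale=noise, n_shift_outliers=n_outliers)
    data = make_ensemble(spec)
    simulate_shifts(data)
    envs = residue_environments(data.ensemble,
                                data.representative_model_id)
    return data, envs


class TestReferencingOffset:
    def test_zero_when_shifts_sit_at_reference_means(self):
        data, envs = _simple_setup()
        for nc, off in all_offsets(data.shifts, data.reference_table,
                                   envs).items():
            assert off == pytest.approx(0.0, abs=1e-9)

    def test_planted_offset_recovered_exactly_without_noise(self):
        data, envs = _simple_setup(offset_ppm=1.7)
        offsets = all_offsets(data.shifts, data.reference_table, envs)
        assert offsets["13C_aliphatic"] == pytest.approx(1.7, abs=0.01)
        for nc in ("1H", "15N", "13C'"):
            assert offsets[nc] == pytest.approx(0.0, abs=0.01)

    def test_below_minimum_matched_atoms_gives_zero(self, caplog):
        data, envs = _simple_setup(offset_ppm=1.7, n_residues=5)
        # 5 residues -> <10 aliphatic carbons only if we restrict the input
        aliphatic = [s for s in data.shifts
                     if s.nucleus_class == "13C_aliphatic"][:9]
        off = referencing_offset(aliphatic, data.reference_table, envs,
                                 "13C_aliphatic")
        assert off == 0.0

    def test_offset_absorbs_constant_translation(self):
        data, envs = _simple_setup(noise=1.0, seed=3)
        base = shift_zscores(data.shifts, data.reference_table, envs,
                             all_offsets(data.shifts, data.reference_table,
                                         envs))
        moved = [ChemicalShiftRecord(s.chain, s.resnum, s.resname, s.atom,
                                     s.nucleus_class,
                                     s.value_ppm + (2.5 if s.nucleus_class ==
                                                    "15N" else 0.0))
                 for s in data.shifts]
        res = shift_zscores(moved, data.reference_table, envs,
                            all_offsets(moved, data.reference_table, envs))
        for a, b in zip(base, res):
            if a.z is not None:
                assert b.z == pytest.approx(a.z, abs=1e-9)


class TestZScores:
    def test_observed_at_mean_plus_offset_scores_zero(self):
        data, envs = _simple_setup(offset_ppm=1.7)
        offsets = all_offsets(data.shifts, data.reference_table, envs)
        records = shift_zscores(data.shifts, data.reference_table, envs,
                                offsets)
        for r in records:
            assert r.z == pytest.approx(0.0, abs=1e-6)
            assert not r.outlier

    def test_exactly_three_sigma_is_not_an_outlier(self):
        data, envs = _simple_setup()
        offsets = {nc: 0.0 for nc in ("1H", "15N", "13C_aliphatic", "13C'")}
        s = data.shifts[5]
        env = envs[(s.chain, s.resnum)]
        mean, sd, _ = data.reference_table.lookup(s.resname, s.atom, env.ss,
                                                  env.acc_bin)
        bumped = ChemicalShiftRecord(s.chain, s.resnum, s.resname, s.atom,
                                     s.nucleus_class, mean + 3.0 * sd)
        (rec,) = shift_zscores([bumped], data.reference_table, envs, offsets)
        assert rec.z == pytest.approx(3.0, abs=1e-9)
        assert not rec.outlier
        above = ChemicalShiftRecord(s.chain, s.resnum, s.resname, s.atom,
                                    s.nucleus_class, mean + 3.01 * sd)
        (rec,) = shift_zscores([above], data.reference_table, envs, offsets)
        assert rec.outlier

    def test_planted_outliers_flagged(self):
        data, envs = _simple_setup(noise=1.0, n_outliers=5, seed=2)
        offsets = all_offsets(data.shifts, data.reference_table, envs)
        records = shift_zscores(data.shifts, data.reference_table, envs,
                                offsets)
        flagged = {(r.chain, r.resnum, r.atom) for r in records if r.outlier}
        assert set(map(tuple, data.planted_outlier_atoms)) <= flagged

    def test_missing_reference_gives_null_z(self):
        data, envs = _simple_setup()
        odd = ChemicalShiftRecord("A", 3, "ALA", "HB1", "1H", 1.4)
        (rec,) = shift_zscores([odd], data.reference_table, envs,
                               {"1H": 0.0})
        assert rec.z is None and rec.color is None and not rec.outlier

    def test_outlier_set_invariant_to_chain_relabeling(self):
        data, envs = _simple_setup(noise=1.0, n_outliers=3, seed=5)
        offsets = all_offsets(data.shifts, data.reference_table, envs)
        records = shift_zscores(data.shifts, data.reference_table, envs,
                                offsets)
        renamed_shifts = [ChemicalShiftRecord("Q", s.resnum, s.resname,
                                              s.atom, s.nucleus_class,
                                              s.value_ppm)
                          for s in data.shifts]
        renamed_envs = {("Q", r): e for (_, r), e in envs.items()}
        renamed = shift_zscores(renamed_shifts, data.reference_table,
                                renamed_envs, offsets)
        assert [(r.resnum, r.atom) for r in records if r.outlier] == \
            [(r.resnum, r.atom) for r in renamed if r.outlier]


class TestColorRamp:
    @pytest.mark.parametrize("z,rgb", [
        (1.0, (0, 255, 0)),
        (2.0, (0, 255, 0)),
        (3.5, (255, 255, 0)),
        (5.0, (255, 0, 0)),
        (-6.0, (255, 0, 0)),
        (7.5, (255, 0, 0)),
    ])
    def test_anchor_points(self, z, rgb):
        assert zscore_color(z) == rgb

    def test_sign_symmetric(self):
        for z in (2.7, 3.9, 4.6):
            assert zscore_color(z) == zscore_color(-z)

    @given(st.floats(min_value=-8.0, max_value=8.0),
           st.floats(min_value=-8.0, max_value=8.0))
    def test_monotone_green_to_red(self, z1, z2):
        a, b = sorted((abs(z1), abs(z2)))
        ra, ga, _ = zscore_color(a)
        rb, gb, _ = zscore_color(b)
        assert rb >= ra        # red channel rises with |z|
        assert gb <= ga        # green channel falls with |z|

    @given(st.floats(min_value=-6.0, max_value=6.0))
    def test_continuity(self, z):
        eps = 1e-4
        c1 = np.array(zscore_color(z))
        c2 = np.array(zscore_color(z + eps))
        assert np.abs(c1 - c2).max() <= 1


class TestAromaticProximity:
    def test_phe_neighbourhood_marked(self):
        data = generate(preset_spec("shifts", seed=1))
        near = aromatic_proximity(data.ensemble, 1)
        assert ("A", data.spec.aromatic_at) in near
        # a residue at the far end of the helix is not near the ring
        assert ("A", 1) not in near

    def test_no_aromatics_no_marks(self, basic_data):
        assert aromatic_proximity(basic_data.ensemble, 1) == set()


class TestNucleusClassMap:
    @pytest.mark.parametrize("res,atom,expected", [
        ("ALA", "H", "1H"), ("ALA", "HA", "1H"), ("ALA", "N", "15N"),
        ("ALA", "C", "13C'"), ("ALA", "CA", "13C_aliphatic"),
        ("PHE", "CD1", "13C_aromatic"), ("PHE", "CB", "13C_aliphatic"),
        ("TRP", "CZ2", "13C_aromatic"), ("ALA", "O", None),
    ])
    def test_mapping(self, res, atom, expected):
        assert nucleus_class(res, atom) == expected
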