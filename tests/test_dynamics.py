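"""Geometry, contacts and electrostatics on toy structures."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from spdca.dynamics import (
    ContactMap,
    ElectrostaticParams,
    K_ELEC,
    StructureFrame,
    debye_huckel_energy,
    debye_length,
    kabsch_rmsd,
    native_contact_fraction,
    radius_of_gyration,
    read_frames,
    residue_contact_map,
    trajectory_summary,
    write_frames,
)
from conftest import make_frame, two_chain_frame


def rigid_copy(frame, seed=0, translation=(3.0, -2.0, 7.0)):
    R = Rotation.random(random_state=seed).as_matrix()
    out = make_frame(
        frame.coords @ R.T + np.asarray(translation),
        chains=list(frame.chain_ids),
        res_ids=list(frame.res_ids),
        res_names=list(frame.res_names),
        atom_names=list(frame.atom_names),
        elements=list(frame.elements),
    )
    return out


class TestReadWriteFrames:
    def test_single_model_round_trip(self, tmp_path):
        fr = two_chain_frame()
        p = tmp_path / "one.pdb"
        write_frames([fr], p)
        frames = read_frames(p)
        assert len(frames) == 1
        assert frames[0].n_atoms == fr.n_atoms
        assert np.abs(frames[0].coords - fr.coords).max() < 1e-3

    def test_multi_model_equal_atom_counts(self, tmp_path):
        fr = two_chain_frame()
        p = tmp_path / "traj.pdb"
        write_frames([fr] * 5, p)
        frames = read_frames(p)
        assert len(frames) == 5
        assert all(f.n_atoms == fr.n_atoms for f in frames)

    def test_hetatm_water_excluded_and_counted(self, tmp_path):
        fr = two_chain_frame()
        p = tmp_path / "wet.pdb"
        write_frames([fr], p)
        text = p.read_text().replace(
            "ENDMDL",
            "HETATM 9991  O   HOH A 900      10.000  10.000  10.000  1.00  0.00           O\nENDMDL",
        )
        p.write_text(text)
        frames = read_frames(p)
        assert frames[0].n_atoms == fr.n_atoms
        assert frames[0].n_hetero_skipped == 1

    def test_malformed_atom_record_raises(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text(
            "MODEL        1\n"
            "ATOM      1  CA  ALA A   1      xx.xxx   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\n"
        )
        with pytest.raises(ValueError, match="unparseable"):
            read_frames(p)

    def test_hydrogens_flagged_non_heavy(self):
        fr = make_frame(np.zeros((2, 3)), elements=["C", "H"])
        assert list(fr.is_heavy) == [True, False]


class TestKabschRmsd:
    def test_identical_frames_zero(self):
        fr = two_chain_frame()
        assert kabsch_rmsd(fr, fr) < 1e-12

    def test_rigid_transform_invariance(self):
        fr = two_chain_frame()
        assert kabsch_rmsd(rigid_copy(fr, seed=3), fr) < 1e-8

    def test_symmetry(self, rng):
        fa = make_frame(rng.normal(size=(8, 3)))
        fb = make_frame(rng.normal(size=(8, 3)))
        assert kabsch_rmsd(fa, fb) == pytest.approx(kabsch_rmsd(fb, fa), abs=1e-8)

    def test_agrees_with_independent_implementation(self, rng):
        import MDAnalysis.analysis.rms as rms

        for _ in range(5):
            A = rng.normal(size=(10, 3))
            B = rng.normal(size=(10, 3))
            ours = kabsch_rmsd(make_frame(A), make_frame(B))
            theirs = rms.rmsd(A, B, superposition=True)
            assert ours == pytest.approx(theirs, abs=1e-8)

    def test_too_few_atoms_rejected(self):
        fa = make_frame(np.zeros((2, 3)) + np.arange(2)[:, None])
        with pytest.raises(ValueError, match="at least 3"):
            kabsch_rmsd(fa, fa)

    def test_mismatched_selections_rejected(self, rng):
        fa = make_frame(rng.normal(size=(5, 3)))
        fb = make_frame(rng.normal(size=(6, 3)))
        with pytest.raises(ValueError, match="differ"):
            kabsch_rmsd(fa, fb)


class TestRadiusOfGyration:
    def test_single_atom_zero(self):
        assert radius_of_gyration(make_frame([[1.0, 2.0, 3.0]])) == 0.0

    def test_two_unit_mass_atoms_one_angstrom(self):
        fr = make_frame([[0.0, 0, 0], [1.0, 0, 0]])
        assert radius_of_gyration(fr) == pytest.approx(0.5)

    def test_matches_direct_formula(self, rng):
        X = rng.normal(size=(20, 3)) * 4
        fr = make_frame(X)
        com = X.mean(axis=0)
        expected = np.sqrt(((X - com) ** 2).sum(axis=1).mean())
        assert radius_of_gyration(fr) == pytest.approx(expected, abs=1e-10)

    def test_rigid_transform_invariance(self, rng):
        fr = make_frame(rng.normal(size=(15, 3)))
        assert radius_of_gyration(rigid_copy(fr, seed=5)) == pytest.approx(
            radius_of_gyration(fr), abs=1e-10
        )

    def test_mass_weighting(self):
        fr = make_frame([[0.0, 0, 0], [1.0, 0, 0]])
        rg = radius_of_gyration(fr, masses=np.array([3.0, 1.0]))
        # com at 0.25; rg = sqrt((3*0.0625 + 1*0.5625)/4)
        assert rg == pytest.approx(np.sqrt(0.1875))

    def test_empty_selection_rejected(self):
        fr = make_frame([[0.0, 0, 0]])
        with pytest.raises(ValueError, match="empty"):
            radius_of_gyration(fr, selection=lambda a: False)


class TestContactMap:
    def test_two_atom_pairs_within_cutoff_is_contact(self):
        fr = two_chain_frame(separation=4.0)
        cm = residue_contact_map(fr, "A", "B", cutoff=5.0, min_atom_pairs=2)
        # same-residue partners sit 4.0 and sqrt(4²+1.2²)≈4.18 Å apart
        assert cm.matrix[0, 0] and cm.matrix[1, 1] and cm.matrix[2, 2]

    def test_single_atom_pair_is_not_a_contact(self):
        # one atom per residue → only one cross pair at 4 Å < cutoff
        fr = make_frame(
            [[0.0, 0, 0], [4.0, 0, 0]],
            chains=["A", "B"],
            res_ids=[1, 1],
        )
        cm = residue_contact_map(fr, "A", "B", cutoff=5.0, min_atom_pairs=2)
        assert not cm.matrix.any()
        lax = residue_contact_map(fr, "A", "B", cutoff=5.0, min_atom_pairs=1)
        assert lax.matrix[0, 0]

    def test_cutoff_is_strict_inequality(self):
        fr = make_frame(
            [[0.0, 0, 0], [0.0, 0, 1], [5.0, 0, 0], [5.0, 0, 1]],
            chains=["A", "A", "B", "B"],
            res_ids=[1, 1, 1, 1],
        )
        cm = residue_contact_map(fr, "A", "B", cutoff=5.0, min_atom_pairs=2)
        assert not cm.matrix.any()  # distances exactly 5.0 and above

    def test_matches_exhaustive_enumeration(self, rng):
        n = 30
        coords = rng.uniform(0, 15, size=(n, 3))
        chains = ["A"] * (n // 2) + ["B"] * (n - n // 2)
        res_ids = [k % 5 + 1 for k in range(n)]
        elements = rng.choice(["C", "N", "O", "H"], size=n).tolist()
        fr = make_frame(coords, chains=chains, res_ids=res_ids, elements=elements)
        cm = residue_contact_map(fr, "A", "B", cutoff=5.0, min_atom_pairs=2)
        for i, ra in enumerate(cm.res_ids_a):
            for j, rb in enumerate(cm.res_ids_b):
                count = 0
                for p in range(n):
                    for q in range(n):
                        if (
                            chains[p] == "A" and chains[q] == "B"
                            and res_ids[p] == ra and res_ids[q] == rb
                            and elements[p] != "H" and elements[q] != "H"
                            and np.linalg.norm(coords[p] - coords[q]) < 5.0
                        ):
                            count += 1
                assert cm.matrix[i, j] == (count >= 2)

    def test_transpose_symmetry(self, rng):
        fr = two_chain_frame(separation=4.5)
        ab = residue_contact_map(fr, "A", "B")
        ba = residue_contact_map(fr, "B", "A")
        assert np.array_equal(ab.matrix, ba.matrix.T)

    def test_hydrogens_ignored(self):
        fr = make_frame(
            [[0.0, 0, 0], [0.1, 0, 0], [4.0, 0, 0], [4.1, 0, 0]],
            chains=["A", "A", "B", "B"],
            res_ids=[1, 1, 1, 1],
            elements=["C", "H", "C", "H"],
        )
        cm = residue_contact_map(fr, "A", "B", cutoff=5.0, min_atom_pairs=2)
        assert not cm.matrix.any()  # only the C–C pair qualifies

    def test_missing_chain_rejected(self):
        fr = two_chain_frame()
        with pytest.raises(ValueError, match="absent"):
            residue_contact_map(fr, "A", "Z")


class TestNativeContactFraction:
    def test_native_frame_scores_one(self):
        fr = two_chain_frame(separation=4.0)
        native = residue_contact_map(fr, "A", "B")
        assert native_contact_fraction([fr], native)[0] == 1.0

    def test_separated_chains_score_zero(self):
        fr = two_chain_frame(separation=4.0)
        far = two_chain_frame(separation=100.0)
        native = residue_contact_map(fr, "A", "B")
        assert native_contact_fraction([far], native)[0] == 0.0

    def test_half_preserved_contacts(self):
        fr = two_chain_frame(separation=4.0, n_res=4)
        native = residue_contact_map(fr, "A", "B")
        assert native.n_contacts == 4  # in-register residue pairs
        # move the last two residues of chain B out of range
        moved = two_chain_frame(separation=4.0, n_res=4)
        sel = (moved.chain_ids == "B") & (moved.res_ids >= 3)
        moved.coords[sel] += np.array([50.0, 0, 0])
        assert native_contact_fraction([moved], native)[0] == pytest.approx(0.5)


class TestDebyeHuckel:
    def charged_pair(self, r, res_names=("LYS", "ARG")):
        return make_frame(
            [[0.0, 0, 0], [r, 0, 0]],
            chains=["A", "B"],
            res_ids=[1, 1],
            res_names=list(res_names),
            atom_names=["CB", "CB"],
        )

    def test_no_charges_zero_energy(self):
        fr = self.charged_pair(5.0, res_names=("ALA", "GLY"))
        assert debye_huckel_energy(fr, ElectrostaticParams(eps_r=1.0)) == 0.0

    def test_closed_form_single_pair(self):
        fr = self.charged_pair(10.0)
        e = debye_huckel_energy(fr, ElectrostaticParams(eps_r=1.0, l_d=10.0))
        assert e == pytest.approx(K_ELEC * np.exp(-1.0) / 10.0, abs=1e-9)

    def test_additive_over_pairs(self):
        fr = make_frame(
            [[0.0, 0, 0], [8.0, 0, 0], [0.0, 6.0, 0]],
            chains=["A", "B", "C"],
            res_ids=[1, 1, 1],
            res_names=["LYS", "ARG", "ASP"],
            atom_names=["CB"] * 3,
        )
        params = ElectrostaticParams(eps_r=2.0, l_d=12.0)
        total = debye_huckel_energy(fr, params)

        def pair_energy(q1, q2, r):
            return K_ELEC * q1 * q2 * np.exp(-r / 12.0) / (2.0 * r)

        expected = (
            pair_energy(1, 1, 8.0)
            + pair_energy(1, -1, 6.0)
            + pair_energy(1, -1, 10.0)
        )
        assert total == pytest.approx(expected, abs=1e-9)

    def test_sign_flips_with_one_charge(self):
        attract = self.charged_pair(7.0, res_names=("LYS", "ASP"))
        repel = self.charged_pair(7.0, res_names=("LYS", "ARG"))
        params = ElectrostaticParams(eps_r=1.0)
        ea = debye_huckel_energy(attract, params)
        er = debye_huckel_energy(repel, params)
        assert ea == pytest.approx(-er)

    def test_linear_in_k_elec(self):
        fr = self.charged_pair(9.0)
        e1 = debye_huckel_energy(fr, ElectrostaticParams(k_elec=K_ELEC, eps_r=1.0))
        e2 = debye_huckel_energy(fr, ElectrostaticParams(k_elec=2 * K_ELEC, eps_r=1.0))
        assert e2 == pytest.approx(2 * e1)

    def test_magnitude_decreases_with_distance(self):
        params = ElectrostaticParams(eps_r=1.0, l_d=10.0)
        energies = [
            debye_huckel_energy(self.charged_pair(r), params) for r in (4.0, 8.0, 16.0)
        ]
        assert energies[0] > energies[1] > energies[2] > 0

    def test_coincident_beads_rejected(self):
        fr = self.charged_pair(0.0)
        with pytest.raises(ValueError, match="r_ij = 0"):
            debye_huckel_energy(fr, ElectrostaticParams(eps_r=1.0))

    def test_inter_chain_only_filters_pairs(self):
        fr = make_frame(
            [[0.0, 0, 0], [6.0, 0, 0], [0.0, 8.0, 0]],
            chains=["A", "A", "B"],
            res_ids=[1, 2, 1],
            res_names=["LYS", "ARG", "ASP"],
            atom_names=["CB"] * 3,
        )
        params = ElectrostaticParams(eps_r=1.0, l_d=10.0)
        inter = debye_huckel_energy(fr, params, inter_chain_only=True)
        # only the two A–B pairs remain: (+1,−1) at 8 Å and at 10 Å
        expected = (
            -K_ELEC * np.exp(-0.8) / 8.0 - K_ELEC * np.exp(-1.0) / 10.0
        )
        assert inter == pytest.approx(expected, abs=1e-9)

    def test_debye_length_matches_aqueous_rule_of_thumb(self):
        # 0.304 nm / sqrt(I[M]) for water at 298 K
        ld = debye_length(298.15, 0.1, eps_r=78.5)
        assert ld == pytest.approx(3.04 / np.sqrt(0.1), rel=0.02)

    def test_from_conditions_consistent_with_direct_value(self):
        p = ElectrostaticParams.from_conditions(300.0, 0.1, eps_r=80.0)
        assert p.l_d == pytest.approx(debye_length(300.0, 0.1, 80.0))
        assert 9.0 < p.l_d < 10.5  # the ~10 Å default is this regime


def test_trajectory_summary_columns_and_values(tmp_path):
    fr = two_chain_frame(separation=4.0)
    frames = [fr, rigid_copy(fr, seed=2)]
    table = trajectory_summary(frames, fr, "A", "B")
    assert list(table.columns) == ["frame", "rmsd", "rg", "native_fraction", "dh_energy"]
    assert table.rmsd[0] < 1e-12 and table.rmsd[1] < 1e-8
    assert table.native_fraction.tolist() == [1.0, 1.0]
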