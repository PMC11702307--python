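"""Structural operations: superposition, contacts, placement, energies."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from lynxkit import structure_tools as st
from lynxkit import synthetic_data as sd


def atom(chain, resnum, x, y, z, name="CA", resname="GLY", element="C"):
    return st.Atom(chain, resnum, resname, name, element, x, y, z)


def grid_structure(chain="A", n=3, spacing=1.0, origin=(0.0, 0.0, 0.0)):
    atoms = []
    k = 1
    for i in range(n):
        for j in range(n):
            atoms.append(atom(chain, k, origin[0] + i * spacing, origin[1] + j * spacing, origin[2]))
            k += 1
    return st.Structure(atoms)


def random_rigid(seed):
    rng = np.random.default_rng(seed)
    rotation = Rotation.random(random_state=rng).as_matrix()
    translation = rng.uniform(-20, 20, size=3)
    return rotation, translation


class TestPdbIO:
    def test_single_atom_round_trip(self, tmp_path):
        s = st.Structure([atom("A", 1, 1.234, -5.678, 9.012)])
        path = tmp_path / "one.pdb"
        st.write_pdb(s, path)
        back = st.read_pdb(path)
        assert len(back) == 1
        assert back.atoms[0].key == ("A", 1, "CA")
        assert np.allclose(back.coords, s.coords, atol=5e-4)

    def test_two_chain_complex(self, tmp_path):
        rec, lig, _ = sd.generate_toy_complex(seed=1)
        path = tmp_path / "both.pdb"
        st.write_pdb(st.Structure(rec.atoms + lig.atoms), path)
        back = st.read_pdb(path)
        assert {a.chain for a in back.atoms} == {"R", "L"}
        assert len(back) == len(rec) + len(lig)

    def test_coordinates_written_at_three_decimals(self, tmp_path):
        s = st.Structure([atom("A", 1, 1.23456, 0.0, 0.0)])
        path = tmp_path / "prec.pdb"
        st.write_pdb(s, path)
        # parser returns float32, hence the 1e-5 comparison window
        assert st.read_pdb(path).atoms[0].x == pytest.approx(1.235, abs=1e-5)

    def test_duplicate_atom_keys_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            st.Structure([atom("A", 1, 0, 0, 0), atom("A", 1, 1, 1, 1)])


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        rotation, translation, rmsd = st.kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(rotation, np.eye(3), atol=1e-12)

    def test_pure_translation(self):
        pts = np.random.default_rng(1).normal(size=(20, 3))
        rotation, translation, rmsd = st.kabsch_superpose(pts, pts + [3.0, -1.0, 7.0])
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(translation, [3.0, -1.0, 7.0], atol=1e-9)

    def test_rotation_recovery_with_noise(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(50, 3))
        true_rot, true_trans = random_rigid(3)
        noisy = pts @ true_rot.T + true_trans + rng.normal(0, 0.1, size=pts.shape)
        rotation, _, rmsd = st.kabsch_superpose(pts, noisy)
        # recovered rotation within ~2 degrees of truth for sigma = 0.1
        # noise on 50 unit-scale points, residual RMSD near sigma*sqrt(3)
        relative = rotation.T @ true_rot
        angle = np.degrees(np.arccos(np.clip((np.trace(relative) - 1) / 2, -1, 1)))
        assert angle < 2.0
        assert 0.1 < rmsd < 0.25

    def test_optimality_against_random_transforms(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(15, 3))
        rot, trans = random_rigid(5)
        target = pts @ rot.T + trans + rng.normal(0, 0.3, size=pts.shape)
        _, _, best = st.kabsch_superpose(pts, target)
        for seed in range(20):
            other_rot, other_trans = random_rigid(seed + 100)
            moved = pts @ other_rot.T + other_trans
            other = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
            assert best <= other + 1e-9

    def test_proper_rotation_even_for_reflected_input(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(12, 3))
        mirrored = pts * [-1.0, 1.0, 1.0]
        rotation, _, _ = st.kabsch_superpose(pts, mirrored)
        assert np.linalg.det(rotation) == pytest.approx(1.0, abs=1e-9)

    def test_collinear_degeneracy_flagged(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear"):
            st.kabsch_superpose(line, line + 1.0)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            st.kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


def _two_chain_complex(seed=0):
    rng = np.random.default_rng(seed)
    rec_atoms = [
        atom("A", i + 1, *rng.normal(scale=8, size=3)) for i in range(12)
    ]
    lig_atoms = [
        atom("B", i + 1, *(rng.normal(scale=4, size=3) + [20, 0, 0])) for i in range(8)
    ]
    return st.Structure(rec_atoms + lig_atoms)


class TestChainAlignedRmsd:
    def test_whole_complex_rigid_move_gives_zero(self):
        initial = _two_chain_complex()
        rot, trans = random_rigid(7)
        snapshot = initial.transformed(rot, trans)
        assert st.chain_aligned_rmsd(snapshot, initial, ["A"], "B") == pytest.approx(
            0.0, abs=1e-9
        )

    def test_ligand_translation_passes_through(self):
        initial = _two_chain_complex()
        coords = initial.coords.copy()
        lig_idx = initial.select(chain="B")
        coords[lig_idx] += [0.0, 0.0, 4.5]
        snapshot = initial.with_coords(coords)
        assert st.chain_aligned_rmsd(snapshot, initial, ["A"], "B") == pytest.approx(
            4.5, abs=1e-9
        )

    def test_matches_two_step_decomposition_oracle(self):
        initial = _two_chain_complex()
        rng = np.random.default_rng(8)
        rot, trans = random_rigid(9)
        coords = initial.coords @ rot.T + trans
        lig_idx = initial.select(chain="B")
        coords[lig_idx] += rng.normal(scale=1.0, size=(len(lig_idx), 3))
        snapshot = initial.with_coords(coords)

        value = st.chain_aligned_rmsd(snapshot, initial, ["A"], "B")
        # explicit two-step oracle: superpose on chain A, then plain RMSD on B
        _, rec_snap = snapshot.ca_coords(["A"])
        _, rec_init = initial.ca_coords(["A"])
        rotation, translation, _ = st.kabsch_superpose(rec_snap, rec_init)
        _, lig_snap = snapshot.ca_coords(["B"])
        _, lig_init = initial.ca_coords(["B"])
        moved = lig_snap @ rotation.T + translation
        oracle = float(np.sqrt(np.mean(np.sum((moved - lig_init) ** 2, axis=1))))
        assert value == pytest.approx(oracle, rel=1e-12)

    def test_chain_mismatch_rejected(self):
        initial = _two_chain_complex()
        with pytest.raises(ValueError):
            st.chain_aligned_rmsd(initial, initial, ["A"], "Z")


class TestBadContacts:
    def test_distant_structures(self):
        a = grid_structure("A")
        b = grid_structure("B", origin=(100.0, 0.0, 0.0))
        assert st.count_bad_contacts(a, b, cutoff=3.0) == 0

    def test_coincident_atoms(self):
        a = st.Structure([atom("A", 1, 0, 0, 0)])
        b = st.Structure([atom("B", 1, 0, 0, 0)])
        assert st.count_bad_contacts(a, b, cutoff=3.0) == 1

    def test_grid_overlap_matches_hand_enumeration(self):
        a = grid_structure("A", n=3, spacing=2.0)
        b = grid_structure("B", n=3, spacing=2.0, origin=(1.0, 0.0, 0.0))
        cutoff = 2.5
        brute = sum(
            1
            for pa in a.atoms
            for pb in b.atoms
            if np.linalg.norm(np.subtract((pa.x, pa.y, pa.z), (pb.x, pb.y, pb.z))) < cutoff
        )
        assert st.count_bad_contacts(a, b, cutoff=cutoff) == brute

    def test_hydrogens_excluded_and_strict_inequality(self):
        a = st.Structure([atom("A", 1, 0, 0, 0, name="H1", element="H")])
        b = st.Structure([atom("B", 1, 0, 0, 0)])
        assert st.count_bad_contacts(a, b, cutoff=3.0) == 0
        c = st.Structure([atom("C", 1, 3.0, 0, 0)])
        d = st.Structure([atom("D", 1, 0, 0, 0)])
        assert st.count_bad_contacts(c, d, cutoff=3.0) == 0  # distance == cutoff


class TestPlacementSearch:
    def test_clash_free_ligand_keeps_offset_zero(self):
        rec, lig, truth = sd.generate_toy_complex(clashes_per_offset=(0, 0, 0), seed=11)
        result = st.outward_placement_search(
            rec, lig, truth["receptor_surface_indices"], truth["ligand_surface_indices"],
            cutoff=truth["clash_cutoff"],
        )
        assert result.chosen_offset == 0.0
        assert result.clash_counts == (0, 0, 0)

    def test_planted_optimum_recovered_over_seeds(self):
        profiles = [(6, 3, 0), (5, 2, 1), (4, 4, 2), (7, 0, 0), (3, 1, 1)]
        for seed in range(50):
            profile = profiles[seed % len(profiles)]
            rec, lig, truth = sd.generate_toy_complex(
                clashes_per_offset=profile, seed=seed
            )
            result = st.outward_placement_search(
                rec, lig,
                truth["receptor_surface_indices"], truth["ligand_surface_indices"],
                cutoff=truth["clash_cutoff"],
            )
            assert result.clash_counts == tuple(truth["planted_clashes_per_offset"])
            assert result.chosen_offset == truth["optimal_offset"]
            assert min(result.clash_counts) == result.clash_counts[
                result.offsets.index(result.chosen_offset)
            ]

    def test_tie_resolves_to_smallest_offset(self):
        # ligand far away: all offsets give zero clashes -> offset 0
        rec = grid_structure("A")
        lig = grid_structure("B", origin=(50.0, 0.0, 0.0))
        result = st.outward_placement_search(rec, lig, [0], [0], cutoff=3.0)
        assert result.chosen_offset == 0.0

    def test_coincident_centroids_rejected(self):
        rec = grid_structure("A")
        lig = grid_structure("B")
        with pytest.raises(ValueError, match="coincident"):
            st.outward_placement_search(rec, lig, [0], [0])


class TestInteractionEnergy:
    def _params(self, charges=None):
        return st.NonbondedParams(
            elements={"C": {"sigma": 3.4, "epsilon": 0.09}}, charges=charges or {}
        )

    def test_lj_zero_at_sigma(self):
        a = st.Structure([atom("A", 1, 0, 0, 0)])
        b = st.Structure([atom("B", 1, 3.4, 0, 0)])
        assert st.interaction_energy(a, b, self._params()).vdw_energy == pytest.approx(0.0)

    def test_lj_minimum_depth(self):
        a = st.Structure([atom("A", 1, 0, 0, 0)])
        b = st.Structure([atom("B", 1, 3.4 * 2 ** (1 / 6), 0, 0)])
        assert st.interaction_energy(a, b, self._params()).vdw_energy == pytest.approx(-0.09)

    def test_coulomb_constant_arithmetic(self):
        params = st.NonbondedParams(
            elements={"C": {"sigma": 3.4, "epsilon": 0.0}},
            charges={("A", 1, "CA"): 1.0, ("B", 1, "CA"): 1.0},
        )
        a = st.Structure([atom("A", 1, 0, 0, 0)])
        b = st.Structure([atom("B", 1, 3.3206, 0, 0)])
        report = st.interaction_energy(a, b, params)
        assert report.electrostatic_energy == pytest.approx(100.0)
        assert report.total_energy == report.vdw_energy + report.electrostatic_energy

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(13)
        a = st.Structure([
            atom("A", i + 1, *rng.uniform(0, 15, 3), element=e)
            for i, e in enumerate(rng.choice(["C", "N", "O", "S"], size=90))
        ])
        b = st.Structure([
            atom("B", i + 1, *(rng.uniform(0, 15, 3) + [6.0, 0, 0]), element=e)
            for i, e in enumerate(rng.choice(["C", "N", "O"], size=80))
        ])
        params = st.NonbondedParams.bundled()
        charges = {at.key: float(q) for at, q in zip(
            a.atoms + b.atoms, rng.uniform(-0.5, 0.5, size=len(a) + len(b))
        )}
        params = st.NonbondedParams(params.elements, params.default, charges)
        cutoff = 10.0
        report = st.interaction_energy(a, b, params, cutoff=cutoff)

        vdw = elec = 0.0
        for pa in a.atoms:
            for pb in b.atoms:
                r = float(np.linalg.norm(np.subtract((pa.x, pa.y, pa.z), (pb.x, pb.y, pb.z))))
                if r > cutoff:
                    continue
                s1, e1 = params.lj(pa.element)
                s2, e2 = params.lj(pb.element)
                sig, eps = 0.5 * (s1 + s2), np.sqrt(e1 * e2)
                vdw += 4 * eps * ((sig / r) ** 12 - (sig / r) ** 6)
                elec += st.COULOMB_CONSTANT * params.charge(pa) * params.charge(pb) / r
        assert report.vdw_energy == pytest.approx(vdw, rel=1e-9)
        assert report.electrostatic_energy == pytest.approx(elec, rel=1e-9)

    def test_vanishes_at_large_separation(self):
        a = grid_structure("A")
        b = grid_structure("B", origin=(500.0, 0.0, 0.0))
        report = st.interaction_energy(a, b)
        assert report.total_energy == 0.0


class TestPolarContacts:
    def test_distant_atoms_empty(self):
        a = st.Structure([atom("A", 1, 0, 0, 0, name="N", element="N")])
        b = st.Structure([atom("B", 1, 10, 0, 0, name="O", element="O")])
        assert st.detect_hbonds(a, b) == []
        assert st.detect_salt_bridges(a, b) == []

    def test_constructed_salt_bridge(self):
        a = st.Structure([atom("A", 1, 0, 0, 0, name="OE1", resname="GLU", element="O")])
        b = st.Structure([atom("B", 1, 3.0, 0, 0, name="NZ", resname="LYS", element="N")])
        (bridge,) = st.detect_salt_bridges(a, b)
        assert bridge[2] == pytest.approx(3.0)

    def test_hbond_boundary_inclusive(self):
        donor = st.Structure([atom("A", 1, 0, 0, 0, name="N", resname="ALA", element="N")])
        at_cut = st.Structure([atom("B", 1, 3.5, 0, 0, name="O", resname="ALA", element="O")])
        past_cut = st.Structure([atom("B", 1, 3.51, 0, 0, name="O", resname="ALA", element="O")])
        assert len(st.detect_hbonds(donor, at_cut)) == 1
        assert st.detect_hbonds(donor, past_cut) == []

    def test_carbon_pairs_never_polar(self):
        a = st.Structure([atom("A", 1, 0, 0, 0)])
        b = st.Structure([atom("B", 1, 3.0, 0, 0)])
        assert st.detect_hbonds(a, b) == []


class TestRigidInvariance:
    def test_all_descriptors_invariant_under_common_rigid_transform(self):
        rec, lig, truth = sd.generate_toy_complex(seed=21)
        params = st.NonbondedParams.bundled()
        before = (
            st.count_bad_contacts(rec, lig, 3.0),
            st.interaction_energy(rec, lig, params).total_energy,
            len(st.detect_hbonds(rec, lig)),
        )
        rot, trans = random_rigid(22)
        rec_t = rec.transformed(rot, trans)
        lig_t = lig.transformed(rot, trans)
        after = (
            st.count_bad_contacts(rec_t, lig_t, 3.0),
            st.interaction_energy(rec_t, lig_t, params).total_energy,
            len(st.detect_hbonds(rec_t, lig_t)),
        )
        assert before[0] == after[0]
        assert before[1] == pytest.approx(after[1], rel=1e-6)
        assert before[2] == after[2]
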