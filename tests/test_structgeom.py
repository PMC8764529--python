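"""Geometry module: parsing, planes, H-bonds, contacts, superposition."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cofkit import structgeom as sg
from cofkit import synthdata as sd
from cofkit.errors import (
    DegenerateGeometryError,
    EmptyStructureError,
    InsufficientPointsError,
    PDBParseError,
    SelectorError,
    SerializationError,
)
from conftest import random_structure
from oracles import (
    brute_contacts,
    brute_hbond_pairs,
    brute_metal_shell,
    random_rigid_motions,
)

ONE_ATOM_PDB = (
    "ATOM      1  N   SER A 162       1.000   2.000   3.000  1.00 10.00"
    "           N\nEND\n"
)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

class TestPDBIO:
    def test_single_atom_fields(self):
        m = sg.read_pdb(ONE_ATOM_PDB)
        assert len(m) == 1
        a = m.atoms[0]
        assert (a.name, a.chain, a.res_name, a.res_num) == ("N", "A", "SER", 162)
        assert a.coords == (1.0, 2.0, 3.0)
        assert not a.is_hetero

    def test_first_model_only(self):
        text = ("MODEL        1\n" + ONE_ATOM_PDB.replace("END\n", "ENDMDL\n")
                + "MODEL        2\n"
                + ONE_ATOM_PDB.replace("   1.000", "   9.000").replace("END\n", "ENDMDL\n")
                + "END\n")
        m = sg.read_pdb(text)
        assert len(m) == 1
        assert m.atoms[0].coords[0] == 1.0

    def test_malformed_record_names_line(self):
        bad = ONE_ATOM_PDB.replace("   3.000", "   x.000")
        with pytest.raises(PDBParseError, match="line 1"):
            sg.read_pdb(bad)

    def test_no_atoms_is_an_error(self):
        with pytest.raises(EmptyStructureError):
            sg.read_pdb("REMARK nothing here\nEND\n")

    def test_altloc_keeps_highest_occupancy_then_letter(self):
        text = (
            "ATOM      1  CA ASER A   1       0.000   0.000   0.000  0.40 10.00           C\n"
            "ATOM      2  CA BSER A   1       1.000   0.000   0.000  0.60 10.00           C\n"
            "ATOM      3  CB ASER A   1       0.000   1.000   0.000  0.50 10.00           C\n"
            "ATOM      4  CB BSER A   1       0.000   2.000   0.000  0.50 10.00           C\n"
            "END\n")
        m = sg.read_pdb(text)
        by_name = {a.name: a for a in m.atoms}
        assert by_name["CA"].coords[0] == 1.0        # occupancy 0.60 wins
        assert by_name["CB"].coords[1] == 1.0        # tie -> alt-loc A wins

    def test_hetero_mg_written_as_hetatm(self):
        a = sg.Atom(serial=1, name="MG", element="Mg", alt_loc="", chain="A",
                    res_name="MG", res_num=301, insertion_code="",
                    coords=(1.0, 2.0, 3.0), occupancy=1.0, is_hetero=True)
        text = sg.write_pdb(sg.StructureModel(atoms=[a]))
        assert "HETATM" in text
        assert "MG" in text

    def test_atom_name_too_long(self):
        a = sg.Atom(serial=1, name="TOOLONG", element="C", alt_loc="",
                    chain="A", res_name="GLY", res_num=1, insertion_code="",
                    coords=(0.0, 0.0, 0.0))
        with pytest.raises(SerializationError):
            sg.write_pdb(sg.StructureModel(atoms=[a]))

    def test_random_roundtrip_coordinates(self, rng):
        m = random_structure(rng, 100)
        m2 = sg.read_pdb(sg.write_pdb(m))
        assert len(m2) == len(m)
        err = np.abs(m.coords() - m2.coords()).max()
        assert err < 5e-4
        # identity of the atom table, not just coordinates
        for a, b in zip(m.atoms, m2.atoms):
            assert (a.name, a.chain, a.res_name, a.res_num) == \
                   (b.name, b.chain, b.res_name, b.res_num)
            assert a.occupancy == pytest.approx(b.occupancy, abs=5e-3)

    def test_generated_pocket_roundtrip(self, toy_pocket):
        model, _ = toy_pocket
        m2 = sg.read_pdb(sg.write_pdb(model))
        assert np.abs(model.coords() - m2.coords()).max() < 5e-4


# ---------------------------------------------------------------------------
# planes
# ---------------------------------------------------------------------------

class TestPlanes:
    def test_exact_triangle(self):
        p = sg.fit_plane([(0, 0, 0), (1, 0, 0), (0, 1, 0)])
        assert abs(abs(p.normal[2]) - 1.0) < 1e-12
        assert p.rms_residual == 0.0

    def test_square_centroid(self):
        pts = [(0, 0, 0), (2, 0, 0), (2, 2, 0), (0, 2, 0)]
        p = sg.fit_plane(pts)
        assert p.rms_residual == 0.0
        assert np.allclose(p.centroid, [1, 1, 0])

    def test_normal_unit_length(self, rng):
        pts = rng.normal(0, 3, (12, 3))
        p = sg.fit_plane(pts)
        assert abs(np.linalg.norm(p.normal) - 1.0) < 1e-9

    def test_noisy_fit_never_beaten(self, rng):
        """TLS residual is minimal over many perturbed candidate planes."""
        pts = np.column_stack([rng.uniform(-5, 5, 10), rng.uniform(-5, 5, 10),
                               rng.normal(0, 0.1, 10)])
        p = sg.fit_plane(pts)
        recomputed = np.sqrt(np.mean(((pts - p.centroid) @ p.normal) ** 2))
        assert p.rms_residual == pytest.approx(recomputed, abs=1e-12)
        for _ in range(500):
            n = p.normal + rng.normal(0, 0.05, 3)
            n /= np.linalg.norm(n)
            c = p.centroid + rng.normal(0, 0.05, 3)
            rms = np.sqrt(np.mean(((pts - c) @ n) ** 2))
            assert p.rms_residual <= rms + 1e-12

    def test_collinear_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            sg.fit_plane([(0, 0, 0), (1, 1, 1), (2, 2, 2), (3, 3, 3)])

    def test_out_of_plane_distance_constructed(self):
        p = sg.fit_plane([(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0)])
        assert sg.out_of_plane_distance(p, (5, -2, 1.38)) == pytest.approx(1.38)
        assert sg.out_of_plane_distance(p, (0.3, 0.7, 0)) == pytest.approx(0.0)

    def test_rigid_motion_invariance(self, rng):
        pts = rng.normal(0, 2, (8, 3))
        pts[:, 2] *= 0.05
        point = rng.normal(0, 3, 3)
        d0 = sg.out_of_plane_distance(sg.fit_plane(pts), point)
        r0 = sg.fit_plane(pts).rms_residual
        for seed in range(20):
            rot = Rotation.random(random_state=seed).as_matrix()
            t = rng.normal(0, 10, 3)
            d = sg.out_of_plane_distance(sg.fit_plane(pts @ rot.T + t),
                                         rot @ point + t)
            r = sg.fit_plane(pts @ rot.T + t).rms_residual
            assert abs(d - d0) < 1e-9
            assert abs(r - r0) < 1e-9


# ---------------------------------------------------------------------------
# H-bonds and distortion
# ---------------------------------------------------------------------------

def _mini_pocket(donor_distance):
    spec = sd.PocketSpec(n_donors=1, planted_pi_offsets=(0.0,),
                         hbond_distance=2.9, seed=0)
    model, truth = sd.make_pocket(spec)
    if donor_distance != 2.9:
        # push the donor radially to the requested distance
        from dataclasses import replace
        lig_o = next(a for a in model.atoms if a.name == "O1")
        donor = next(a for a in model.atoms if a.name == "N")
        v = donor.xyz - lig_o.xyz
        v *= donor_distance / np.linalg.norm(v)
        new = replace(donor, coords=tuple(lig_o.xyz + v))
        model.atoms[model.atoms.index(donor)] = new
    return model, truth


class TestHBonds:
    def test_donor_inside_cutoff_detected(self):
        model, truth = _mini_pocket(2.9)
        hb = sg.detect_hbonds(model, truth["ligand"])
        assert len(hb) == 1
        assert hb[0].heavy_distance == pytest.approx(2.9, abs=1e-6)

    def test_donor_outside_cutoff_rejected(self):
        model, truth = _mini_pocket(3.8)
        assert sg.detect_hbonds(model, truth["ligand"],
                                max_heavy_distance=3.5) == []

    def test_missing_ligand_raises(self):
        model, _ = _mini_pocket(2.9)
        with pytest.raises(SelectorError):
            sg.detect_hbonds(model, ("Z", "XXX", 1))

    def test_planted_offsets_recovered(self, toy_pocket):
        model, truth = toy_pocket
        hb = sg.detect_hbonds(model, truth["ligand"])
        got = sorted(h.pi_distance for h in hb)
        want = sorted(x["pi_offset"] for x in truth["hbonds"])
        assert got == pytest.approx(want, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        offs = tuple(np.round(rng.uniform(0.0, 2.0, rng.integers(1, 5)), 3))
        spec = sd.PocketSpec(n_donors=len(offs), planted_pi_offsets=offs,
                             n_metals=int(rng.integers(0, 3)),
                             chains=int(rng.integers(1, 3)),
                             jitter_sd=0.05, seed=seed)
        model, truth = sd.make_pocket(spec)
        hb = sg.detect_hbonds(model, truth["ligand"], 3.5, 2.4)
        got = {frozenset((h.donor.serial, h.acceptor.serial)) for h in hb}
        want = brute_hbond_pairs(model, truth["ligand"], 3.5, 2.4)
        assert got == want

    def test_average_distortion(self):
        def mk(d):
            return sg.HBondGeometry(donor=None, acceptor=None,
                                    heavy_distance=3.0,
                                    pi_group=object(), pi_distance=d)
        assert sg.average_pi_distortion([mk(0.5), mk(1.5)]) == pytest.approx(1.0)
        assert sg.average_pi_distortion([mk(0.74)]) == pytest.approx(0.74)
        no_pi = sg.HBondGeometry(donor=None, acceptor=None, heavy_distance=3.0)
        with pytest.raises(SelectorError):
            sg.average_pi_distortion([no_pi])


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

class TestContacts:
    def test_two_chain_mean(self):
        spec = sd.PocketSpec(n_donors=1, planted_pi_offsets=(0.5,),
                             chains=2, jitter_sd=0.0, seed=0)
        model, truth = sd.make_pocket(spec)
        recs = sg.contact_table(model, truth["ligand_res_name"], cutoff=4.0)
        assert recs
        for r in recs:
            assert set(r.per_chain_distances) == {"A", "B"}
            assert r.mean_distance == pytest.approx(
                np.mean(list(r.per_chain_distances.values())), abs=1e-9)
            a, b = r.per_chain_distances["A"], r.per_chain_distances["B"]
            assert a == pytest.approx(b, abs=1e-9)   # jitter 0: identical chains

    def test_absent_ligand_raises(self, toy_pocket):
        model, _ = toy_pocket
        with pytest.raises(SelectorError):
            sg.contact_table(model, "ZZZ")

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_bruteforce(self, seed):
        rng = np.random.default_rng(100 + seed)
        offs = tuple(np.round(rng.uniform(0.0, 1.5, rng.integers(1, 4)), 3))
        spec = sd.PocketSpec(n_donors=len(offs), planted_pi_offsets=offs,
                             n_metals=1, chains=int(rng.integers(1, 3)),
                             jitter_sd=0.1, seed=seed)
        model, truth = sd.make_pocket(spec)
        recs = sg.contact_table(model, truth["ligand_res_name"], 4.0, 3.5)
        got = {(r.protein_residue[2], r.protein_atom, r.ligand_atom):
               {c: round(d, 9) for c, d in r.per_chain_distances.items()}
               for r in recs}
        want_raw = brute_contacts(model, truth["ligand_res_name"], 4.0, 3.5)
        want = {k: {c: round(d, 9) for c, (d, _) in v.items()}
                for k, v in want_raw.items()}
        assert got == want

    def test_output_order_deterministic(self, toy_pocket):
        model, truth = toy_pocket
        recs = sg.contact_table(model, truth["ligand_res_name"])
        keys = [(r.protein_residue[2], r.protein_atom, r.ligand_atom)
                for r in recs]
        assert keys == sorted(keys)


# ---------------------------------------------------------------------------
# superposition & pose comparison
# ---------------------------------------------------------------------------

class TestSuperposition:
    def test_identity(self, rng):
        pts = rng.normal(0, 5, (6, 3))
        s = sg.superpose_kabsch(pts, pts)
        assert np.allclose(s.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(s.translation, 0, atol=1e-12)
        assert s.rmsd < 1e-12

    def test_recovers_constructed_motion(self, rng):
        ref = rng.normal(0, 5, (8, 3))
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        mov = (ref - np.array([1, 1, 1])) @ rot   # ref = rot @ mov + (1,1,1)
        s = sg.superpose_kabsch(ref, mov)
        assert s.rmsd < 1e-9
        assert np.allclose(s.apply(mov), ref, atol=1e-9)
        assert abs(np.linalg.det(s.rotation) - 1.0) < 1e-9
        assert np.linalg.norm(s.rotation.T @ s.rotation - np.eye(3)) < 1e-9

    def test_never_beaten_by_random_motions(self, rng):
        ref = rng.normal(0, 3, (4, 3))
        mov = ref + rng.normal(0, 0.1, (4, 3))
        s = sg.superpose_kabsch(ref, mov)
        rots, trans = random_rigid_motions(rng, 1000)
        for R, t in zip(rots, trans):
            rmsd = np.sqrt(np.mean(np.sum((mov @ R.T + t - ref) ** 2, axis=1)))
            assert s.rmsd <= rmsd + 1e-12

    def test_matches_scipy_align_vectors(self, rng):
        """Cross-check the optimum against an independent library solver."""
        ref = rng.normal(0, 3, (10, 3))
        mov = ref @ Rotation.random(random_state=5).as_matrix() + 2.0
        mov += rng.normal(0, 0.05, mov.shape)
        s = sg.superpose_kabsch(ref, mov)
        rot_sp, _ = Rotation.align_vectors(ref - ref.mean(0), mov - mov.mean(0))
        moved = (mov - mov.mean(0)) @ rot_sp.as_matrix().T + ref.mean(0)
        rmsd_sp = np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1)))
        assert s.rmsd == pytest.approx(rmsd_sp, abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(InsufficientPointsError):
            sg.superpose_kabsch(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_flagged_unstable(self):
        ref = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0.0]])
        with pytest.warns(RuntimeWarning):
            s = sg.superpose_kabsch(ref, ref)
        assert not s.stable


class TestPoseComparison:
    def test_zero_rotation(self):
        la, lb, _ = sd.make_ligand_pair(rotation_deg=0.0)
        assert sg.carboxylate_rotation(la, lb).angle_deg == pytest.approx(0.0, abs=1e-9)

    def test_constructed_36_degrees(self):
        la, lb, _ = sd.make_ligand_pair(rotation_deg=36.0)
        assert sg.carboxylate_rotation(la, lb).angle_deg == pytest.approx(36.0, abs=1e-6)

    def test_angle_is_unsigned(self):
        la, lb, _ = sd.make_ligand_pair(rotation_deg=-36.0)
        assert sg.carboxylate_rotation(la, lb).angle_deg == pytest.approx(36.0, abs=1e-6)

    def test_hundred_seeded_angles_recovered(self):
        rng = np.random.default_rng(42)
        for theta in rng.uniform(-360, 360, 100):
            la, lb, truth = sd.make_ligand_pair(rotation_deg=float(theta))
            got = sg.carboxylate_rotation(la, lb).angle_deg
            assert got == pytest.approx(truth["angle_deg"], abs=1e-6)

    def test_on_axis_reference_rejected(self):
        la, lb, _ = sd.make_ligand_pair(rotation_deg=10.0)
        mid_atom = dict(la)
        mid_atom["MID"] = (np.asarray(la["O1"]) + np.asarray(la["O2"])) / 2
        lb2 = dict(lb)
        lb2["MID"] = mid_atom["MID"]
        with pytest.raises(DegenerateGeometryError):
            sg.carboxylate_rotation(mid_atom, lb2, reference_atom="MID")

    def test_displacement_translation(self):
        la, _, _ = sd.make_ligand_pair(rotation_deg=0.0)
        lb = {k: np.asarray(v) + [0, 0, 2.5] for k, v in la.items()}
        assert sg.group_displacement(la, lb, "P1") == pytest.approx(2.5)
        assert sg.group_displacement(la, la, "P1") == pytest.approx(0.0)

    def test_displacement_matches_chord_formula(self):
        """A point r off the axis rotated by theta moves 2 r sin(theta/2)."""
        la = {"O1": (0, 0, 0), "O2": (0, 0, 2.164), "C2": (1.0, 0, 1.0),
              "P": (4.0, 0.0, 1.0)}    # P exactly 4 A off the O-O (z) axis
        la_, lb, _ = sd.make_ligand_pair(la, rotation_deg=36.0,
                                         displacement_target_atom="P")
        chord = 2 * 4.0 * math.sin(math.radians(18.0))
        assert sg.group_displacement(la_, lb, "P") == pytest.approx(chord, abs=1e-9)

    def test_missing_atom_raises(self):
        la, lb, _ = sd.make_ligand_pair(rotation_deg=5.0)
        with pytest.raises(SelectorError):
            sg.group_displacement(la, lb, "NOPE")


# ---------------------------------------------------------------------------
# metal coordination
# ---------------------------------------------------------------------------

class TestMetals:
    def test_octahedral_shell_complete(self):
        spec = sd.PocketSpec(n_donors=1, planted_pi_offsets=(0.0,),
                             n_metals=1, seed=0)
        model, _ = sd.make_pocket(spec)
        sites = sg.metal_coordination(model, "MG", 2.8)
        assert len(sites) == 1
        assert len(sites[0].coordinating) == 6
        for _, d, src in sites[0].coordinating:
            assert d == pytest.approx(2.1, abs=1e-9)
            assert src == "water"

    def test_cutoff_excludes(self):
        spec = sd.PocketSpec(n_donors=1, planted_pi_offsets=(0.0,),
                             n_metals=1, seed=0)
        model, _ = sd.make_pocket(spec)
        sites = sg.metal_coordination(model, "MG", 2.0)
        assert sites[0].coordinating == []

    def test_absent_metal_empty_list(self, toy_pocket):
        model, _ = toy_pocket
        assert sg.metal_coordination(model, "ZN") == []

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_bruteforce(self, seed):
        spec = sd.PocketSpec(n_donors=2, planted_pi_offsets=(0.3, 1.1),
                             n_metals=2, chains=2, jitter_sd=0.2, seed=seed)
        model, _ = sd.make_pocket(spec)
        sites = sg.metal_coordination(model, "MG", 2.8)
        got = {s.metal.serial: {(a.serial, round(d, 9))
                                for a, d, _ in s.coordinating}
               for s in sites}
        assert got == brute_metal_shell(model, "MG", 2.8)
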