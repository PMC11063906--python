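"""Glycan geometry: dihedrals, glycosidic torsions, ring puckering,
detection and the active-site overlay."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gemmi

from endofc.errors import MissingAtomError, NoGlycanError
from endofc.fixtures import (
    make_disaccharide, make_nlinked_glycan, make_ring, make_ring_coords,
    write_fixture,
)
from endofc.glycan import (
    CANONICAL_CONFORMERS, classify_conformer, cremer_pople, detect_glycan,
    dihedral, glycosidic_torsions, ring_pucker,
)
from endofc.model import read_structure
from endofc.superpose import RigidTransform


def _random_points(seed, n=4, scale=3.0):
    return np.random.default_rng(seed).normal(size=(n, 3)) * scale


class TestDihedral:
    def test_constructed_angle_is_recovered(self):
        # four points built with an exact 5.9° twist about the central bond
        th = np.radians(5.9)
        p = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 0.0], [0.0, 1.5, 0.0],
                      [np.cos(th), 1.5, -np.sin(th)]])
        assert dihedral(*p) == pytest.approx(5.9, abs=1e-6)

    def test_anti_periplanar_is_180(self):
        p = np.array([[1.0, 0, 0], [0, 0, 0], [0, 1.5, 0], [-1.0, 1.5, 0]])
        assert abs(dihedral(*p)) == pytest.approx(180.0, abs=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_gemmi_reference(self, seed):
        p = _random_points(seed)
        ref = np.degrees(gemmi.calculate_dihedral(*[gemmi.Position(*x) for x in p]))
        assert dihedral(*p) == pytest.approx(ref, abs=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_rigid_invariance_and_reversal_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.normal(size=(4, 3)) * 3
        base = dihedral(*p)
        tf = RigidTransform.from_axis_angle(rng.normal(size=3),
                                            rng.uniform(0, 180),
                                            translation=rng.uniform(-9, 9, 3))
        moved = tf.apply(p)
        assert dihedral(*moved) == pytest.approx(base, abs=1e-9)
        rev = dihedral(*p[::-1])
        assert rev == pytest.approx(base, abs=1e-9)  # symmetric under full reversal
        swapped = dihedral(p[0], p[2], p[1], p[3])   # central-bond flip negates
        # (only check sign when well away from 0/180)
        if 5 < abs(base) < 175:
            assert np.sign(swapped) == -np.sign(base)


class TestGlycosidicTorsions:
    @pytest.mark.parametrize("phi,psi", [(5.9, -120.0), (-74.0, -120.0), (-59.0, 0.0)])
    def test_disaccharide_construction_recovers_exact_angles(self, phi, psi):
        struct, truth = make_disaccharide(phi, psi)
        donor = struct.chains[0].residues[1]
        acceptor = struct.chains[0].residues[0]
        got_phi, got_psi = glycosidic_torsions(donor, acceptor, "O4")
        assert got_phi == pytest.approx(phi, abs=1e-3)
        assert got_psi == pytest.approx(psi, abs=1e-3)

    def test_missing_atom_is_named_in_error(self):
        struct, _ = make_disaccharide(10.0, 20.0)
        donor = struct.chains[0].residues[1]
        acceptor = struct.chains[0].residues[0]
        donor.atoms = [a for a in donor.atoms if a.atom_name != "O5"]
        with pytest.raises(MissingAtomError, match="O5"):
            glycosidic_torsions(donor, acceptor, "O4")

    def test_hydrogen_convention_requires_h1(self):
        struct, _ = make_disaccharide(10.0, 20.0)
        donor = struct.chains[0].residues[1]
        acceptor = struct.chains[0].residues[0]
        with pytest.raises(MissingAtomError):
            glycosidic_torsions(donor, acceptor, "O4", convention="hydrogen")


class TestCremerPople:
    def test_planar_hexagon_has_zero_amplitude(self):
        ang = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        ring = np.column_stack([np.cos(ang), np.sin(ang), np.zeros(6)]) * 1.45
        assert cremer_pople(ring).Q < 1e-6

    def test_ideal_chair_is_4c1(self):
        ring = make_ring("4C1")
        p = cremer_pople(ring)
        assert p.theta == pytest.approx(0.0, abs=1.0)
        assert p.conformer_label == "4C1"

    def test_skew_boat_parameters_recovered(self):
        ring = make_ring_coords(0.6, 90.0, 210.0)
        p = cremer_pople(ring)
        assert p.Q == pytest.approx(0.6, abs=0.01)
        assert p.theta == pytest.approx(90.0, abs=1.0)
        assert p.phi2 == pytest.approx(210.0, abs=1.0)
        assert p.conformer_label == "1S3"

    @pytest.mark.parametrize("label,theta,phi2", CANONICAL_CONFORMERS)
    def test_forward_inverse_identity_on_canonical_set(self, label, theta, phi2):
        ring = make_ring_coords(0.55, theta, phi2)
        p = cremer_pople(ring)
        assert p.Q == pytest.approx(0.55, abs=0.01)
        if 1.0 < theta < 179.0:      # φ2 undefined at the poles
            dphi = (p.phi2 - phi2 + 180.0) % 360.0 - 180.0
            assert abs(dphi) < 1.0
        assert p.theta == pytest.approx(theta, abs=1.0)
        assert classify_conformer(p.theta, p.phi2) == label

    def test_wrong_atom_count_raises(self):
        with pytest.raises(ValueError):
            cremer_pople(np.zeros((5, 3)))

    def test_unknown_label_raises(self):
        with pytest.raises(ValueError):
            make_ring("7C9")


class TestDetectGlycan:
    def test_single_sugar_tree(self):
        struct, _ = make_nlinked_glycan(n_core=1, fucose=False)
        tree = detect_glycan(struct, ("A", 297))
        assert [g.code for g in tree.residues] == ["NAG"]
        # only the Asn attachment, no inter-sugar linkage
        assert [l.acceptor_atom for l in tree.linkages] == ["ND2"]

    def test_two_sugar_chain_has_one_o4_linkage(self):
        struct, truth = make_nlinked_glycan(n_core=2, fucose=False,
                                            phi=5.9, psi=-120.0)
        tree = detect_glycan(struct, ("A", 297))
        core = [l for l in tree.linkages if l.acceptor_atom == "O4"]
        assert len(core) == 1
        assert core[0].linkage_type == "1-4"
        assert core[0].phi == pytest.approx(5.9, abs=1e-3)
        assert core[0].psi == pytest.approx(-120.0, abs=1e-3)

    def test_fucose_attaches_via_o6(self):
        struct, _ = make_nlinked_glycan(n_core=2, fucose=True)
        tree = detect_glycan(struct, ("A", 297))
        codes = sorted(g.code for g in tree.residues)
        assert codes == ["FUC", "NAG", "NAG"]
        fuc = next(l for l in tree.linkages if l.donor.code == "FUC")
        assert fuc.acceptor_atom == "O6" and fuc.linkage_type == "1-6"

    def test_detection_independent_of_record_order(self, tmp_path):
        struct, _ = make_nlinked_glycan(n_core=3, fucose=True)
        p1 = write_fixture(struct, tmp_path / "fwd.pdb")
        tree1 = detect_glycan(read_structure(p1), ("A", 297))
        struct.chains[0].residues = list(reversed(struct.chains[0].residues))
        p2 = write_fixture(struct, tmp_path / "rev.pdb")
        tree2 = detect_glycan(read_structure(p2), ("A", 297))
        key = lambda t: sorted((g.code, g.seq_id) for g in t.residues)
        assert key(tree1) == key(tree2)
        links = lambda t: sorted((l.donor.seq_id, l.acceptor_atom,
                                  round(l.phi, 3), round(l.psi, 3))
                                 for l in t.linkages)
        assert links(tree1) == links(tree2)

    def test_no_sugar_near_asn_raises(self):
        struct, _ = make_nlinked_glycan(n_core=1, fucose=False)
        # move the sugar far away
        for res in struct.chains[0].residues:
            if res.name == "NAG":
                for a in res.atoms:
                    a.coords = a.coords + 100.0
        with pytest.raises(NoGlycanError):
            detect_glycan(struct, ("A", 297))

    def test_ring_pucker_of_generated_sugar_is_chair(self):
        struct, _ = make_nlinked_glycan(n_core=2, fucose=False)
        for res in struct.chains[0].residues:
            if res.name == "NAG":
                assert ring_pucker(res).conformer_label == "4C1"


class TestActiveSiteGeometry:
    def test_self_overlay_places_dyad_at_constructed_distance(self, binding_study):
        from endofc.glycan import active_site_geometry
        structures, truth = binding_study
        rep = active_site_geometry(
            structures["complex"], "A", structures["wt_enzyme"], "A",
            (46, 386), [184, 186],
            linkage_oxygen=("C", 401, "O4"),
        )
        assert rep.gh_fit_rmsd == pytest.approx(0.0, abs=1e-9)
        assert rep.distances["GLU186:OE1->O4"] == pytest.approx(
            truth["dyad_min_distance_A"], abs=1e-6)

    def test_missing_dyad_raises(self, binding_study):
        from endofc.glycan import active_site_geometry
        structures, _ = binding_study
        with pytest.raises(MissingAtomError):
            active_site_geometry(
                structures["complex"], "A", structures["unliganded"], "A",
                (46, 386), [184], linkage_oxygen=("C", 401, "O4"))
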