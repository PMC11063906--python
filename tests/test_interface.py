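"""SASA against closed forms and an independent engine; interface areas,
solvation energy, contacts and hydrogen bonds."""

import numpy as np
import pytest

from endofc.errors import UnknownElementError
from endofc.fixtures import make_sphere_cluster, sphere_area, two_sphere_area
from endofc.interface import (
    ATOMIC_SOLVATION, RadiiTable, domain_restricted_interface, find_contacts,
    find_hydrogen_bonds, golden_spiral, interface_area, interface_report,
    sasa_from_arrays, shrake_rupley_sasa, solvation_energy_gain,
)
from endofc.model import AtomRecord, Chain, Residue, Structure, select


def _sel(positions, elements):
    return select(make_sphere_cluster(positions, elements), "A")


class TestSasaAnalytic:
    def test_isolated_oxygen_sphere(self, element_radii):
        res = shrake_rupley_sasa(_sel([[0, 0, 0]], ["O"]), element_radii, 960)
        assert res.total == pytest.approx(sphere_area(1.40), rel=0.01)

    def test_two_distant_carbons_do_not_occlude(self, element_radii):
        res = shrake_rupley_sasa(_sel([[0, 0, 0], [10, 0, 0]], ["C", "C"]),
                                 element_radii, 960)
        assert res.per_atom == pytest.approx(
            [sphere_area(1.70)] * 2, rel=0.01)
        # 4*pi*(3.1)^2 = 120.76
        assert sphere_area(1.70) == pytest.approx(120.76, abs=0.01)

    def test_two_close_carbons_match_spherical_cap_formula(self, element_radii):
        res = shrake_rupley_sasa(_sel([[0, 0, 0], [2, 0, 0]], ["C", "C"]),
                                 element_radii, 960)
        expected = two_sphere_area(1.70, 2.0)     # 4πR² − 2πRh, h = R − d/2
        assert expected == pytest.approx(79.86, abs=0.01)
        assert res.per_atom == pytest.approx([expected] * 2, rel=0.02)

    def test_convergence_960_vs_4000(self, element_radii, rng):
        coords = rng.normal(scale=3.0, size=(25, 3))
        vdw = np.full(25, 1.70)
        t960 = sasa_from_arrays(coords, vdw, 1.4, 960).sum()
        t4000 = sasa_from_arrays(coords, vdw, 1.4, 4000).sum()
        assert abs(t960 - t4000) / t4000 < 0.01

    def test_agrees_with_independent_engine(self, rng):
        biotite_struc = pytest.importorskip("biotite.structure")
        coords = rng.normal(scale=3.0, size=(30, 3))
        arr = biotite_struc.AtomArray(30)
        arr.coord = coords.astype(np.float32)
        arr.element = np.array(["C"] * 30)
        arr.atom_name = np.array(["C"] * 30)
        arr.res_name = np.array(["UNL"] * 30)
        arr.res_id = np.arange(1, 31)
        ref = biotite_struc.sasa(arr, probe_radius=1.4, point_number=2000,
                                 vdw_radii="Single").sum()
        mine = sasa_from_arrays(coords, np.full(30, 1.70), 1.4, 2000).sum()
        assert mine == pytest.approx(ref, rel=0.005)

    def test_golden_spiral_is_unit_and_well_spread(self):
        pts = golden_spiral(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)
        assert np.abs(pts.mean(axis=0)).max() < 0.01

    def test_unknown_element_raises(self):
        with pytest.raises(UnknownElementError):
            shrake_rupley_sasa(_sel([[0, 0, 0]], ["XX"]), RadiiTable.element())

    def test_too_few_points_rejected(self, element_radii):
        with pytest.raises(ValueError):
            shrake_rupley_sasa(_sel([[0, 0, 0]], ["O"]), element_radii, 32)


class TestInterfaceArea:
    def test_distant_sides_bury_nothing(self, element_radii):
        st = make_sphere_cluster([[0, 0, 0], [50, 0, 0]], ["C", "C"])
        a = select(st, "A").subset([0])
        b = select(st, "A").subset([1])
        assert abs(interface_area(a, b, element_radii)) < 0.5

    def test_two_atom_interface_matches_cap_oracle(self, element_radii):
        st = make_sphere_cluster([[0, 0, 0], [2, 0, 0]], ["C", "C"])
        a = select(st, "A").subset([0])
        b = select(st, "A").subset([1])
        expected = (2 * sphere_area(1.70) - 2 * two_sphere_area(1.70, 2.0)) / 2
        assert expected == pytest.approx(40.90, abs=0.01)
        assert interface_area(a, b, element_radii) == pytest.approx(expected, rel=0.02)

    def test_symmetric_in_sides(self, element_radii, rng):
        st = make_sphere_cluster(
            np.vstack([rng.normal(size=(6, 3)) * 2,
                       rng.normal(size=(6, 3)) * 2 + [4, 0, 0]]), ["C"] * 12)
        full = select(st, "A")
        a, b = full.subset(range(6)), full.subset(range(6, 12))
        assert interface_area(a, b, element_radii) == pytest.approx(
            interface_area(b, a, element_radii), abs=1e-9)

    def test_overlapping_sides_rejected(self, element_radii):
        st = make_sphere_cluster([[0, 0, 0], [2, 0, 0]], ["C", "C"])
        full = select(st, "A")
        with pytest.raises(ValueError):
            interface_area(full, full.subset([0]), element_radii)


class TestDomainRestrictedInterface:
    def _sides(self, rng):
        # side A: ten atoms in two residue blocks; side B: facing cluster
        pa = np.vstack([rng.normal(0, 1.5, size=(5, 3)),
                        rng.normal(0, 1.5, size=(5, 3)) + [0, 6, 0]])
        pb = rng.normal(0, 1.5, size=(8, 3)) + [4.0, 3.0, 0]
        st = make_sphere_cluster(np.vstack([pa, pb]), ["C"] * 18)
        full = select(st, "A")
        return full.subset(range(10)), full.subset(range(10, 18))

    def test_identity_restriction_equals_total(self, element_radii, rng):
        a, b = self._sides(rng)
        total = interface_area(a, b, element_radii)
        restricted = domain_restricted_interface(a, (1, 10), b, element_radii)
        assert restricted == pytest.approx(total, abs=1e-9)

    def test_disjoint_windows_partition_the_total(self, element_radii, rng):
        a, b = self._sides(rng)
        total = interface_area(a, b, element_radii)
        part = (domain_restricted_interface(a, (1, 5), b, element_radii)
                + domain_restricted_interface(a, (6, 10), b, element_radii))
        assert part == pytest.approx(total, abs=2.0)


class TestSolvationEnergy:
    def test_zero_buried_area_gives_zero(self, element_radii):
        st = make_sphere_cluster([[0, 0, 0], [50, 0, 0]], ["C", "C"])
        full = select(st, "A")
        dg = solvation_energy_gain(full.subset([0]), full.subset([1]), element_radii)
        assert dg == pytest.approx(0.0, abs=1e-6)

    def test_single_buried_apolar_carbon_sign_and_magnitude(self, element_radii):
        # two touching carbons: ΔG = σ(C) × (ΔASA_1 + ΔASA_2), negative
        st = make_sphere_cluster([[0, 0, 0], [2, 0, 0]], ["C", "C"])
        full = select(st, "A")
        a, b = full.subset([0]), full.subset([1])
        per_atom_delta = sphere_area(1.70) - two_sphere_area(1.70, 2.0)
        expected = -ATOMIC_SOLVATION["C"] * 2 * per_atom_delta
        dg = solvation_energy_gain(a, b, element_radii)
        assert dg < 0
        assert dg == pytest.approx(expected, rel=0.02)

    def test_unclassifiable_atom_raises(self, element_radii):
        st = make_sphere_cluster([[0, 0, 0], [2, 0, 0]], ["P", "C"])
        full = select(st, "A")
        with pytest.raises(UnknownElementError):
            solvation_energy_gain(full.subset([0]), full.subset([1]), element_radii)


def _residue(chain, name, seq, atoms):
    res = Residue(name=name, seq_id=seq)
    for atom_name, el, xyz in atoms:
        res.atoms.append(AtomRecord(atom_name, el, np.asarray(xyz, dtype=float)))
    chain.residues.append(res)
    return res


def _two_chain_structure(builder_a, builder_b):
    st = Structure("pair", source_format="PDB")
    ca, cb = Chain("A"), Chain("B")
    builder_a(ca)
    builder_b(cb)
    st.chains.extend([ca, cb])
    return st


class TestContacts:
    @pytest.mark.parametrize("sep,expected", [(4.4, 1), (4.6, 0)])
    def test_cutoff_is_inclusive_at_45(self, sep, expected):
        st = _two_chain_structure(
            lambda c: _residue(c, "ALA", 1, [("CB", "C", (0, 0, 0))]),
            lambda c: _residue(c, "ALA", 1, [("CB", "C", (sep, 0, 0))]))
        contacts = find_contacts(select(st, "A"), select(st, "B"), cutoff=4.5)
        assert len(contacts) == expected
        if contacts:
            assert contacts[0].min_distance == pytest.approx(sep)

    def test_sorted_by_min_distance(self, rng):
        st = _two_chain_structure(
            lambda c: [_residue(c, "ALA", i, [("CB", "C", (0, i * 5.0, 0))])
                       for i in range(1, 4)],
            lambda c: [_residue(c, "ALA", i, [("CB", "C", (2.0 + i, i * 5.0, 0))])
                       for i in range(1, 4)])
        contacts = find_contacts(select(st, "A"), select(st, "B"), cutoff=6.0)
        dists = [c.min_distance for c in contacts]
        assert dists == sorted(dists)


class TestHydrogenBonds:
    def _ser_asp(self, sep):
        return _two_chain_structure(
            lambda c: _residue(c, "SER", 1, [("CB", "C", (-1.5, 0, 0)),
                                             ("OG", "O", (0, 0, 0))]),
            lambda c: _residue(c, "ASP", 2, [("CG", "C", (sep + 1.3, 0, 0)),
                                             ("OD1", "O", (sep, 0, 0))]))

    def test_ser_to_asp_at_28_is_one_bond(self):
        st = self._ser_asp(2.8)
        bonds = find_hydrogen_bonds(select(st, "A"), select(st, "B"))
        assert len(bonds) == 1
        assert bonds[0].donor[3] == "OG" and bonds[0].acceptor[3] == "OD1"
        assert bonds[0].distance == pytest.approx(2.8)

    def test_same_pair_at_40_is_empty(self):
        st = self._ser_asp(4.0)
        assert find_hydrogen_bonds(select(st, "A"), select(st, "B")) == []

    def test_antecedent_angle_rejects_backside_approach(self):
        # acceptor placed behind the donor antecedent (angle < 90°)
        st = _two_chain_structure(
            lambda c: _residue(c, "SER", 1, [("CB", "C", (1.0, 0, 0)),
                                             ("OG", "O", (0, 0, 0))]),
            lambda c: _residue(c, "ASP", 2, [("CG", "C", (3.5, 0, 0)),
                                             ("OD1", "O", (2.2, 0, 0))]))
        assert find_hydrogen_bonds(select(st, "A"), select(st, "B")) == []

    def test_every_hbond_is_a_contact(self, binding_study):
        structures, _ = binding_study
        st = structures["complex"]
        a, b = select(st, "A"), select(st, "C")
        contacts = {(c.residue_a[:2], c.residue_b[:2])
                    for c in find_contacts(a, b, cutoff=4.5)}
        for bond in find_hydrogen_bonds(a, b, dist_cutoff=3.5):
            key = ((bond.donor[0], bond.donor[1]), (bond.acceptor[0], bond.acceptor[1]))
            rev = (key[1], key[0])
            assert key in contacts or rev in contacts


def test_interface_report_bundles_consistent_results(element_radii, rng):
    st = make_sphere_cluster(
        np.vstack([rng.normal(size=(5, 3)), rng.normal(size=(5, 3)) + [3.5, 0, 0]]),
        ["C"] * 10)
    full = select(st, "A")
    a, b = full.subset(range(5)), full.subset(range(5, 10))
    rep = interface_report(a, b, element_radii)
    assert rep.buried_area == pytest.approx(interface_area(a, b, element_radii))
    assert rep.delta_g_solv < 0
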