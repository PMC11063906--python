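"""Protein-protein interface analysis: solvent-accessible surface area
(SASA), buried interface area, solvation-energy gain, contacts and
hydrogen bonds.

SASA uses the Shrake-Rupley numerical method with a deterministic
golden-spiral point distribution: for each atom, test points are placed on
a sphere of radius (r_vdW + probe) and counted accessible when they fall
outside every neighbour's expanded sphere.  The buried interface area
between two chains follows the PISA convention,

    buried = (SASA(A) + SASA(B) - SASA(A ∪ B)) / 2,

and the solvation-energy gain is the atomic-solvation-parameter-weighted
change in per-atom area on complexation (negative = hydrophobically
favourable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import UnknownElementError
from .model import Selection

# ---------------------------------------------------------------------------
# Radii

#: Plain van der Waals radii by element (Å) — used by the analytic fixtures.
ELEMENT_RADII = {
    "H": 1.09, "C": 1.70, "N": 1.55, "O": 1.40, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "SE": 1.90, "ZN": 1.39, "MG": 1.73, "CA": 1.97, "NA": 2.27, "K": 2.75,
}

#: Chothia/NACCESS-style protein radii by atom class (Å).
_CHOTHIA = {
    "C_aliphatic": 1.87,
    "C_aromatic": 1.76,   # aromatic and carbonyl/carboxyl carbons
    "N": 1.65,
    "O": 1.40,
    "S": 1.85,
}

_AROMATIC_CARBONS = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "HIS": {"CG", "CD2", "CE1"},
    "ARG": {"CZ"},
    "ASP": {"CG"}, "ASN": {"CG"},
    "GLU": {"CD"}, "GLN": {"CD"},
}


@dataclass
class RadiiTable:
    """Van der Waals radii plus the solvent probe radius (Å)."""

    name: str
    probe_radius: float = 1.4
    element_radii: dict[str, float] = field(default_factory=lambda: dict(ELEMENT_RADII))
    use_atom_classes: bool = False

    def radius(self, res_name: str, atom_name: str, element: str) -> float:
        el = element.upper()
        if self.use_atom_classes and el in ("C", "N", "O", "S"):
            if el == "C":
                if atom_name == "C" or atom_name in _AROMATIC_CARBONS.get(res_name, ()):
                    return _CHOTHIA["C_aromatic"]
                return _CHOTHIA["C_aliphatic"]
            return _CHOTHIA[el]
        try:
            return self.element_radii[el]
        except KeyError:
            raise UnknownElementError(
                f"no radius for element {element!r} (atom {res_name}/{atom_name})"
            ) from None

    @classmethod
    def chothia(cls, probe_radius: float = 1.4) -> "RadiiTable":
        """Default protein table (NACCESS/Chothia atom classes)."""
        return cls("chothia", probe_radius=probe_radius, use_atom_classes=True)

    @classmethod
    def element(cls, probe_radius: float = 1.4) -> "RadiiTable":
        """Plain per-element vdW radii."""
        return cls("element", probe_radius=probe_radius)


DEFAULT_RADII = RadiiTable.chothia()


# ---------------------------------------------------------------------------
# Shrake-Rupley SASA

def golden_spiral(n: int) -> np.ndarray:
    """n points quasi-uniform on the unit sphere (deterministic)."""
    i = np.arange(n) + 0.5
    polar = np.arccos(1.0 - 2.0 * i / n)
    azim = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack([
        np.cos(azim) * np.sin(polar),
        np.sin(azim) * np.sin(polar),
        np.cos(polar),
    ])


@dataclass
class SasaResult:
    per_atom: np.ndarray     # Å² per atom, selection order
    n_sphere_points: int

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())


def _selection_radii(sel: Selection, radii: RadiiTable) -> np.ndarray:
    return np.array([radii.radius(r.name, a.atom_name, a.element) for _, r, a in sel])


def sasa_from_arrays(
    coords: np.ndarray, vdw: np.ndarray, probe: float, n_points: int = 960
) -> np.ndarray:
    """Per-atom accessible area (Å²) for raw coordinate/radius arrays."""
    coords = np.asarray(coords, dtype=float)
    n_atoms = coords.shape[0]
    expanded = np.asarray(vdw, dtype=float) + probe
    unit = golden_spiral(n_points)
    tree = cKDTree(coords)
    # neighbour lists within the largest possible occluding distance
    pairs = tree.query_pairs(r=2.0 * expanded.max(), output_type="ndarray")
    nbrs: list[list[int]] = [[] for _ in range(n_atoms)]
    for i, j in pairs:
        if np.linalg.norm(coords[i] - coords[j]) < expanded[i] + expanded[j]:
            nbrs[i].append(j)
            nbrs[j].append(i)
    areas = np.empty(n_atoms)
    for i in range(n_atoms):
        pts = coords[i] + expanded[i] * unit
        acc = np.ones(n_points, dtype=bool)
        for j in nbrs[i]:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            acc &= d2 > expanded[j] ** 2
            if not acc.any():
                break
        areas[i] = 4.0 * np.pi * expanded[i] ** 2 * acc.sum() / n_points
    return areas


def shrake_rupley_sasa(
    selection: Selection, radii: RadiiTable = DEFAULT_RADII, n_points: int = 960
) -> SasaResult:
    """Shrake-Rupley SASA of a selection; deterministic for fixed n_points."""
    if n_points < 64:
        raise ValueError("n_points must be >= 64")
    vdw = _selection_radii(selection, radii)
    per_atom = sasa_from_arrays(selection.coords, vdw, radii.probe_radius, n_points)
    return SasaResult(per_atom=per_atom, n_sphere_points=n_points)


def _check_disjoint(side_a: Selection, side_b: Selection) -> None:
    keys_a = {(c.chain_id, r.seq_id, r.insertion_code, a.atom_name) for c, r, a in side_a}
    keys_b = {(c.chain_id, r.seq_id, r.insertion_code, a.atom_name) for c, r, a in side_b}
    if keys_a & keys_b:
        raise ValueError("interface sides share atoms")


def _combined_sasa(
    side_a: Selection, side_b: Selection, radii: RadiiTable, n_points: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-atom SASA of A and of B computed with both present."""
    coords = np.vstack([side_a.coords, side_b.coords])
    vdw = np.concatenate([_selection_radii(side_a, radii), _selection_radii(side_b, radii)])
    per = sasa_from_arrays(coords, vdw, radii.probe_radius, n_points)
    return per[: len(side_a)], per[len(side_a):]


def interface_area(
    side_a: Selection,
    side_b: Selection,
    radii: RadiiTable = DEFAULT_RADII,
    n_points: int = 960,
) -> float:
    """Buried interface area (Å²), (SASA(A) + SASA(B) − SASA(A∪B)) / 2."""
    _check_disjoint(side_a, side_b)
    alone_a = shrake_rupley_sasa(side_a, radii, n_points).total
    alone_b = shrake_rupley_sasa(side_b, radii, n_points).total
    ab_a, ab_b = _combined_sasa(side_a, side_b, radii, n_points)
    return (alone_a + alone_b - float(ab_a.sum()) - float(ab_b.sum())) / 2.0


def domain_restricted_interface(
    side_a: Selection,
    window: tuple[int, int],
    side_b: Selection,
    radii: RadiiTable = DEFAULT_RADII,
    n_points: int = 960,
) -> float:
    """Interface area (Å²) contributed by the residues of ``window`` on
    side A, with occlusion computed in the context of the full chain.

    The A-side term sums per-atom area loss over window atoms only (full
    chain present on both ends); the B-side term is the extra area B loses
    when the window atoms are added to the rest of A.  With the identity
    window this reduces exactly to :func:`interface_area`, and restricted
    areas over disjoint windows covering all contacts sum to the total up
    to point-count noise.
    """
    _check_disjoint(side_a, side_b)
    lo, hi = window
    in_w = np.array([lo <= r.seq_id <= hi for _, r, _ in side_a])
    alone_a = shrake_rupley_sasa(side_a, radii, n_points).per_atom
    ab_a, ab_b = _combined_sasa(side_a, side_b, radii, n_points)
    term_a = float((alone_a[in_w] - ab_a[in_w]).sum())
    rest_idx = np.flatnonzero(~in_w)
    if rest_idx.size:
        rest = side_a.subset(rest_idx)
        _, b_ctx = _combined_sasa(rest, side_b, radii, n_points)
    else:
        b_ctx = shrake_rupley_sasa(side_b, radii, n_points).per_atom
    term_b = float((b_ctx - ab_b).sum())
    return (term_a + term_b) / 2.0


# ---------------------------------------------------------------------------
# Solvation energy

#: Atomic solvation parameters (kcal/mol/Å²), Eisenberg-McLachlan style:
#: transfer free energy per unit of accessible area by atom class.
ATOMIC_SOLVATION = {
    "C": 0.016,
    "N/O": -0.006,
    "O-": -0.024,
    "N+": -0.050,
    "S": 0.021,
}

_CHARGED_O = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
_CHARGED_N = {("LYS", "NZ"), ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE")}


def solvation_class(res_name: str, atom_name: str, element: str) -> str:
    el = element.upper()
    if el == "C":
        return "C"
    if el == "S" or el == "SE":
        return "S"
    if el == "O":
        return "O-" if (res_name, atom_name) in _CHARGED_O or atom_name == "OXT" else "N/O"
    if el == "N":
        return "N+" if (res_name, atom_name) in _CHARGED_N else "N/O"
    raise UnknownElementError(
        f"cannot assign solvation class to {res_name}/{atom_name} ({element})"
    )


def solvation_energy_gain(
    side_a: Selection,
    side_b: Selection,
    radii: RadiiTable = DEFAULT_RADII,
    n_points: int = 960,
    asp_table: dict[str, float] | None = None,
) -> float:
    """Solvation free-energy gain on complexation (kcal/mol).

    ΔG = Σ_i σ(class_i) · (ASA_i(complex) − ASA_i(alone)); burial of apolar
    area (σ > 0) makes the gain negative, i.e. favourable.
    """
    asp = asp_table or ATOMIC_SOLVATION
    _check_disjoint(side_a, side_b)
    alone_a = shrake_rupley_sasa(side_a, radii, n_points).per_atom
    alone_b = shrake_rupley_sasa(side_b, radii, n_points).per_atom
    ab_a, ab_b = _combined_sasa(side_a, side_b, radii, n_points)
    sig_a = np.array([asp[solvation_class(r.name, a.atom_name, a.element)]
                      for _, r, a in side_a])
    sig_b = np.array([asp[solvation_class(r.name, a.atom_name, a.element)]
                      for _, r, a in side_b])
    return float((sig_a * (ab_a - alone_a)).sum() + (sig_b * (ab_b - alone_b)).sum())


# ---------------------------------------------------------------------------
# Contacts and hydrogen bonds

@dataclass
class ContactPair:
    residue_a: tuple[str, int, str]   # (chain, seq_id, name)
    residue_b: tuple[str, int, str]
    min_distance: float


@dataclass
class HydrogenBond:
    donor: tuple[str, int, str, str]     # (chain, seq_id, res name, atom name)
    acceptor: tuple[str, int, str, str]
    distance: float


def find_contacts(
    side_a: Selection, side_b: Selection, cutoff: float = 4.5
) -> list[ContactPair]:
    """Residue pairs with any heavy-atom distance ≤ cutoff, each annotated
    with the minimum distance; sorted by that distance."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ia = [k for k, e in enumerate(side_a.elements) if e != "H"]
    ib = [k for k, e in enumerate(side_b.elements) if e != "H"]
    if not ia or not ib:
        return []
    ca, cb = side_a.coords[ia], side_b.coords[ib]
    pairs = cKDTree(ca).query_ball_tree(cKDTree(cb), r=cutoff)
    best: dict[tuple, float] = {}
    for ka, hits in enumerate(pairs):
        _, res_a, atom_a = side_a.triples[ia[ka]]
        chain_a = side_a.triples[ia[ka]][0]
        for kb in hits:
            chain_b, res_b, atom_b = side_b.triples[ib[kb]]
            d = float(np.linalg.norm(atom_a.coords - atom_b.coords))
            key = ((chain_a.chain_id, res_a.seq_id, res_a.name),
                   (chain_b.chain_id, res_b.seq_id, res_b.name))
            if d < best.get(key, np.inf):
                best[key] = d
    out = [ContactPair(k[0], k[1], d) for k, d in best.items()]
    out.sort(key=lambda c: c.min_distance)
    return out


# Donor/acceptor templates.  Backbone N donates, backbone O accepts; side
# chains follow standard chemistry.  Sugars: hydroxyls both donate and
# accept, ring O5 and the acetamido carbonyl O7 accept, N2 donates.
_DONORS: dict[str, set[str]] = {
    "*": {"N"},
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
    "ASN": {"ND2"}, "GLN": {"NE2"}, "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"}, "HIS": {"ND1", "NE2"}, "TRP": {"NE1"},
    "NAG": {"O1", "O3", "O4", "O6", "N2"}, "NDG": {"O1", "O3", "O4", "O6", "N2"},
    "FUC": {"O2", "O3", "O4"}, "BMA": {"O1", "O2", "O3", "O4", "O6"},
    "MAN": {"O1", "O2", "O3", "O4", "O6"}, "GAL": {"O1", "O2", "O3", "O4", "O6"},
}
_ACCEPTORS: dict[str, set[str]] = {
    "*": {"O", "OXT"},
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "ASN": {"OD1"}, "GLN": {"OE1"},
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"},
    "HIS": {"ND1", "NE2"}, "MET": {"SD"},
    "NAG": {"O1", "O3", "O4", "O5", "O6", "O7"},
    "NDG": {"O1", "O3", "O4", "O5", "O6", "O7"},
    "FUC": {"O2", "O3", "O4", "O5"},
    "BMA": {"O1", "O2", "O3", "O4", "O5", "O6"},
    "MAN": {"O1", "O2", "O3", "O4", "O5", "O6"},
    "GAL": {"O1", "O2", "O3", "O4", "O5", "O6"},
}


def _polar_atoms(sel: Selection, table: dict[str, set[str]]):
    known = set(_DONORS) | set(_ACCEPTORS)
    out = []
    for chain, res, atom in sel:
        if atom.element not in ("N", "O", "S"):
            continue
        names = table.get(res.name, set()) | table["*"]
        if atom.atom_name in names:
            out.append((chain, res, atom))
        elif res.name not in known and atom.element in ("N", "O") and not res.is_water:
            # residue without a template: treat any N/O generically as polar
            out.append((chain, res, atom))
    return out


def _antecedent(res, atom) -> np.ndarray | None:
    """Nearest covalently bonded heavy atom in the same residue."""
    best, best_d = None, 1.8
    for other in res.resolved_atoms():
        if other is atom or other.element == "H":
            continue
        d = float(np.linalg.norm(other.coords - atom.coords))
        if d < best_d:
            best, best_d = other, d
    return None if best is None else best.coords


def find_hydrogen_bonds(
    side_a: Selection, side_b: Selection, dist_cutoff: float = 3.5
) -> list[HydrogenBond]:
    """Donor-acceptor heavy-atom pairs across the interface with distance
    ≤ cutoff.  No explicit hydrogens are required: the geometric test is
    the distance plus, when a donor antecedent exists, an
    antecedent-donor-acceptor angle ≥ 90°."""
    bonds: list[HydrogenBond] = []
    for d_side, a_side in ((side_a, side_b), (side_b, side_a)):
        donors = _polar_atoms(d_side, _DONORS)
        acceptors = _polar_atoms(a_side, _ACCEPTORS)
        if not donors or not acceptors:
            continue
        acc_coords = np.array([a.coords for _, _, a in acceptors])
        tree = cKDTree(acc_coords)
        for chain_d, res_d, atom_d in donors:
            for k in tree.query_ball_point(atom_d.coords, r=dist_cutoff):
                chain_a, res_a, atom_a = acceptors[k]
                dist = float(np.linalg.norm(atom_d.coords - atom_a.coords))
                ante = _antecedent(res_d, atom_d)
                if ante is not None:
                    v1 = ante - atom_d.coords
                    v2 = atom_a.coords - atom_d.coords
                    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    if np.degrees(np.arccos(np.clip(cosang, -1, 1))) < 90.0:
                        continue
                bonds.append(HydrogenBond(
                    donor=(chain_d.chain_id, res_d.seq_id, res_d.name, atom_d.atom_name),
                    acceptor=(chain_a.chain_id, res_a.seq_id, res_a.name, atom_a.atom_name),
                    distance=dist,
                ))
    bonds.sort(key=lambda b: b.distance)
    return bonds


@dataclass
class InterfaceReport:
    buried_area: float
    delta_g_solv: float
    contacts: list[ContactPair]
    hbonds: list[HydrogenBond]
    restriction: tuple[int, int] | None = None


def interface_report(
    side_a: Selection,
    side_b: Selection,
    radii: RadiiTable = DEFAULT_RADII,
    n_points: int = 960,
    contact_cutoff: float = 4.5,
    hbond_cutoff: float = 3.5,
    restriction: tuple[int, int] | None = None,
) -> InterfaceReport:
    """Full interface characterization for a chain (or domain-restricted) pair."""
    if restriction is None:
        buried = interface_area(side_a, side_b, radii, n_points)
        eff_a = side_a
    else:
        buried = domain_restricted_interface(side_a, restriction, side_b, radii, n_points)
        lo, hi = restriction
        eff_a = side_a.subset(
            [i for i, (_, r, _) in enumerate(side_a.triples) if lo <= r.seq_id <= hi]
        )
    return InterfaceReport(
        buried_area=buried,
        delta_g_solv=solvation_energy_gain(side_a, side_b, radii, n_points),
        contacts=find_contacts(eff_a, side_b, contact_cutoff),
        hbonds=find_hydrogen_bonds(eff_a, side_b, hbond_cutoff),
        restriction=restriction,
    )
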