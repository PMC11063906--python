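"""N-glycan detection and linkage geometry.

A glycan is detected by a breadth-first covalent walk from the ND2 atom of
an asparagine over saccharide HETATM residues, bonding the anomeric carbon
C1 of each sugar to an N or O of its acceptor at ≤ 1.8 Å.  For every
inter-residue linkage the glycosidic torsions are reported in the
heavy-atom convention

    Φ = O5–C1–Ox–Cx,   Ψ = C1–Ox–Cx–C(x+1),

signed per the IUPAC rule (clockwise positive looking down the central
bond).  Ring shapes are summarized with Cremer–Pople puckering
coordinates (Q, θ, φ2), ring atoms ordered O5, C1..C5, so that the
standard ⁴C₁ pyranose chair sits at θ = 0°.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .errors import MissingAtomError, NoGlycanError
from .model import Residue, Structure, select
from .superpose import kabsch_fit, match_residues

RING_ATOMS = ("O5", "C1", "C2", "C3", "C4", "C5")

#: covalent C-O / C-N single-bond upper bound (Å)
BOND_CUTOFF = 1.8


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees, (−180, 180], IUPAC convention."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = np.degrees(np.arctan2(y, x))
    return float(ang if ang > -180.0 else 180.0)


# ---------------------------------------------------------------------------
# Cremer-Pople puckering


@dataclass
class RingPucker:
    Q: float          # total puckering amplitude, Å
    theta: float      # degrees, [0, 180]
    phi2: float       # degrees, [0, 360)
    conformer_label: str


def _canonical_conformers() -> list[tuple[str, float, float]]:
    """(label, theta, phi2) for the canonical pyranose conformer set:
    2 chairs, 6 boats, 6 skew-boats, 12 half-chairs (+ 12 envelopes),
    ring order O5,C1..C5.  Positions follow from the ideal out-of-plane
    displacement patterns of each form."""
    loc = ["O", "1", "2", "3", "4", "5"]
    out = [("4C1", 0.0, 0.0), ("1C4", 180.0, 0.0)]
    # boats: atoms j0 and j0+3 puckered up at phi2 = -120*j0; down at +180
    for j0 in range(3):
        up = sorted([loc[j0], loc[(j0 + 3) % 6]], key=lambda s: (s != "O", s))
        out.append((f"{up[0]}{up[1]}B", 90.0, (-120.0 * j0) % 360.0))
        out.append((f"B{up[0]}{up[1]}", 90.0, (-120.0 * j0 + 180.0) % 360.0))
    # skew-boats (twist-boats), canonical wheel for this atom ordering
    out += [("3S1", 90.0, 30.0), ("5S1", 90.0, 90.0), ("2SO", 90.0, 150.0),
            ("1S3", 90.0, 210.0), ("1S5", 90.0, 270.0), ("OS2", 90.0, 330.0)]
    # half-chairs jH_k (atom j up, adjacent k down), theta = 50.8/129.2
    for j0 in range(6):
        for k, phi in (((j0 - 1) % 6, (-120.0 * j0 - 30.0) % 360.0),
                       ((j0 + 1) % 6, (-120.0 * j0 + 30.0) % 360.0)):
            theta = 50.8 if j0 % 2 == 0 else 129.2
            out.append((f"{loc[j0]}H{loc[k]}", theta, phi))
    # envelopes: single atom out of plane, theta = 54.7/125.3
    for j0 in range(6):
        theta = 54.7 if j0 % 2 == 0 else 125.3
        out.append((f"{loc[j0]}E", theta, (-120.0 * j0) % 360.0))
        theta = 125.3 if j0 % 2 == 0 else 54.7
        out.append((f"E{loc[j0]}", theta, (-120.0 * j0 + 180.0) % 360.0))
    return out


CANONICAL_CONFORMERS = _canonical_conformers()


def _sphere_distance(t1: float, p1: float, t2: float, p2: float) -> float:
    """Great-circle distance (deg) between (theta, phi) points."""
    t1, p1, t2, p2 = map(np.radians, (t1, p1, t2, p2))
    c = (np.sin(t1) * np.sin(t2) * np.cos(p1 - p2) + np.cos(t1) * np.cos(t2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def classify_conformer(theta: float, phi2: float) -> str:
    best = min(CANONICAL_CONFORMERS,
               key=lambda c: _sphere_distance(theta, phi2, c[1], c[2]))
    return best[0]


def cremer_pople(ring_coords: np.ndarray) -> RingPucker:
    """Cremer-Pople (Q, θ, φ2) of a six-membered ring.

    ``ring_coords`` is 6x3 in the order O5, C1, C2, C3, C4, C5.
    """
    R = np.asarray(ring_coords, dtype=float)
    if R.shape != (6, 3):
        raise ValueError(f"expected 6 ring atoms, got shape {R.shape}")
    center = R.mean(axis=0)
    r = R - center
    j = np.arange(6)
    R1 = (r * np.sin(2 * np.pi * j / 6)[:, None]).sum(axis=0)
    R2 = (r * np.cos(2 * np.pi * j / 6)[:, None]).sum(axis=0)
    n = np.cross(R1, R2)
    n = n / np.linalg.norm(n)
    z = r @ n
    q2c = np.sqrt(1 / 3) * (z * np.cos(4 * np.pi * j / 6)).sum()
    q2s = -np.sqrt(1 / 3) * (z * np.sin(4 * np.pi * j / 6)).sum()
    q3 = np.sqrt(1 / 6) * (z * (-1.0) ** j).sum()
    q2 = float(np.hypot(q2c, q2s))
    Q = float(np.hypot(q2, q3))
    if Q < 1e-3:
        return RingPucker(Q=Q, theta=0.0, phi2=0.0, conformer_label="planar")
    theta = float(np.degrees(np.arctan2(q2, q3)))
    phi2 = float(np.degrees(np.arctan2(q2s, q2c)) % 360.0)
    return RingPucker(Q=Q, theta=theta, phi2=phi2,
                      conformer_label=classify_conformer(theta, phi2))


def ring_pucker(residue: Residue) -> RingPucker:
    """Cremer-Pople descriptors of a pyranose residue's ring."""
    coords = []
    for name in RING_ATOMS:
        a = residue.get_atom(name)
        if a is None:
            raise MissingAtomError(f"{residue.name} {residue.seq_id}: missing ring atom {name}")
        coords.append(a.coords)
    return cremer_pople(np.array(coords))


# ---------------------------------------------------------------------------
# Glycan detection


@dataclass
class GlycanResidue:
    code: str
    chain_id: str
    residue: Residue

    @property
    def seq_id(self) -> int:
        return self.residue.seq_id


@dataclass
class GlycosidicLinkage:
    donor: GlycanResidue          # provides C1
    acceptor: GlycanResidue | None  # None when the acceptor is the Asn
    acceptor_name: str            # residue code of the acceptor (e.g. NAG, ASN)
    acceptor_atom: str            # e.g. O4, O6, ND2
    phi: float
    psi: float

    @property
    def linkage_type(self) -> str:
        m = re.fullmatch(r"O(\d)", self.acceptor_atom)
        return f"1-{m.group(1)}" if m else self.acceptor_atom


@dataclass
class GlycanTree:
    asn: tuple[str, int]
    residues: list[GlycanResidue] = field(default_factory=list)
    linkages: list[GlycosidicLinkage] = field(default_factory=list)


def _torsion_atoms(donor: Residue, acceptor: Residue, acceptor_atom: str,
                   convention: str = "heavy"):
    """Atom positions for (Φ, Ψ) about donor-C1 → acceptor-Ox."""
    first = "O5" if convention == "heavy" else "H1"
    a_first = donor.get_atom(first)
    c1 = donor.get_atom("C1")
    ox = acceptor.get_atom(acceptor_atom)
    if a_first is None or c1 is None or ox is None:
        missing = [n for n, a in ((first, a_first), ("C1", c1), (acceptor_atom, ox)) if a is None]
        raise MissingAtomError(f"linkage atoms missing: {missing}")
    if acceptor_atom == "ND2":          # Asn attachment
        cx, cnext = acceptor.get_atom("CG"), acceptor.get_atom("CB")
        if cx is None or cnext is None:
            raise MissingAtomError("Asn missing CG/CB")
        return a_first, c1, ox, cx, cnext
    m = re.fullmatch(r"O(\d)", acceptor_atom)
    if not m:
        raise MissingAtomError(f"unsupported acceptor atom {acceptor_atom}")
    x = int(m.group(1))
    cx = acceptor.get_atom(f"C{x}")
    cnext = acceptor.get_atom(f"C{x + 1}") or acceptor.get_atom(f"C{x - 1}")
    if cx is None or cnext is None:
        raise MissingAtomError(f"acceptor missing C{x} or its ring neighbour")
    return a_first, c1, ox, cx, cnext


def glycosidic_torsions(donor: Residue, acceptor: Residue, acceptor_atom: str,
                        convention: str = "heavy") -> tuple[float, float]:
    """(Φ, Ψ) in degrees for the linkage donor-C1 → acceptor atom.

    ``convention='heavy'`` uses Φ = O5-C1-Ox-Cx (crystallographic survey
    convention); ``'hydrogen'`` uses H1 in place of O5 (NMR convention,
    requires an explicit H1).
    """
    a_first, c1, ox, cx, cnext = _torsion_atoms(donor, acceptor, acceptor_atom, convention)
    phi = dihedral(a_first.coords, c1.coords, ox.coords, cx.coords)
    psi = dihedral(c1.coords, ox.coords, cx.coords, cnext.coords)
    return phi, psi


def detect_glycan(structure: Structure, asn: tuple[str, int],
                  convention: str = "heavy") -> GlycanTree:
    """Walk the covalent glycan attached to an Asn residue.

    Returns the tree in breadth-first order with one GlycosidicLinkage per
    bond (including the Asn attachment).  The result is independent of
    HETATM record order.
    """
    chain_id, seq_id = asn
    chain = structure.chain(chain_id)
    asn_res = chain.find(seq_id)
    if asn_res is None or asn_res.get_atom("ND2") is None:
        raise NoGlycanError(f"no Asn with ND2 at {chain_id}:{seq_id}")
    nd2 = asn_res.get_atom("ND2")

    sugars: list[tuple[str, Residue]] = [
        (c.chain_id, r)
        for c in structure.chains
        for r in c.residues
        if r.is_saccharide and r.get_atom("C1") is not None
    ]
    sugars.sort(key=lambda t: (t[0], t[1].seq_id, t[1].insertion_code))

    def c1_bonds_to(target_coords: np.ndarray):
        hits = []
        for cid, res in sugars:
            c1 = res.get_atom("C1")
            if float(np.linalg.norm(c1.coords - target_coords)) <= BOND_CUTOFF:
                hits.append((cid, res))
        return hits

    roots = c1_bonds_to(nd2.coords)
    if not roots:
        raise NoGlycanError(f"no saccharide C1 within {BOND_CUTOFF} Å of {chain_id}:{seq_id} ND2")

    tree = GlycanTree(asn=asn)
    seen: set[int] = set()
    queue: list[tuple[GlycanResidue, Residue | None, str, str]] = []
    for cid, res in roots:
        gr = GlycanResidue(res.name, cid, res)
        queue.append((gr, asn_res, "ASN", "ND2"))
    while queue:
        gr, acc_res, acc_name, acc_atom = queue.pop(0)
        if id(gr.residue) in seen:
            continue
        seen.add(id(gr.residue))
        tree.residues.append(gr)
        phi, psi = glycosidic_torsions(gr.residue, acc_res, acc_atom, convention)
        acc_gr = next((g for g in tree.residues if g.residue is acc_res), None)
        tree.linkages.append(GlycosidicLinkage(
            donor=gr, acceptor=acc_gr, acceptor_name=acc_name,
            acceptor_atom=acc_atom, phi=phi, psi=psi,
        ))
        # children: sugars whose C1 bonds to one of this residue's oxygens
        for ox_name in ("O2", "O3", "O4", "O6", "O1"):
            ox = gr.residue.get_atom(ox_name)
            if ox is None:
                continue
            for cid, res in c1_bonds_to(ox.coords):
                if res is gr.residue or id(res) in seen:
                    continue
                queue.append((GlycanResidue(res.name, cid, res), gr.residue,
                              gr.residue.name, ox_name))
    return tree


# ---------------------------------------------------------------------------
# Active-site overlay


@dataclass
class ActiveSiteReport:
    gh_fit_rmsd: float
    n_matched: int
    distances: dict[str, float]   # "E186:OE1->O4" style keys, Å


def active_site_geometry(
    complex_struct: Structure,
    complex_chain: str,
    wt_struct: Structure,
    wt_chain: str,
    gh_window: tuple[int, int],
    dyad: list[int],
    linkage_oxygen: tuple[str, int, str],
    anomeric_carbon: tuple[str, int, str] | None = None,
) -> ActiveSiteReport:
    """Superpose a wild-type enzyme's catalytic domain onto the complex and
    measure dyad carboxyl-oxygen distances to a glycosidic linkage.

    ``linkage_oxygen``/``anomeric_carbon`` are (chain, seq_id, atom_name)
    in the complex structure; ``dyad`` lists wild-type residue numbers
    whose side-chain carboxyl oxygens (OD1/OD2/OE1/OE2) are measured.
    """
    sel_c = select(complex_struct, complex_chain, seq_range=gh_window, atom_names=["CA"])
    sel_w = select(wt_struct, wt_chain, seq_range=gh_window, atom_names=["CA"])
    W, C = match_residues(sel_w, sel_c)
    fit = kabsch_fit(W, C)

    def _atom_coords(struct, cid, sid, name):
        res = struct.chain(cid).find(sid)
        if res is None or res.get_atom(name) is None:
            raise MissingAtomError(f"{cid}:{sid}:{name} not found")
        return res.get_atom(name).coords

    targets = {linkage_oxygen[2]: _atom_coords(complex_struct, *linkage_oxygen)}
    if anomeric_carbon is not None:
        targets[anomeric_carbon[2]] = _atom_coords(complex_struct, *anomeric_carbon)

    distances: dict[str, float] = {}
    wt = wt_struct.chain(wt_chain)
    for sid in dyad:
        res = wt.find(sid)
        if res is None:
            raise MissingAtomError(f"dyad residue {sid} absent from wild-type chain")
        oxy = [a for a in res.resolved_atoms()
               if a.atom_name in ("OD1", "OD2", "OE1", "OE2")]
        if not oxy:
            raise MissingAtomError(f"dyad residue {res.name} {sid} has no carboxyl oxygens")
        for a in oxy:
            moved = fit.transform.apply(a.coords[None, :])[0]
            for tname, tcoords in targets.items():
                distances[f"{res.name}{sid}:{a.atom_name}->{tname}"] = float(
                    np.linalg.norm(moved - tcoords)
                )
    return ActiveSiteReport(gh_fit_rmsd=fit.rmsd, n_matched=fit.n_matched,
                            distances=distances)
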