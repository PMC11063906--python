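"""Synthetic test structures with analytically known ground truth.

Every generator is deterministic given its parameters (and seed, where one
is used), and the ground truth (applied transforms, exact torsions, ring
parameters) is returned alongside and can be written as a sidecar JSON so
tests never re-derive it.

The generators emulate, at toy scale, the inputs of the real analyses:
multi-domain Cα chains related by known per-domain rigid transforms, small
atom clusters whose accessible areas have closed forms, idealized pyranose
rings at exact Cremer-Pople coordinates, and disaccharides built at exact
glycosidic torsions.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .glycan import RING_ATOMS, dihedral
from .model import AtomRecord, Chain, DomainScheme, Residue, Structure, write_structure
from .superpose import RigidTransform

# ---------------------------------------------------------------------------
# Multi-domain toys


def make_multidomain_toy(
    scheme: DomainScheme,
    per_domain_transforms: dict[str, tuple[float, tuple, tuple]] | None = None,
    atoms_per_domain: int = 60,
    noise_sigma: float = 0.0,
    seed: int = 0,
    domain_sigma: float = 8.0,
    domain_spacing: float = 35.0,
) -> tuple[Structure, Structure, dict]:
    """Reference and per-domain-transformed Cα chains.

    The reference is a set of Gaussian Cα clouds (sd ``domain_sigma`` Å)
    centered on a gently curved path of domain centroids, residue-numbered
    from each scheme window.  ``per_domain_transforms`` maps a domain name
    to (angle_deg, axis, translation); each transform acts about that
    domain's centroid.  Gaussian coordinate noise of ``noise_sigma`` Å is
    added to the transformed copy only.  Returns (reference, transformed,
    ground_truth).
    """
    rng = np.random.default_rng(seed)
    domains = list(scheme.windows)
    truth: dict = {"seed": seed, "noise_sigma": noise_sigma, "domains": {}}
    ref = Structure("toy_ref", source_format="PDB")
    mov = Structure("toy_mov", source_format="PDB")
    ref_chain, mov_chain = Chain("A"), Chain("A")
    ref.chains.append(ref_chain)
    mov.chains.append(mov_chain)
    for k, dom in enumerate(domains):
        lo, hi = scheme.windows[dom]
        if hi - lo + 1 < atoms_per_domain:
            raise ValueError(f"window {dom} smaller than atoms_per_domain={atoms_per_domain}")
        # centroid path: a shallow arc so domains are well separated
        t = k * domain_spacing
        centroid = np.array([t, 10.0 * np.sin(t / 50.0), 6.0 * np.cos(t / 70.0)])
        cloud = centroid + rng.normal(0.0, domain_sigma, size=(atoms_per_domain, 3))
        angle, axis, trans = (per_domain_transforms or {}).get(
            dom, (0.0, (0, 0, 1), (0, 0, 0))
        )
        actual_centroid = cloud.mean(axis=0)
        tf = RigidTransform.from_axis_angle(axis, angle, translation=trans,
                                            center=actual_centroid)
        moved = tf.apply(cloud)
        if noise_sigma > 0:
            moved = moved + rng.normal(0.0, noise_sigma, size=moved.shape)
        truth["domains"][dom] = {
            "angle_deg": float(angle),
            "axis": list(map(float, np.asarray(axis, dtype=float))),
            "translation": list(map(float, np.asarray(trans, dtype=float))),
            "centroid": [float(x) for x in actual_centroid],
        }
        for i in range(atoms_per_domain):
            seq = lo + i
            for chain, xyz in ((ref_chain, cloud[i]), (mov_chain, moved[i])):
                res = Residue(name="ALA", seq_id=seq)
                res.atoms.append(AtomRecord("CA", "C", np.array(xyz)))
                chain.residues.append(res)
    return ref, mov, truth


# ---------------------------------------------------------------------------
# Sphere clusters for SASA


def make_sphere_cluster(positions, elements) -> Structure:
    """One HETATM chain with one single-atom residue per position."""
    positions = np.asarray(positions, dtype=float)
    if len(positions) != len(elements):
        raise ValueError("positions and elements must have equal length")
    st = Structure("spheres", source_format="PDB")
    chain = Chain("A")
    st.chains.append(chain)
    for i, (pos, el) in enumerate(zip(positions, elements), start=1):
        res = Residue(name="UNL", seq_id=i)
        res.atoms.append(AtomRecord(el.upper(), el.upper(), np.array(pos), is_hetero=True))
        chain.residues.append(res)
    return st


def sphere_area(radius: float, probe: float = 1.4) -> float:
    """Accessible area of an isolated atom: 4π(r+probe)²."""
    return 4.0 * np.pi * (radius + probe) ** 2


def two_sphere_area(radius: float, separation: float, probe: float = 1.4) -> float:
    """Accessible area of one of two equal overlapping expanded spheres:
    4πR² minus the spherical cap hidden inside the partner,
    cap height h = R − d/2."""
    R = radius + probe
    if separation >= 2 * R:
        return sphere_area(radius, probe)
    h = R - separation / 2.0
    return 4.0 * np.pi * R**2 - 2.0 * np.pi * R * h


# ---------------------------------------------------------------------------
# Idealized pyranose rings and disaccharides


def make_ring_coords(Q: float, theta: float, phi2: float,
                     radius: float = 1.46) -> np.ndarray:
    """6x3 ring coordinates (order O5,C1..C5) built from the Cremer-Pople
    forward equations: a planar hexagon plus out-of-plane displacements

        z_j = (1/√3) q2 cos(φ2 + 4πj/6) + (1/√6) q3 (−1)^j,

    with q2 = Q sinθ, q3 = Q cosθ."""
    j = np.arange(6)
    q2 = Q * np.sin(np.radians(theta))
    q3 = Q * np.cos(np.radians(theta))
    ang = 2 * np.pi * j / 6
    x = radius * np.cos(ang)
    y = -radius * np.sin(ang)   # clockwise so the ring normal points +z
    z = (np.sqrt(1 / 3) * q2 * np.cos(np.radians(phi2) + 4 * np.pi * j / 6)
         + np.sqrt(1 / 6) * q3 * (-1.0) ** j)
    return np.column_stack([x, y, z])


_CANONICAL_QTP = {"4C1": (0.55, 0.0, 0.0), "1C4": (0.55, 180.0, 0.0),
                  "1S3": (0.62, 90.0, 210.0), "OS2": (0.62, 90.0, 330.0),
                  "B25": (0.62, 90.0, 300.0), "O3B": (0.62, 90.0, 0.0)}


def make_ring(conformer: str | tuple[float, float, float]) -> np.ndarray:
    """Ring coordinates for a canonical conformer label or (Q, θ, φ2)."""
    if isinstance(conformer, str):
        try:
            Q, theta, phi2 = _CANONICAL_QTP[conformer]
        except KeyError:
            raise ValueError(f"unknown conformer label {conformer!r}") from None
    else:
        Q, theta, phi2 = conformer
    return make_ring_coords(Q, theta, phi2)


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector a to unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180° about any perpendicular axis
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return RigidTransform.from_axis_angle(perp, 180.0).rotation
    k = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + k + k @ k * ((1 - c) / np.linalg.norm(v) ** 2)


def nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
         bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d bonded to c with |dc| = bond, angle(d,c,b) = angle and
    dihedral(d,c,b,a) = torsion (natural extension reference frame)."""
    ang, tor = np.radians(angle_deg), np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


_EXO_BOND = 1.43


def _sugar_template(code: str = "NAG") -> dict[str, np.ndarray]:
    """Idealized 4C1 pyranose with ring atoms plus O2, O3, O4, C6, O6."""
    ring = make_ring("4C1")
    atoms = dict(zip(RING_ATOMS, ring))

    def exo(center: str, n1: str, n2: str, out: float = 0.0) -> np.ndarray:
        c, a1, a2 = atoms[center], atoms[n1], atoms[n2]
        d = 2 * c - a1 - a2
        d = d / np.linalg.norm(d)
        d = d + np.array([0.0, 0.0, out])
        return c + _EXO_BOND * d / np.linalg.norm(d)

    atoms["O2"] = exo("C2", "C1", "C3", out=0.4)
    atoms["O3"] = exo("C3", "C2", "C4", out=-0.4)
    atoms["O4"] = exo("C4", "C3", "C5", out=0.4)
    atoms["C6"] = exo("C5", "C4", "O5", out=0.9)
    o6dir = atoms["C6"] - atoms["C5"]
    atoms["O6"] = atoms["C6"] + 1.43 * (
        (o6dir / np.linalg.norm(o6dir)) + np.array([0.4, 0.0, 0.4])
    ) / np.linalg.norm((o6dir / np.linalg.norm(o6dir)) + np.array([0.4, 0.0, 0.4]))
    return atoms


def _place_donor_ring(template: dict[str, np.ndarray], c1: np.ndarray,
                      o5: np.ndarray) -> dict[str, np.ndarray]:
    """Rigidly place a sugar template so its C1 and O5 land on the given
    points (the free spin about the C1-O5 axis is fixed deterministically)."""
    rot = _rotation_between(template["O5"] - template["C1"], o5 - c1)
    return {name: rot @ (xyz - template["C1"]) + c1 for name, xyz in template.items()}


def attach_sugar(acceptor: dict[str, np.ndarray], acceptor_oxygen: str,
                 phi: float, psi: float, code: str = "NAG") -> dict[str, np.ndarray]:
    """Attach a donor pyranose to ``acceptor_oxygen`` at exact (Φ, Ψ).

    Ψ fixes the donor C1 via the frame (C(x+1), Cx, Ox); Φ then fixes the
    donor O5 about the new glycosidic bond; the rest of the ring follows
    rigidly, so the torsions are exact by construction.
    """
    x = int(acceptor_oxygen[1])
    ox = acceptor[acceptor_oxygen]
    cx = acceptor[f"C{x}"]
    cnext = acceptor.get(f"C{x + 1}", acceptor.get(f"C{x - 1}"))
    template = _sugar_template(code)
    c1o5 = float(np.linalg.norm(template["O5"] - template["C1"]))
    c1 = nerf(cnext, cx, ox, bond=1.41, angle_deg=117.0, torsion_deg=psi)
    o5 = nerf(cx, ox, c1, bond=c1o5, angle_deg=109.5, torsion_deg=phi)
    return _place_donor_ring(template, c1, o5)


def _sugar_residue(atoms: dict[str, np.ndarray], code: str, seq_id: int) -> Residue:
    res = Residue(name=code, seq_id=seq_id)
    for name in sorted(atoms):
        el = "O" if name.startswith("O") else ("N" if name.startswith("N") else "C")
        res.atoms.append(AtomRecord(name, el, atoms[name], is_hetero=True))
    return res


def make_disaccharide(phi: float, psi: float, linkage_oxygen: str = "O4",
                      codes: tuple[str, str] = ("NAG", "NAG")) -> tuple[Structure, dict]:
    """Two idealized 4C1 pyranoses joined at exact glycosidic (Φ, Ψ).

    Residue 1 is the acceptor (provides the linkage oxygen), residue 2 the
    donor (provides C1).  Returns (structure, ground_truth)."""
    acceptor = _sugar_template(codes[0])
    donor = attach_sugar(acceptor, linkage_oxygen, phi, psi, codes[1])
    st = Structure("disaccharide", source_format="PDB")
    chain = Chain("A")
    chain.residues.append(_sugar_residue(acceptor, codes[0], 1))
    chain.residues.append(_sugar_residue(donor, codes[1], 2))
    st.chains.append(chain)
    truth = {"phi": float(phi), "psi": float(psi), "linkage_oxygen": linkage_oxygen,
             "donor_seq_id": 2, "acceptor_seq_id": 1}
    return st, truth


def make_nlinked_glycan(
    n_core: int = 2,
    fucose: bool = True,
    phi: float = -74.0,
    psi: float = -120.0,
    asn_seq_id: int = 297,
    chain_id: str = "A",
) -> tuple[Structure, dict]:
    """A synthetic Asn with an attached GlcNAc chain (β1-4-style O4 links)
    and optionally an α1-6-style fucose on the first GlcNAc.

    The construction is idealized geometry, not a physical model; it
    exercises detection, torsion and puckering code paths end to end.
    Sugars are numbered from 401.
    """
    st = Structure("nglycan", source_format="PDB")
    chain = Chain(chain_id)
    st.chains.append(chain)
    # minimal Asn: backbone-free side chain fragment CB-CG(-OD1)=ND2
    cb = np.array([0.0, 0.0, 0.0])
    cg = np.array([1.52, 0.0, 0.0])
    od1 = nerf(cb + np.array([0, 0, 1.0]), cb, cg, 1.23, 121.0, 0.0)
    nd2 = nerf(cb + np.array([0, 0, 1.0]), cb, cg, 1.33, 116.0, 180.0)
    asn = Residue(name="ASN", seq_id=asn_seq_id)
    for name, el, xyz in (("CB", "C", cb), ("CG", "C", cg), ("OD1", "O", od1),
                          ("ND2", "N", nd2)):
        asn.atoms.append(AtomRecord(name, el, xyz))
    chain.residues.append(asn)

    truth = {"linkages": []}
    # root GlcNAc on ND2
    template = _sugar_template("NAG")
    c1o5 = float(np.linalg.norm(template["O5"] - template["C1"]))
    root_psi, root_phi = 180.0, -95.0
    c1 = nerf(cb, cg, nd2, bond=1.45, angle_deg=124.0, torsion_deg=root_psi)
    o5 = nerf(cg, nd2, c1, bond=c1o5, angle_deg=109.5, torsion_deg=root_phi)
    sugars = [_place_donor_ring(template, c1, o5)]
    codes = ["NAG"]
    truth["linkages"].append({"donor": 401, "acceptor_atom": "ND2",
                              "phi": root_phi, "psi": root_psi})
    for k in range(1, n_core):
        sugars.append(attach_sugar(sugars[-1], "O4", phi, psi, "NAG"))
        codes.append("NAG")
        truth["linkages"].append({"donor": 401 + k, "acceptor_atom": "O4",
                                  "phi": phi, "psi": psi})
    if fucose:
        fuc = attach_sugar(sugars[0], "O6", -70.0, 170.0, "FUC")
        sugars.append(fuc)
        codes.append("FUC")
        truth["linkages"].append({"donor": 401 + len(sugars) - 1,
                                  "acceptor_atom": "O6", "phi": -70.0, "psi": 170.0})
    for k, (atoms, code) in enumerate(zip(sugars, codes)):
        chain.residues.append(_sugar_residue(atoms, code, 401 + k))
    return st, truth


def make_binding_study(seed: int = 0, atoms_per_domain: int = 40) -> tuple[dict, dict]:
    """A complete synthetic enzyme-Fc binding study with known ground truth.

    Returns ``(structures, truth)`` where ``structures`` holds the five
    roles the full pipeline consumes:

    - ``complex``       enzyme chain A + glycosylated Fc chain C + distal
                        Fc partner chain D
    - ``unliganded``    the enzyme with known per-domain rearrangements
                        applied (LRR 10° tilt, hIg and CBM displacements)
    - ``wt_enzyme``     the enzyme plus catalytic-dyad residues (Asp184,
                        Glu186) whose carboxyl oxygens sit at an exact,
                        recorded distance from the core glycan linkage
    - ``wt_fc``         a rigidly moved Fc copy with one loop residue
                        displaced by a known amount (deviation-profile peak)
    - ``endos_complex`` a second complex whose Fc dimer is closer together

    Every structure is a Cα-level toy (plus full-atom glycan); the study
    emulates the shape of the real comparison, not its chemistry.
    """
    rng = np.random.default_rng(seed)
    from .model import get_scheme

    scheme = get_scheme("endos2")
    rearr = {"LRR": (10.0, (0, 1, 0), (0.0, 0.0, 0.0)),
             "hIg": (0.0, (0, 0, 1), (8.2, 0.0, 0.0)),
             "CBM": (4.0, (1, 0, 0), (0.0, 19.4, 0.0))}
    enzyme, free_enzyme, toy_truth = make_multidomain_toy(
        scheme, rearr, atoms_per_domain=atoms_per_domain, seed=seed)
    truth: dict = {"rearrangement": toy_truth, "seed": seed}

    cbm_centroid = np.array(toy_truth["domains"]["CBM"]["centroid"])
    gh_centroid = np.array(toy_truth["domains"]["GH"]["centroid"])

    def fc_chain(chain_id: str, center: np.ndarray, spread: float = 5.0) -> Chain:
        chain = Chain(chain_id)
        pts = center + rng.normal(0.0, spread, size=(104, 3))
        for i, seq in enumerate(range(237, 341)):
            res = Residue(name="GLY", seq_id=seq)
            res.atoms.append(AtomRecord("CA", "C", pts[i]))
            chain.residues.append(res)
        return chain

    complex_st = Structure("toy_complex", source_format="PDB")
    complex_st.chains.append(enzyme.chains[0])
    chain_c = fc_chain("C", cbm_centroid + np.array([0.0, 0.0, 14.0]))
    # graft a glycosylated Asn onto chain C, placed against the GH domain
    glyc, glyc_truth = make_nlinked_glycan(n_core=2, fucose=True, phi=5.9,
                                           psi=-120.0, asn_seq_id=297)
    shift = gh_centroid + np.array([0.0, 0.0, 12.0])
    glyc_residues = []
    for res in glyc.chains[0].residues:
        moved = Residue(name=res.name, seq_id=res.seq_id)
        for a in res.atoms:
            moved.atoms.append(AtomRecord(a.atom_name, a.element, a.coords + shift,
                                          is_hetero=a.is_hetero))
        glyc_residues.append(moved)
    chain_c.residues = (
        [r for r in chain_c.residues if r.seq_id != 297]
        + glyc_residues
    )
    chain_c.residues.sort(key=lambda r: r.seq_id)
    complex_st.chains.append(chain_c)
    chain_d = fc_chain("D", cbm_centroid + np.array([0.0, 26.0, 14.0]))
    complex_st.chains.append(chain_d)
    truth["glycan"] = glyc_truth
    truth["cgamma2_separation_direction"] = "complex > endos_complex"

    free_enzyme.identifier = "toy_free"

    # wild-type enzyme: same conformation, plus the catalytic dyad with a
    # carboxyl oxygen placed exactly 3.0 Å from the core-linkage O4
    wt = Structure("toy_wt_enzyme", source_format="PDB")
    wt_chain = Chain("A")
    for res in enzyme.chains[0].residues:
        cp = Residue(name=res.name, seq_id=res.seq_id)
        for a in res.atoms:
            cp.atoms.append(AtomRecord(a.atom_name, a.element, a.coords.copy()))
        wt_chain.residues.append(cp)
    core_o4 = next(r for r in glyc_residues if r.seq_id == 401).get_atom("O4").coords
    for seq, name, oxys in ((184, "ASP", ("OD1", "OD2")), (186, "GLU", ("OE1", "OE2"))):
        res = Residue(name=name, seq_id=seq)
        base = core_o4 + np.array([3.0 if name == "GLU" else 4.5, 0.0, 0.0])
        res.atoms.append(AtomRecord("CA", "C", base + np.array([1.5, 1.5, 0.0])))
        for k, oxy in enumerate(oxys):
            res.atoms.append(AtomRecord(oxy, "O", base + np.array([0.0, 2.2 * k, 0.0])))
        wt_chain.residues.append(res)
    wt_chain.residues.sort(key=lambda r: r.seq_id)
    wt.chains.append(wt_chain)
    truth["dyad_min_distance_A"] = 3.0

    # unbound Fc: rigidly moved copy of chain C with residue 298 pushed 5 Å
    wt_fc = Structure("toy_wt_fc", source_format="PDB")
    move = RigidTransform.from_axis_angle((1, 1, 0), 25.0, translation=(30.0, -10.0, 5.0))
    fc_copy = Chain("C")
    for res in chain_c.residues:
        if res.get_atom("CA") is None:
            continue
        cp = Residue(name=res.name, seq_id=res.seq_id)
        xyz = move.apply(res.get_atom("CA").coords[None, :])[0]
        if res.seq_id == 298:
            xyz = xyz + np.array([0.0, 0.0, 5.0])
        cp.atoms.append(AtomRecord("CA", "C", xyz))
        fc_copy.residues.append(cp)
    wt_fc.chains.append(fc_copy)
    truth["ce_loop_peak"] = {"seq_id": 298, "deviation_A": 5.0}

    # second complex: different enzyme scaffold, closer Fc dimer
    es = get_scheme("endos")
    enz2, _, _ = make_multidomain_toy(es, atoms_per_domain=atoms_per_domain,
                                      seed=seed + 1)
    endos_complex = Structure("toy_endos_complex", source_format="PDB")
    endos_complex.chains.append(enz2.chains[0])
    cbm2 = np.array([3 * 35.0, 0.0, 0.0])
    endos_complex.chains.append(fc_chain("C", cbm2 + np.array([0.0, 0.0, 14.0])))
    endos_complex.chains.append(fc_chain("D", cbm2 + np.array([0.0, 16.0, 14.0])))

    structures = {"complex": complex_st, "unliganded": free_enzyme,
                  "wt_enzyme": wt, "wt_fc": wt_fc, "endos_complex": endos_complex}
    return structures, truth


def write_fixture(structure: Structure, path, format: str = "auto",
                  ground_truth: dict | None = None) -> Path:
    """Write a fixture structure (PDB or mmCIF) and, when ground truth is
    given, a ``<path>.json`` sidecar; output is byte-stable."""
    if not structure.chains or not any(r.atoms for c in structure.chains for r in c):
        raise ValueError("refusing to write an empty structure")
    path = Path(path)
    write_structure(structure, path, format=format)
    if ground_truth is not None:
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(ground_truth, indent=1, sort_keys=True))
    return path
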