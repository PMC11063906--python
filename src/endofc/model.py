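"""Hierarchical coordinate model, selections and domain schemes.

Coordinate files (PDB fixed-column or mmCIF/PDBx) are parsed with gemmi and
lifted into a small, explicit hierarchy ``Structure -> Chain -> Residue ->
AtomRecord``.  Author residue numbering is used throughout, because the
domain windows quoted in the structural literature for these enzymes
(GH 43-386, LRR 387-547, ...) are author-numbered.

Altloc records are preserved on read; they are resolved at selection time
by keeping the highest-occupancy conformer (ties broken A-first), which is
deterministic and matches common practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import EmptySelectionError, FormatError, ParseError

WATER_NAMES = {"HOH", "DOD", "WAT"}

#: Common monosaccharide component codes seen in N-glycans.
SACCHARIDE_NAMES = {
    "NAG", "NDG", "FUC", "FUL", "BMA", "MAN", "GAL", "GLA", "GLC", "BGC",
    "SIA", "NGA", "A2G", "XYS", "XYP",
}


@dataclass
class AtomRecord:
    """One atom: name, element, position (Å), occupancy, B factor (Å²)."""

    atom_name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    altloc: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.atom_name}: coords must be a finite 3-vector")


@dataclass
class Residue:
    name: str
    seq_id: int
    insertion_code: str = ""
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def is_water(self) -> bool:
        return self.name in WATER_NAMES

    @property
    def is_saccharide(self) -> bool:
        return self.name in SACCHARIDE_NAMES

    def get_atom(self, atom_name: str) -> AtomRecord | None:
        """Return the named atom after altloc resolution, or None."""
        best = None
        for a in self.atoms:
            if a.atom_name != atom_name:
                continue
            if best is None or (a.occupancy, -ord(a.altloc or "A")) > (
                best.occupancy, -ord(best.altloc or "A")
            ):
                best = a
        return best

    def resolved_atoms(self) -> list[AtomRecord]:
        """Atoms with altlocs collapsed to the highest-occupancy conformer."""
        seen: dict[str, AtomRecord] = {}
        for a in self.atoms:
            cur = seen.get(a.atom_name)
            if cur is None or (a.occupancy, -ord(a.altloc or "A")) > (
                cur.occupancy, -ord(cur.altloc or "A")
            ):
                seen[a.atom_name] = a
        return list(seen.values())


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def find(self, seq_id: int, insertion_code: str = "") -> Residue | None:
        for r in self.residues:
            if r.seq_id == seq_id and r.insertion_code == insertion_code:
                return r
        return None

    def __iter__(self):
        return iter(self.residues)


@dataclass
class Structure:
    identifier: str
    chains: list[Chain] = field(default_factory=list)
    source_format: str = "PDB"

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.identifier}")

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]


@dataclass
class DomainScheme:
    """Named residue-number windows (inclusive, author numbering).

    ``alignment_windows`` optionally narrows a domain's window for
    superposition (e.g. the catalytic domain is drawn 43-386 but aligned
    on 46-386); analyses that fit on a domain prefer the alignment window
    when one is defined.
    """

    name: str
    windows: dict[str, tuple[int, int]]
    alignment_windows: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.windows:
            raise ValueError("scheme must define at least one window")
        for dom, (lo, hi) in self.windows.items():
            if lo > hi:
                raise ValueError(f"window {dom}: start {lo} > end {hi}")

    def window(self, domain: str, align: bool = False) -> tuple[int, int]:
        if align and domain in self.alignment_windows:
            return self.alignment_windows[domain]
        return self.windows[domain]

    @property
    def span(self) -> tuple[int, int]:
        los, his = zip(*self.windows.values())
        return min(los), max(his)


#: Shipped domain schemes.  The enzyme windows follow the domain boundaries
#: used in the structural literature on these IgG-specific endoglycosidases.
SHIPPED_SCHEMES: dict[str, DomainScheme] = {
    "endos2": DomainScheme(
        "endos2",
        windows={"GH": (43, 386), "LRR": (387, 547), "hIg": (548, 680), "CBM": (681, 843)},
        alignment_windows={"GH": (46, 386)},
    ),
    "endos": DomainScheme(
        "endos",
        windows={"GH": (113, 445), "LRR": (446, 631), "hIg": (632, 764), "CBM": (765, 923)},
    ),
    "fc_cgamma2": DomainScheme(
        "fc_cgamma2",
        windows={"Cgamma2": (237, 340)},
        alignment_windows={"Cgamma2": (238, 340)},
    ),
}


def get_scheme(name: str) -> DomainScheme:
    try:
        return SHIPPED_SCHEMES[name]
    except KeyError:
        raise KeyError(
            f"unknown scheme {name!r}; shipped: {sorted(SHIPPED_SCHEMES)}"
        ) from None


class Selection:
    """An ordered set of resolved atoms from one Structure.

    ``members`` is the ordered list of (chain_id, seq_id, atom_name) keys and
    ``coords`` the matching N x 3 coordinate matrix (Å).  ``n_skipped``
    counts residues of the requested range missing from the model.
    """

    def __init__(
        self,
        parent: Structure,
        triples: Sequence[tuple[Chain, Residue, AtomRecord]],
        n_skipped: int = 0,
    ) -> None:
        self.parent = parent
        self.triples = list(triples)
        self.n_skipped = n_skipped

    @property
    def members(self) -> list[tuple[str, int, str]]:
        return [(c.chain_id, r.seq_id, a.atom_name) for c, r, a in self.triples]

    @property
    def coords(self) -> np.ndarray:
        if not self.triples:
            return np.empty((0, 3))
        return np.array([a.coords for _, _, a in self.triples])

    @property
    def elements(self) -> list[str]:
        return [a.element for _, _, a in self.triples]

    def __len__(self) -> int:
        return len(self.triples)

    def __iter__(self):
        return iter(self.triples)

    def subset(self, indices: Iterable[int]) -> "Selection":
        idx = list(indices)
        return Selection(self.parent, [self.triples[i] for i in idx], self.n_skipped)


def _detect_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        f = fmt.lower()
        if f in ("pdb",):
            return "PDB"
        if f in ("mmcif", "cif", "pdbx"):
            return "mmCIF"
        raise FormatError(f"unknown coordinate format {fmt!r}")
    suffix = path.suffix.lower()
    if suffix in (".pdb", ".ent"):
        return "PDB"
    if suffix in (".cif", ".mmcif"):
        return "mmCIF"
    raise FormatError(f"cannot infer format from suffix {suffix!r} of {path}")


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into the hierarchy.

    All ATOM and HETATM records are retained, altlocs preserved, and the
    author residue numbering kept as ``seq_id``.  Only the first model of a
    multi-model file is read.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    fmt = _detect_format(path, format)
    try:
        if fmt == "PDB":
            st = gemmi.read_pdb(str(path))
        else:
            doc = gemmi.cif.read(str(path))
            st = gemmi.make_structure_from_block(doc.sole_block())
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path} as {fmt}: {exc}") from exc

    if len(st) == 0:
        raise ParseError(f"{path}: no models")
    out = Structure(identifier=path.stem, source_format=fmt)
    for gchain in st[0]:
        chain = Chain(chain_id=gchain.name)
        for gres in gchain:
            res = Residue(
                name=gres.name,
                seq_id=gres.seqid.num,
                insertion_code=(gres.seqid.icode or "").strip(),
            )
            for ga in gres:
                res.atoms.append(
                    AtomRecord(
                        atom_name=ga.name,
                        element=ga.element.name,
                        coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        occupancy=ga.occ,
                        b_factor=ga.b_iso,
                        altloc=(ga.altloc or "").strip(),
                        is_hetero=(gres.het_flag == "H"),
                    )
                )
            if res.atoms:
                chain.residues.append(res)
        if chain.residues:
            out.chains.append(chain)
    if not out.chains:
        raise ParseError(f"{path}: no atoms found")
    return out


def to_gemmi(structure: Structure) -> gemmi.Structure:
    """Convert the hierarchy back to a gemmi Structure (for writing)."""
    st = gemmi.Structure()
    st.name = structure.identifier
    model = gemmi.Model("1")
    for chain in structure.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seq_id, res.insertion_code or " ")
            gres.het_flag = "H" if (res.atoms and res.atoms[0].is_hetero) else "A"
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.atom_name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coords)
                ga.occ = a.occupancy
                ga.b_iso = a.b_factor
                ga.altloc = a.altloc or "\0"
                gres.add_atom(ga)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(structure: Structure, path: str | Path, format: str = "auto") -> Path:
    """Write the hierarchy as PDB or mmCIF; the output is byte-stable."""
    path = Path(path)
    fmt = _detect_format(path, format)
    st = to_gemmi(structure)
    if fmt == "PDB":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))
    return path


def select(
    structure: Structure,
    chain_id: str,
    seq_range: tuple[int, int] | None = None,
    atom_names: Sequence[str] | str = "all",
    include_water: bool = False,
    include_hetero: bool = True,
) -> Selection:
    """Select atoms of one chain, optionally restricted by residue window
    and atom names.  Altlocs are resolved keep-highest-occupancy.

    Residues of the requested window missing from the model are skipped
    silently but counted in ``Selection.n_skipped``.  An empty result raises
    :class:`EmptySelectionError`.
    """
    chain = structure.chain(chain_id)
    names = None if atom_names == "all" else set(atom_names)
    triples: list[tuple[Chain, Residue, AtomRecord]] = []
    present: set[int] = set()
    for res in chain.residues:
        if seq_range is not None and not (seq_range[0] <= res.seq_id <= seq_range[1]):
            continue
        if res.is_water and not include_water:
            continue
        if res.atoms and res.atoms[0].is_hetero and not include_hetero and not res.is_saccharide:
            continue
        present.add(res.seq_id)
        for a in res.resolved_atoms():
            if names is None or a.atom_name in names:
                triples.append((chain, res, a))
    n_skipped = 0
    if seq_range is not None:
        n_skipped = (seq_range[1] - seq_range[0] + 1) - len(
            present & set(range(seq_range[0], seq_range[1] + 1))
        )
    if not triples:
        raise EmptySelectionError(
            f"selection {chain_id}:{seq_range}:{atom_names} resolved to 0 atoms"
        )
    return Selection(structure, triples, n_skipped=n_skipped)


def _chain_heavy_coords(chain: Chain, include_water: bool = False) -> np.ndarray:
    pts = []
    for res in chain.residues:
        if res.is_water and not include_water:
            continue
        for a in res.resolved_atoms():
            if a.element != "H":
                pts.append(a.coords)
    return np.array(pts) if pts else np.empty((0, 3))


def _is_enzyme_like(chain: Chain, scheme: DomainScheme, min_per_window: int = 10) -> bool:
    """True when the chain populates most of the scheme's domain windows.

    A partner chain (e.g. an Fc gamma chain) overlaps at most one or two
    enzyme windows numerically; the enzyme itself populates them all.
    """
    covered = 0
    for lo, hi in scheme.windows.values():
        n = sum(1 for r in chain.residues if lo <= r.seq_id <= hi and not r.is_water)
        if n >= min_per_window:
            covered += 1
    return covered >= min(3, len(scheme.windows))


def pair_complex_copies(
    structure: Structure,
    enzyme_scheme: DomainScheme,
    max_distance: float = 5.0,
) -> list[tuple[str, str]]:
    """Pair each enzyme-like chain with its closest non-enzyme partner.

    A chain is enzyme-like when it covers at least half of the scheme's
    residue span.  The partner is the other chain with the smallest minimum
    heavy-atom distance; an enzyme chain with no partner within
    ``max_distance`` Å is omitted with a warning.  Pairs are ordered by
    enzyme chain id.
    """
    if len(structure.chains) < 2:
        warnings.warn("structure has fewer than 2 chains; no pairs")
        return []
    enzyme = [c for c in structure.chains if _is_enzyme_like(c, enzyme_scheme)]
    partners = [c for c in structure.chains if c not in enzyme]
    if not enzyme or not partners:
        warnings.warn("no enzyme/partner chain split found; no pairs")
        return []
    partner_trees = [
        (c, cKDTree(_chain_heavy_coords(c))) for c in partners if len(_chain_heavy_coords(c))
    ]
    pairs: list[tuple[str, str]] = []
    for ec in sorted(enzyme, key=lambda c: c.chain_id):
        pts = _chain_heavy_coords(ec)
        best, best_d = None, np.inf
        for pc, tree in partner_trees:
            d = tree.query(pts, k=1)[0].min()
            if d < best_d:
                best, best_d = pc, d
        if best is None or best_d > max_distance:
            warnings.warn(
                f"chain {ec.chain_id}: no partner within {max_distance} Å (closest "
                f"{best_d:.1f} Å); omitted"
            )
            continue
        pairs.append((ec.chain_id, best.chain_id))
    return pairs


def domain_bfactor_summary(structure: Structure, scheme: DomainScheme) -> pd.DataFrame:
    """Mean Cα B factor per (chain, domain window).

    Raises if no Cα atoms with finite B factors fall in any window.
    """
    rows = []
    for chain in structure.chains:
        for dom, (lo, hi) in scheme.windows.items():
            bs = [
                a.b_factor
                for r in chain.residues
                if lo <= r.seq_id <= hi
                for a in [r.get_atom("CA")]
                if a is not None and np.isfinite(a.b_factor)
            ]
            if bs:
                rows.append({"chain": chain.chain_id, "domain": dom,
                             "mean_b": float(np.mean(bs)), "n_ca": len(bs)})
    if not rows:
        raise EmptySelectionError("no Cα atoms with B factors in any scheme window")
    return pd.DataFrame(rows).set_index(["chain", "domain"])
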