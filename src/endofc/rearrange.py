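"""Inter-domain rearrangement between two conformers of a multi-domain
protein, plus Fc-specific geometry.

The rearrangement protocol: superpose conformer A onto conformer B globally
on the Cα atoms of a chosen reference domain, then for every other domain
report (i) the Cα displacement RMSD in that frame, without re-fitting, and
(ii) the magnitude of the residual local rotation obtained by a Kabsch fit
of that domain alone.  "Tilt"/"offset" is thus the total rotation angle of
the local fit; no axis projection is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import EmptySelectionError, InsufficientAtomsError, NoOverlapError
from .model import DomainScheme, Structure, select
from .superpose import kabsch_fit, match_residues, rmsd_noalign, rotation_angle


@dataclass
class DomainEntry:
    rotation_angle: float      # degrees, [0, 180]
    displacement_rmsd: float   # Å, after the reference-domain alignment
    n_matched: int


@dataclass
class DomainRearrangementReport:
    reference_domain: str
    reference_fit_rmsd: float
    reference_n_matched: int
    domains: dict[str, DomainEntry] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"domain": d, "rotation_deg": e.rotation_angle,
             "displacement_rmsd_A": e.displacement_rmsd, "n_matched": e.n_matched}
            for d, e in self.domains.items()
        ]
        return pd.DataFrame(rows)


def _ca_selection(struct: Structure, chain: str, window: tuple[int, int]):
    return select(struct, chain, seq_range=window, atom_names=["CA"])


def domain_rearrangement(
    struct_a: Structure,
    chain_a: str,
    struct_b: Structure,
    chain_b: str,
    scheme: DomainScheme,
    reference_domain: str,
) -> DomainRearrangementReport:
    """Quantify per-domain reorientation of chain A relative to chain B
    after aligning on the reference domain's Cα atoms.

    Domains with fewer than 3 matched Cα are skipped with a warning.
    Missing residues inside windows are tolerated: every comparison uses
    the intersection of resolved residues.
    """
    ref_win = scheme.window(reference_domain, align=True)
    ref_a = _ca_selection(struct_a, chain_a, ref_win)
    ref_b = _ca_selection(struct_b, chain_b, ref_win)
    A, B = match_residues(ref_a, ref_b)
    global_fit = kabsch_fit(A, B)
    report = DomainRearrangementReport(
        reference_domain=reference_domain,
        reference_fit_rmsd=global_fit.rmsd,
        reference_n_matched=global_fit.n_matched,
    )
    for dom in scheme.windows:
        if dom == reference_domain:
            continue
        try:
            da = _ca_selection(struct_a, chain_a, scheme.windows[dom])
            db = _ca_selection(struct_b, chain_b, scheme.windows[dom])
            Da, Db = match_residues(da, db)
        except (EmptySelectionError, NoOverlapError):
            warnings.warn(f"domain {dom}: no matched Cα; skipped")
            continue
        if Da.shape[0] < 3:
            warnings.warn(f"domain {dom}: fewer than 3 matched Cα; skipped")
            continue
        Da_aligned = global_fit.transform.apply(Da)
        local = kabsch_fit(Da_aligned, Db)
        report.domains[dom] = DomainEntry(
            rotation_angle=rotation_angle(local.transform),
            displacement_rmsd=rmsd_noalign(Da_aligned, Db),
            n_matched=Da.shape[0],
        )
    return report


def interdomain_distance(
    structure: Structure,
    chain_id: str,
    domain_a: str,
    domain_b: str,
    scheme: DomainScheme,
    metric: str = "min",
) -> float:
    """Distance between two domains of one chain (Å).

    ``metric='min'``: smallest pairwise heavy-atom distance;
    ``metric='centroid'``: distance between Cα centroids.
    """
    if metric not in ("min", "centroid"):
        raise ValueError(f"unknown metric {metric!r}")
    wa, wb = scheme.windows[domain_a], scheme.windows[domain_b]
    if metric == "centroid":
        ca = _ca_selection(structure, chain_id, wa).coords.mean(axis=0)
        cb = _ca_selection(structure, chain_id, wb).coords.mean(axis=0)
        return float(np.linalg.norm(ca - cb))
    heavy_a = select(structure, chain_id, seq_range=wa)
    heavy_b = select(structure, chain_id, seq_range=wb)
    pa = heavy_a.coords[[e != "H" for e in heavy_a.elements]]
    pb = heavy_b.coords[[e != "H" for e in heavy_b.elements]]
    return float(cKDTree(pa).query(pb, k=1)[0].min())


def cgamma2_separation(
    struct: Structure,
    fc_chain_a: str,
    fc_chain_b: str,
    window: tuple[int, int] = (237, 340),
) -> float:
    """Distance (Å) between the Cα centroids of the two Cγ2 domains of an
    Fc homodimer — larger values mean a more "open" Fc conformation."""
    ca = _ca_selection(struct, fc_chain_a, window).coords.mean(axis=0)
    cb = _ca_selection(struct, fc_chain_b, window).coords.mean(axis=0)
    return float(np.linalg.norm(ca - cb))


def per_residue_deviation(
    struct_a: Structure,
    chain_a: str,
    struct_b: Structure,
    chain_b: str,
    align_window: tuple[int, int],
    report_window: tuple[int, int] | None = None,
) -> pd.Series:
    """Per-residue Cα distance profile after a Kabsch fit on
    ``align_window``, indexed by seq_id in sequence order.

    Used to locate localized conformational change (e.g. the C′E loop of
    an Fc Cγ2 domain) against a reference structure.
    """
    ref_a = _ca_selection(struct_a, chain_a, align_window)
    ref_b = _ca_selection(struct_b, chain_b, align_window)
    A, B = match_residues(ref_a, ref_b)
    if A.shape[0] < 3:
        raise InsufficientAtomsError("fewer than 3 shared residues in align window")
    fit = kabsch_fit(A, B)
    win = report_window or align_window
    all_a = _ca_selection(struct_a, chain_a, win)
    all_b = _ca_selection(struct_b, chain_b, win)
    key_a = {r.seq_id: a.coords for _, r, a in all_a}
    key_b = {r.seq_id: a.coords for _, r, a in all_b}
    common = sorted(set(key_a) & set(key_b))
    if not common:
        raise NoOverlapError("no shared residues to profile")
    moved = fit.transform.apply(np.array([key_a[s] for s in common]))
    dist = np.linalg.norm(moved - np.array([key_b[s] for s in common]), axis=1)
    return pd.Series(dist, index=pd.Index(common, name="seq_id"), name="ca_deviation_A")
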