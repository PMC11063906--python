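"""Full-study orchestration: run every analysis on a set of user-supplied
coordinate files and emit machine-readable comparison tables.

The run is driven by a :class:`RunConfig` naming local files by role:

- ``complex``        the enzyme-Fc complex to analyse (all copies)
- ``unliganded``     the free enzyme, for domain-rearrangement reference
- ``endos_complex``  a second enzyme-Fc complex, for cross-enzyme comparison
- ``wt_enzyme``      wild-type enzyme with intact catalytic dyad
- ``wt_fc``          an unbound Fc, for the C'E-loop deviation profile

A missing file disables only the analyses that need it; every skip is
logged.  No network access: files are fetched separately (see
``scripts/fetch_structures.sh``) and referenced by path.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import glycan as glycan_mod
from . import interface as iface_mod
from . import rearrange as rearr_mod
from .model import DomainScheme, Structure, get_scheme, pair_complex_copies, read_structure, select

log = logging.getLogger("endofc")

#: Published reference values for the deposited enzyme-Fc entries, used
#: only to annotate the side-by-side comparison column of the output table.
REFERENCE_VALUES = {
    "rearrangement/GH/LRR/rotation_deg": 10.0,
    "rearrangement/GH/hIg/displacement_A": 8.2,
    "rearrangement/GH/CBM/displacement_A": 19.4,
    "rearrangement/CBM/hIg/rotation_deg": 4.2,
    "rearrangement/CBM/LRR/displacement_A": 5.1,
    "rearrangement/CBM/GH/displacement_A": 6.3,
    "rearrangement/LRR/hIg/rotation_deg": 11.6,
    "interface/total_A2": 978.0,
    "interface/CBM_A2": 608.0,
    "interface/GH_A2": 369.0,
    "interface/delta_g_kcal_mol": -8.6,
    "glycan/core_b14_phi_deg": 5.9,
    "distance/GH_CBM_min_A": 25.0,
}


@dataclass
class RunConfig:
    files: dict[str, Path]
    enzyme_scheme: str = "endos2"
    fc_scheme: str = "fc_cgamma2"
    asn_seq: int = 297
    dyad: list[int] = field(default_factory=lambda: [184, 186])
    contact_cutoff: float = 4.5
    hbond_cutoff: float = 3.5
    sasa_points: int = 960
    out_dir: Path = Path("results")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        raw = tomllib.loads(Path(path).read_text())
        files = {k: Path(v) for k, v in raw.get("files", {}).items()}
        kwargs = {k: v for k, v in raw.items() if k != "files"}
        if "out_dir" in kwargs:
            kwargs["out_dir"] = Path(kwargs["out_dir"])
        return cls(files=files, **kwargs)

    def validate(self) -> None:
        missing = [f"{role}={p}" for role, p in self.files.items() if not p.exists()]
        if missing:
            raise FileNotFoundError("missing input files: " + ", ".join(missing))


def _load(config: RunConfig, role: str) -> Structure | None:
    path = config.files.get(role)
    if path is None or not Path(path).exists():
        log.warning("input %r not provided; dependent analyses skipped", role)
        return None
    return read_structure(path)


def _fc_dimer_pairs(struct: Structure, enzyme_scheme: DomainScheme) -> list[tuple[str, str]]:
    """Pair the non-enzyme (Fc) chains among themselves by proximity."""
    from .model import _chain_heavy_coords, _is_enzyme_like
    from scipy.spatial import cKDTree

    fc = [c for c in struct.chains if not _is_enzyme_like(c, enzyme_scheme)]
    pairs, used = [], set()
    for c in sorted(fc, key=lambda c: c.chain_id):
        if c.chain_id in used:
            continue
        best, best_d = None, np.inf
        pts = _chain_heavy_coords(c)
        for o in fc:
            if o is c or o.chain_id in used:
                continue
            d = cKDTree(_chain_heavy_coords(o)).query(pts, k=1)[0].min()
            if d < best_d:
                best, best_d = o, d
        if best is not None and best_d < 15.0:
            pairs.append((c.chain_id, best.chain_id))
            used.update({c.chain_id, best.chain_id})
    return pairs


class ReproductionTable:
    """Accumulates (quantity, value, units, reference, provenance) rows."""

    def __init__(self) -> None:
        self.rows: list[dict] = []

    def add(self, quantity: str, value: float, units: str, provenance: str,
            reference_key: str | None = None) -> None:
        self.rows.append({
            "quantity": quantity,
            "value": round(float(value), 4),
            "units": units,
            "reference_value": REFERENCE_VALUES.get(reference_key or quantity, ""),
            "provenance": provenance,
        })

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def run_report(config: RunConfig) -> pd.DataFrame:
    """Run every applicable analysis and write the output files.

    Outputs under ``config.out_dir``: ``reproduction.tsv`` (the main
    table), ``interfaces.json``, ``rearrangement.tsv``, ``glycan.tsv`` and
    ``run.log``.  Returns the main table as a DataFrame.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    enzyme_scheme = get_scheme(config.enzyme_scheme)
    fc_scheme = get_scheme(config.fc_scheme)
    fc_window = fc_scheme.window(next(iter(fc_scheme.windows)))
    table = ReproductionTable()
    rearr_rows: list[dict] = []
    glycan_rows: list[dict] = []
    interfaces: dict = {}

    complex_st = _load(config, "complex")
    if complex_st is None:
        raise FileNotFoundError("the 'complex' input is required")
    pairs = pair_complex_copies(complex_st, enzyme_scheme)
    log.info("complex %s: %d enzyme-partner pairs: %s",
             complex_st.identifier, len(pairs), pairs)
    table.add("n_complex_copies", len(pairs), "count", complex_st.identifier)

    try:
        from .model import domain_bfactor_summary
        bsum = domain_bfactor_summary(complex_st, enzyme_scheme)
        enzyme_chains = {e for e, _ in pairs}
        for (chain, dom), row in bsum.iterrows():
            if chain in enzyme_chains:
                table.add(f"bfactor/{chain}/{dom}_mean", row["mean_b"], "A2",
                          f"{complex_st.identifier}:{chain}")
    except Exception as exc:  # B factors are optional input
        log.warning("B-factor summary skipped: %s", exc)

    unliganded = _load(config, "unliganded")
    wt_fc = _load(config, "wt_fc")
    wt_enzyme = _load(config, "wt_enzyme")
    endos_complex = _load(config, "endos_complex")

    for enz_chain, fc_chain in pairs:
        prov = f"{complex_st.identifier}:{enz_chain}-{fc_chain}"
        # --- domain rearrangement vs the unliganded enzyme
        if unliganded is not None:
            free_chain = unliganded.chain_ids[0]
            for ref_dom in ("GH", "CBM", "LRR"):
                rep = rearr_mod.domain_rearrangement(
                    complex_st, enz_chain, unliganded, free_chain,
                    enzyme_scheme, ref_dom)
                for dom, e in rep.domains.items():
                    rearr_rows.append({
                        "copy": prov, "reference": ref_dom, "domain": dom,
                        "rotation_deg": round(e.rotation_angle, 2),
                        "displacement_rmsd_A": round(e.displacement_rmsd, 2),
                        "n_matched": e.n_matched,
                    })
                    table.add(f"rearrangement/{ref_dom}/{dom}/rotation_deg",
                              e.rotation_angle, "deg", prov)
                    table.add(f"rearrangement/{ref_dom}/{dom}/displacement_A",
                              e.displacement_rmsd, "A", prov)
        # --- interfaces
        radii = iface_mod.DEFAULT_RADII
        side_e = select(complex_st, enz_chain)
        side_f = select(complex_st, fc_chain)
        rep = iface_mod.interface_report(
            side_e, side_f, radii, config.sasa_points,
            config.contact_cutoff, config.hbond_cutoff)
        table.add("interface/total_A2", rep.buried_area, "A2", prov)
        table.add("interface/delta_g_kcal_mol", rep.delta_g_solv, "kcal/mol", prov)
        dom_areas = {}
        for dom in ("GH", "CBM"):
            area = iface_mod.domain_restricted_interface(
                side_e, enzyme_scheme.windows[dom], side_f, radii, config.sasa_points)
            dom_areas[dom] = area
            table.add(f"interface/{dom}_A2", area, "A2", prov)
        interfaces[prov] = {
            "buried_area_A2": rep.buried_area,
            "delta_g_solv_kcal_mol": rep.delta_g_solv,
            "domain_areas_A2": dom_areas,
            "contacts": [
                {"a": c.residue_a, "b": c.residue_b, "min_distance_A": round(c.min_distance, 2)}
                for c in rep.contacts],
            "hbonds": [
                {"donor": b.donor, "acceptor": b.acceptor, "distance_A": round(b.distance, 2)}
                for b in rep.hbonds],
        }
        # --- glycan geometry at the conserved Asn
        try:
            tree = glycan_mod.detect_glycan(complex_st, (fc_chain, config.asn_seq))
        except glycan_mod.NoGlycanError as exc:
            log.warning("glycan %s: %s", prov, exc)
            tree = None
        if tree is not None:
            for link in tree.linkages:
                glycan_rows.append({
                    "copy": prov, "donor": f"{link.donor.code}{link.donor.seq_id}",
                    "acceptor": f"{link.acceptor_name}",
                    "oxygen": link.acceptor_atom,
                    "phi_deg": round(link.phi, 1), "psi_deg": round(link.psi, 1),
                })
                if link.acceptor_atom == "O4":
                    table.add("glycan/core_b14_phi_deg", link.phi, "deg", prov)
            for g in tree.residues:
                try:
                    p = glycan_mod.ring_pucker(g.residue)
                except glycan_mod.MissingAtomError:
                    continue
                glycan_rows.append({
                    "copy": prov, "donor": f"{g.code}{g.seq_id}", "acceptor": "",
                    "oxygen": "", "phi_deg": "", "psi_deg": "",
                    "Q_A": round(p.Q, 2), "theta_deg": round(p.theta, 1),
                    "phi2_deg": round(p.phi2, 1), "conformer": p.conformer_label,
                })
        # --- GH-CBM inter-domain distance (enzyme conformational state)
        for metric in ("min", "centroid"):
            d = rearr_mod.interdomain_distance(
                complex_st, enz_chain, "GH", "CBM", enzyme_scheme, metric)
            table.add(f"distance/GH_CBM_{metric}_A", d, "A", prov)
        # --- C'E loop deviation vs an unbound Fc
        if wt_fc is not None:
            wt_chain = wt_fc.chain_ids[0]
            align = fc_scheme.window(next(iter(fc_scheme.windows)), align=True)
            profile = rearr_mod.per_residue_deviation(
                complex_st, fc_chain, wt_fc, wt_chain, align)
            peak = int(profile.idxmax())
            table.add("fc/ce_loop_peak_residue", peak, "seq_id",
                      f"{prov} vs {wt_fc.identifier}")
            table.add("fc/ce_loop_peak_deviation_A", float(profile.max()), "A",
                      f"{prov} vs {wt_fc.identifier}")
        # --- active-site overlay vs the wild-type enzyme
        if wt_enzyme is not None and tree is not None:
            core = next((l for l in tree.linkages if l.acceptor_atom == "O4"), None)
            if core is not None and core.acceptor is not None:
                try:
                    asr = glycan_mod.active_site_geometry(
                        complex_st, enz_chain, wt_enzyme, wt_enzyme.chain_ids[0],
                        enzyme_scheme.window("GH", align=True), config.dyad,
                        (core.acceptor.chain_id, core.acceptor.seq_id, "O4"),
                        (core.donor.chain_id, core.donor.seq_id, "C1"))
                    table.add("active_site/gh_fit_rmsd_A", asr.gh_fit_rmsd, "A", prov)
                    for key, dist in asr.distances.items():
                        table.add(f"active_site/{key}_A", dist, "A", prov)
                except glycan_mod.MissingAtomError as exc:
                    log.warning("active site %s: %s", prov, exc)

    # --- Fc openness: Cgamma2 centroid separation of each Fc dimer
    for st in (complex_st, endos_complex):
        if st is None:
            continue
        scheme = enzyme_scheme if st is complex_st else get_scheme("endos")
        for a, b in _fc_dimer_pairs(st, scheme):
            sep = rearr_mod.cgamma2_separation(st, a, b, fc_window)
            table.add("fc/cgamma2_separation_A", sep, "A", f"{st.identifier}:{a}-{b}")

    frame = table.to_frame()
    frame.to_csv(out / "reproduction.tsv", sep="\t", index=False)
    pd.DataFrame(rearr_rows).to_csv(out / "rearrangement.tsv", sep="\t", index=False)
    pd.DataFrame(glycan_rows).to_csv(out / "glycan.tsv", sep="\t", index=False)
    (out / "interfaces.json").write_text(json.dumps(interfaces, indent=1, default=list))
    log.info("wrote %d table rows to %s", len(frame), out)
    log.removeHandler(handler)
    handler.close()
    return frame
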