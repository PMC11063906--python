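# Methods

This note documents the models, conventions and numerical choices behind
`endofc`, and what the synthetic fixtures do and do not establish about
real crystallographic data.

## Coordinate model

Files are parsed with gemmi (PDB fixed-column and mmCIF/PDBx) into a small
explicit hierarchy. **Author residue numbering** is used throughout,
because the domain windows conventional for these enzymes (GH 43–386,
LRR 387–547, hIg 548–680, CBM 681–843 for EndoS2; GH 113–445, LRR 446–631,
hIg 632–764, CBM 765–923 for EndoS; Cγ2 237–340 for IgG1 Fc) are
author-numbered. Alternate locations are kept on read and resolved at
selection time to the highest-occupancy conformer, ties broken A-first —
deterministic and standard. Residues missing from a requested window are
skipped silently but counted (`Selection.n_skipped`); superpositions
always use the intersection of residues resolved in both structures.
Waters are excluded from selections by default; saccharide heteroatoms
stay attached to their parent chain so the Fc glycan contributes to the
catalytic-domain interface.

Enzyme chains in a multi-copy asymmetric unit are identified as chains
populating at least three of the scheme's domain windows (an Fc chain's
numbering overlaps at most two), and each is paired with the non-enzyme
chain at smallest minimum heavy-atom distance (within 5 Å; unpaired
chains are dropped with a warning). Every copy is analysed and reported —
no copy is chosen silently.

## Superposition and rearrangement

The rigid fit is the closed-form Kabsch solution: SVD of the centered
cross-covariance with the sign of the smallest singular vector flipped
when det < 0, so only proper rotations are returned. Fits use Cα atoms
matched by (residue number, atom name). The total rotation magnitude is
θ = arccos((tr R − 1)/2) with the argument clamped to [−1, 1]; near the
identity this expression is accurate to roughly 10⁻⁵ degrees in double
precision, which sets the floor for "zero rotation" assertions.

Domain rearrangement between two conformers: (1) a single global fit of A
onto B on the reference domain's Cα (GH uses its alignment window
46–386); (2) for every other domain, the Cα displacement RMSD in that
frame *without re-fitting*, plus the rotation magnitude of a local Kabsch
fit of that domain. A domain "tilt" is thus reported as the total rotation
angle of the local best-fit transform; no axis projection or hinge
localization is attempted, since no axis convention is standard for these
comparisons. Domains with fewer than three matched Cα are skipped with a
warning.

Inter-domain distance supports two metrics, reported explicitly: smallest
pairwise heavy-atom distance (the convention used for open/closed enzyme
states) and Cα-centroid distance. Fc "openness" is the distance between
Cα centroids of the two Cγ2 windows of the homodimer. The per-residue
deviation profile (for localizing loop movement such as the Cγ2 C′E loop)
aligns on a window — 238–340 for Fc Cγ2 comparisons — then reports every
matched residue's Cα distance in sequence order.

## Surface area, buried interfaces and solvation energy

SASA is Shrake–Rupley with a golden-spiral point set: test points are
placed quasi-uniformly (deterministically — no RNG anywhere in the
analyses) on each atom's expanded sphere of radius r_vdW + probe, and a
point is accessible when outside every neighbour's expanded sphere. The
default is 960 points and a 1.4 Å water probe; on fixtures the total
changes by well under 1% between 960 and 4000 points, and one- and
two-atom systems match the analytic 4πR² and spherical-cap forms to
better than 1–2%.

Two radii tables ship: `chothia` (default for proteins) with
NACCESS/Chothia-style atom classes — aliphatic C 1.87 Å,
aromatic/carbonyl C 1.76 Å, N 1.65 Å, O 1.40 Å, S 1.85 Å — and `element`,
a plain per-element vdW table (C 1.70, O 1.40, …) used by the analytic
fixtures. Both are overridable.

Buried interface area follows the PISA convention,
(SASA(A) + SASA(B) − SASA(A∪B))/2. The domain-restricted variant keeps
occlusion in the context of the full chain:

    buried(w) = ½ [ Σ_{a∈w} ΔASA_a  +  Σ_{b∈B} (ASA_b(B ∪ A\w) − ASA_b(B ∪ A)) ]

which reduces exactly to the total at the identity restriction and is
additive over disjoint windows covering all contacts to within
point-count noise (≈2 Å² on the fixtures).

The solvation-energy gain is ΔG = Σᵢ σ(classᵢ)·(ASAᵢ(complex) −
ASAᵢ(alone)) over both sides, with Eisenberg–McLachlan-style atomic
solvation parameters (kcal·mol⁻¹·Å⁻²): C +0.016, neutral N/O −0.006,
charged O −0.024, charged N −0.050, S +0.021. Burying apolar area makes
the gain negative (favourable). PISA's internal parameter set is not
published in full, so agreement with PISA-derived values should be
expected in sign and rough magnitude (within a factor of ~2), not to the
printed decimal.

Contacts are residue pairs with any heavy-atom distance ≤ 4.5 Å (sorted
by minimum distance). Hydrogen bonds are donor–acceptor heavy-atom pairs
≤ 3.5 Å from per-residue templates (backbone N donates, backbone O
accepts; side chains and sugars per standard chemistry), with an
antecedent–donor–acceptor angle ≥ 90° required when a covalent antecedent
exists. No explicit hydrogens are used — appropriate at the ~3 Å
resolution typical of these complexes. Both cutoffs are CLI-overridable.
Every reported hydrogen bond is necessarily also a contact at the default
cutoffs.

## Glycan geometry

The N-glycan is found by a breadth-first covalent walk from the Asn ND2
over saccharide residues, bonding each sugar's anomeric C1 to an acceptor
N/O at ≤ 1.8 Å (a standard single-bond upper bound); linkage type follows
from the acceptor oxygen (O4 → 1-4 core linkage, O6 → 1-6 fucose). The
walk sorts candidates by chain and residue number, so the result is
independent of record order in the file.

Glycosidic torsions use the heavy-atom convention Φ = O5–C1–Ox–Cx,
Ψ = C1–Ox–Cx–C(x+1), signed per IUPAC; this is the convention of the
crystallographic surveys against which distorted linkages are judged
(mean core GlcNAc β1–4 Φ of −74° ± 8.4°). The NMR (H1-based) convention
is available behind a flag when explicit hydrogens exist. A signed
torsion is invariant under full reversal of the atom order and changes
sign when the two central atoms are swapped; the tests assert both.

Ring puckering uses Cremer–Pople (Q, θ, φ₂) with ring atoms ordered
O5, C1…C5, which puts the relaxed ⁴C₁ pyranose chair at θ = 0° and ¹C₄ at
180°. Conformers are labelled by nearest canonical point on the (θ, φ₂)
sphere: 2 chairs, 6 boats and 6 skew-boats on the equator (e.g. ¹S₃ at
φ₂ = 210°), plus half-chairs and envelopes in the mid-bands at the
θ values (50.8°, 54.7° and mirrors) that follow from their ideal
displacement patterns. Rings with Q < 10⁻³ Å are labelled planar. The
forward construction (`make_ring_coords`) inverts exactly on the whole
canonical set to within 1° and 0.01 Å.

The active-site overlay superposes a wild-type enzyme's catalytic-domain
Cα onto the complex and reports distances from the dyad's carboxyl
oxygens (Asp OD1/OD2, Glu OE1/OE2) to the scissile linkage's glycosidic
oxygen and anomeric carbon — the geometric test of whether the
general-acid/nucleophile pair is positioned against the distorted bond.

## Synthetic fixtures: what they show and what they do not

All generators are deterministic given their parameters and seed, and emit
their ground truth (applied transforms, exact torsions, puckering
coordinates) alongside, optionally as a JSON sidecar, so tests never
re-derive it.

- Multi-domain toys: Gaussian Cα clouds (sd 8 Å, 35 Å centroid spacing —
  compact-domain scale) with exact per-domain rigid transforms about each
  centroid and optional iid coordinate noise. Default 0.3 Å noise in the
  recovery studies corresponds to the coordinate uncertainty scale of a
  ~3 Å-resolution structure; with 60 atoms per domain, the planted 10°
  rotation is recovered to within 0.5° in the mean over 20 seeds.
- Sphere clusters: one- and two-atom systems whose accessible areas have
  closed forms (isolated sphere; spherical caps at 2.0 Å separation,
  giving a derived two-atom interface of 40.90 Å² with the element
  radii).
- Disaccharides and rings: idealized 4C1 pyranoses joined at *exact*
  (Φ, Ψ) by construction (the donor is placed by internal coordinates,
  then spun about the glycosidic bond to the target Φ), and rings built
  directly from the Cremer–Pople forward equations.
- The composite binding study wires all of these into the five input
  roles of the full pipeline (complex with glycosylated Fc and Fc dimer
  partner, rearranged free enzyme, wild-type enzyme with dyad, displaced
  unbound Fc, second closer-dimer complex).

Passing on these fixtures establishes that the geometry, area and
detection code is numerically correct and self-consistent. It does not
exercise real-data pathology — alternate conformations at interfaces,
missing loops inside alignment windows, non-standard saccharide codes,
or genuinely ambiguous chain pairing — beyond the specific cases tested,
and toy interface magnitudes are not calibrated to protein-sized values.
Reproduction of published interface areas and rearrangement values runs
against the deposited entries (PDB 8Q5U, 6E58, 8A49, 6MDS, 3AVE) when
those files are supplied locally (`scripts/fetch_structures.sh`); the
analysis tool itself performs no network access.

## Numerical choices and degenerate inputs

- Kabsch requires ≥ 3 pairs; near-collinear point sets trigger a
  conditioning warning. Reflections are never returned.
- Zero-rotation assertions use a 10⁻⁵-degree floor (arccos conditioning);
  noiseless transform recovery is exact to 10⁻⁶ in angle and translation.
- SASA point counts below 64 are rejected; unknown elements raise with
  the offending atom named rather than defaulting silently.
- Torsions are reported in (−180°, 180°]; φ₂ in [0°, 360°).
- Empty selections raise a dedicated error type, distinct from parse
  errors, so callers can tell a bad window from a bad file.
- Report runs are bit-stable: re-running an identical configuration
  reproduces identical output files.

## Problem sizes

The test-suite and acceptance-script runs use 100 random fit instances,
20-seed noise ensembles, 25–80 atoms per toy domain and 960-point (4000
for convergence checks) SASA spheres — sizes chosen so each check
resolves its tolerance comfortably while the whole suite stays
interactive-fast.
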