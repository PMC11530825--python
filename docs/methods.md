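# Methods

This note documents the models, conventions and numerical choices behind
`rnacontactdyn`, and what the synthetic validation does and does not show
about real trajectory data.

## Scope and data model

The package analyses ordered structural ensembles of RNA complexes: a
`StructureTopology` (atoms with base/backbone roles, residues with region
labels, donor/acceptor/apolar/charged atom sets, optional nonbonded
parameters) plus an `Ensemble` of coordinate frames with strictly
increasing time stamps (ns). The baseline interchange format is multi-model
PDB; frames map one-to-one to MODEL records and coordinates survive a
write/read round trip to the format's three-decimal precision.

Every atom has exactly one role. The phosphate (P, OP1/OP2) and the sugar
(C1′–C5′, O4′, O3′, O5′, and the 2′-hydroxyl O2′/HO2′, treated as a sugar
substituent) are *backbone*; all ring and exocyclic base atoms and their
hydrogens are *base*. The O2′ assignment is configurable. Region labels
follow a configurable numbering profile whose default is the ASO–hairpin
scheme: residues 1–10 oligonucleotide, 11–26 hairpin strand 1, 27–42
hairpin strand 2. Regions come from configuration, never from PDB chain
identifiers alone.

## Contact analysis

Per frame, three contact types are detected between non-neighbouring
residues (covalent neighbours |i−j| ≤ 1 within one molecule are excluded):

- hydrogen bond: donor-heavy…acceptor distance ≤ 3.0 Å and, when the
  donor's hydrogens are present, donor–H…acceptor angle ≥ 135°; without
  hydrogens the criterion degrades to distance-only and outputs carry an
  `hbond_mode: distance_only` flag;
- salt bridge: anionic (phosphate oxygens) to cationic group atoms ≤ 4.0 Å.
  Unmodified RNA has no formal cation, so the default cation set is empty
  and this type is inert unless configured;
- apolar: carbon–carbon ≤ 4.0 Å. Base–base apolar contacts serve as the
  operational proxy for stacking; no dedicated stacking geometry test is
  performed.

An atom pair reports at most one type per frame with precedence
hbond > salt_bridge > apolar, so the unit-weight strengths (every contact
counts 1 regardless of type — the energetic cost of the types varies too
much for a common scale) are never double-counted. A contact is *specific*
iff both atoms are base-role. Residue-pair series record per-frame
presence and strength; occupancy is the fraction of window frames with at
least one contact; mean strength is averaged over the frames where the
pair is in contact, separately for the specific and nonspecific shares so
the two maps add exactly to the total. The occupancy filter keeps pairs
with occupancy strictly greater than the threshold (default 0.10).
Evolution tables split the window into near-equal consecutive frame
blocks.

## Nonbonded energies

The pair potential is k·q_iq_j/r + 4ε_ij[(σ_ij/r)¹² − (σ_ij/r)⁶] with
k = 332.0636 kcal·Å·mol⁻¹·e⁻², Lorentz–Berthelot combination (arithmetic
σ, geometric ε), truncated sharply at a configurable 10 Å cutoff — the
short-range force-field convention, with no switching function, PME
long-range term, or solvation model. Group energies are intermolecular
only; 1–2/1–3/1–4 exclusions are therefore irrelevant, and overlapping
groups are refused rather than mis-summed. The four-group decomposition
crosses ASO base/backbone with hairpin base/backbone; the total is defined
as the sum of the four means, and partition additivity against the
undecomposed cross energy holds to 1e−8 relative on arbitrary inputs. The
per-residue-pair matrix is the force-field nonbonded analogue of an
implicit-solvent residue interaction map and is labelled as such in its
output header. `combine_free_energy` implements the end-point bookkeeping
ΔG = ΔH − TΔS; the solvation and normal-mode entropy terms themselves are
outside scope.

## Descriptors

RMSD is reported after optimal least-squares (Kabsch) superposition of
each frame onto the reference (first frame by default) over the heavy-atom
selection; a no-fit mode gives the raw deviation. RMSF superposes window
frames onto their mean structure (two passes) and averages the per-atom
√⟨|r−⟨r⟩|²⟩ unweighted over each residue's heavy atoms. The radius of
gyration is mass-weighted with standard atomic masses. Moving averages are
centred with truncated endpoint windows. PCA superposes frames to the mean
and eigendecomposes the 3N heavy-atom covariance (via SVD); eigenvalues
descend, their sum equals the total positional variance, and variance
fractions are λ_k/Σλ. Mode animations interpolate ±2σ along a chosen PC as
a multi-model PDB.

Both RMSF and PCA expose `fit=False`. The synthetic generator adds
independent Gaussian noise with no rigid-body component, so the unfitted
mode recovers injected amplitudes exactly (a σ-residue among static ones
reads √3·σ, statics read numerical zero); with fitting, superposition
necessarily redistributes a little mobile-residue noise onto static
residues (~0.1 Å at typical amplitudes). On real trajectories, where
frames carry global rotation/translation, the fitted mode is the correct
default.

## Geometry

Torsions use the standard atan2 dihedral with the conventional sign
(verified against an independent implementation); α and ε/ζ span residue
boundaries and are computed only within a continuous chain. Circular means
are used wherever angles are averaged. Sugar pucker follows
Altona–Sundaralingam: tan P = ((ν4+ν1)−(ν3+ν0))/(2ν2(sin 36° + sin 72°)),
amplitude ν_max = ν2/cos P, with the 20-sector conformer wheel (18°
sectors; C3′-endo centred at 18°, C4′-exo at 54°, C2′-endo at 162°,
C2′-exo at 342°); flat rings get amplitude 0 and a `flat` sentinel.

Base reference frames are proper rotations least-squares fitted from
idealized base templates to observed base atoms. Template poses are
calibrated per nucleotide so that the two frames of an idealized
Watson-Crick pair coincide after the strand-II y/z flip — the defining
property of a standard base reference frame; the calibration constants
were derived once from the generator's ideal A–U and G–C pairs and are
fixed in code. Base-pair and step parameters use mid-frame algebra: the
origin displacement and the rotation vector carrying frame 1 onto frame 2,
both expressed in the average frame, give (shear, stretch, stagger,
buckle, propeller, opening) within a pair (strand II flipped first) and
(shift, slide, rise, tilt, roll, twist) between consecutive pair
mid-frames. Constructed pure transformations are recovered exactly, and
the strand-swap sign rules (shear/buckle antisymmetric, the rest
invariant) hold on arbitrary frames. This is a standard-reference-frame
analysis, not the curvilinear-axis algorithm of CURVES+; values agree in
convention but not bit-for-bit with that program.

## Pairing motifs

Base pairs are detected from base–base hydrogen bonds using a
heavy-atom, distance-only criterion of 3.7 Å with no angle term — the
convention of base-pair annotation tools (which must work without
hydrogens), chosen here also because an angle criterion on ~1 Å N–H bonds
is dominated by hydrogen scatter under thermal noise. Every
H-bond-capable base atom of A, C, G, U is assigned to exactly one edge
(WC / Hoogsteen / sugar); because chemistry reuses atoms across edges
(the adenine amine serves both WC and Hoogsteen faces), the pair-level
edge call is a weighted vote in which ring heteroatoms count double. A
pair is Watson-Crick when both edges vote WC (≥2 H-bonds), Hoogsteen when
either side presents the N7 face (≥1 H-bond), otherwise "other" (≥2).
Neutral G·C on the Hoogsteen face is geometrically constructible but not
detectable as Hoogsteen — the N7 contact has no donor without cytosine
protonation — which is chemically faithful. Triples are residues engaged
in two or more pairs; open and closed (partners also mutually paired)
triples are both reported with a flag, and cis/trans orientations are not
classified. Pair persistence gives per-pair presence fractions and block
series; a first-to-last block drop above 0.5 flags a fraying candidate.

## Synthetic ensembles

Nucleotides are built from idealized internal coordinates: the furanose
ring from a pentagon-with-out-of-plane-displacement model solved
numerically so the realized pseudorotation phase hits the requested
conformer's sector centre to well under a degree; the base (with
hydrogens) rigidly from chemical-component-dictionary ideal geometry,
oriented by the exact requested χ; the phosphate and hydroxyls from ideal
bond/angle values with A-form γ/β. Pairs and triples are posed by
deterministic multi-start rigid-body least squares driving the target
donor–acceptor distances to 2.85 Å with edge-facing, coplanarity and
clash terms; sterically impossible plans (< 1.5 Å between residues) raise
an error. Fluctuation specs add independent isotropic Gaussian noise per
atom with per-residue σ; contact schedules realize exact occupancies
(round-half-away frame counts, seeded frame choice) by rigidly separating
the partner residue in off frames. Equal spec + seed gives bit-identical
ensembles.

What this emulates: residue-resolved fluctuation amplitudes, on/off
contact geometries with known occupancies, pairing motifs with known
edges, and controllable sugar geometry — exactly the observables the
analysis stages measure. What it does not emulate: force-field-driven
correlated dynamics, solvent and ions, base-stacking energetics,
backbone continuity across posed pairs, or realistic transition kinetics.
Passing the recovery tests therefore demonstrates that the estimators are
correct and unbiased on known ground truth, not that any particular
biological conclusion follows from real data.

The built-in demo scene uses thermal-like amplitudes (σ ≤ 0.25 Å):
independent per-atom noise much larger than that occasionally collapses
contact atoms into the steep repulsive wall of the pair potential, which
is an artefact of the uncorrelated-noise model rather than of the energy
code. The synthetic parameter table carries AMBER-flavoured magnitudes
with element-level charges chosen so hydrogen-bonded pairs are net
attractive; it is a stand-in for a real force-field table, which can be
supplied as CSV (`residue, atom, charge_e, sigma_A, epsilon_kcal`).

## Pipeline and determinism

The `rnacontactdyn` CLI binds the stages into one workflow. Configuration
is validated up front with a complete error list (range checks, region
disjointness, window ordering); unknown config keys are rejected. Windows
are specified in ns and mapped to frames through the ensemble's time
stamps. Every output carries a provenance header (version, config hash,
seed, full config); identical config + seed reproduce all outputs byte
for byte. Problem sizes in the test-suite and acceptance runs (hundreds
of frames, 2–10 residues, 5000 frames for fluctuation recovery) were
chosen as the smallest ensembles at which the statistical recovery
targets (e.g. 3% on √3·σ) are comfortably inside their tolerances.

## Known limitations

- Modified nucleotides, protein residues and mmCIF input are out of scope.
- Contact criteria are conventions, not fits; absolute occupancies shift
  with the cutoffs (all configurable and recorded in outputs).
- The energy module omits long-range electrostatics and solvation; its
  totals are comparable between systems analysed identically, not
  absolute binding energies.
- Base-pair parameters use fixed idealized templates; heavily distorted
  bases are fitted in the least-squares sense without warning.
- Leontis–Westhof cis/trans classes and isostericity are not annotated.
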