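# rnacontactdyn

Trajectory analysis for nucleic-acid complexes, built around the question of
what holds an antisense oligonucleotide (ASO) on its target RNA hairpin.
Given a structural ensemble (multi-model PDB or frames in memory), the
package computes:

- **Dynamic contact maps** — per-frame hydrogen-bond / salt-bridge / apolar
  contacts aggregated to residue pairs with unit weight per contact,
  classified *specific* (base–base) vs *nonspecific* (at least one backbone
  atom), filtered at a strict >10% occupancy threshold, and resolved into
  time blocks to expose contact rearrangements.
- **Four-group interaction energies** — short-range Coulomb + Lennard-Jones
  energies (10 Å cutoff, Lorentz–Berthelot combination) decomposed into the
  ASO(base/backbone) × hairpin(base/backbone) cross terms, per-residue-pair
  energy matrices, and the ΔG = ΔH − TΔS bookkeeping of end-point
  free-energy tables.
- **Ensemble descriptors** — RMSD after optimal superposition, per-residue
  RMSF, mass-weighted radius of gyration, centred moving averages, and PCA
  of the heavy-atom coordinate covariance with variance fractions and
  mode-animation output.
- **Nucleic-acid geometry** — backbone torsions (α…ζ, χ),
  Altona–Sundaralingam sugar pucker (phase, amplitude, 20-sector conformer
  wheel), and base-pair / base-pair-step parameters (shear…opening,
  shift…twist) from standard-reference-frame mid-frame algebra.
- **Pairing motifs** — base pairs classified by nucleobase edge
  (Watson-Crick / Hoogsteen / sugar), base triples (one base H-bonded to two
  partners on distinct edges, e.g. U·A–U), and pair-persistence series that
  flag terminal fraying.

Because real microsecond trajectories are too large to ship, the package
includes a first-class **synthetic ensemble generator**: idealized
nucleotides with controllable sugar pucker and χ, posed Watson-Crick /
Hoogsteen pairs and triples, seeded Gaussian fluctuations of prescribed
per-residue amplitude, and contact schedules with exact target occupancies.
Every analysis stage is validated against this known ground truth.

## Worked example

Run the full pipeline on the built-in demo scene (two ASO–hairpin
Watson-Crick pairs, one Hoogsteen interaction closing a base triple, a
mobile ASO tail and one intermittent scheduled contact):

```bash
rnacontactdyn run --seed 1 --out demo
```

`demo/contacts.csv` (occupancy-filtered residue pairs):

```
residue_i,residue_j,occupancy,mean_strength,mean_specific,mean_nonspecific
1,11,0.975,1.80342,1.80342,0
2,12,0.583333,2.34286,2.34286,0
11,27,0.966667,1.97414,1.97414,0
```

The two stable pairs are the constructed WC (1–11) and Hoogsteen (11–27)
interactions; pair 2–12 is the scheduled intermittent contact, present in
~58% of frames — above the 10% cutoff, so it survives the filter.
`demo/triples.json` identifies the constructed triple: central residue 11
bound to residue 1 on its WC edge and residue 27 on its Hoogsteen edge.
`demo/energy_decomposition.csv` gives the four-group split (kcal/mol):

```
component,mean_kcal_mol,sd_kcal_mol
base_base,-23.249,25.2515
backbone_backbone,-0.746533,2.78106
base_backbone,30.8083,16.353
backbone_base,3.58654,12.8172
total,10.3994,26.9825
```

With the synthetic parameter set the specific (base–base) component is
attractive while backbone-involving terms are mildly repulsive; the total
is exactly the sum of the four components. `demo/rmsf.csv` shows residue 12
as the most mobile (it is rigidly displaced whenever its scheduled contact
is off), and `demo/pca.json` loads ~99.7% of the variance on PC1 — the
on/off contact switch is the dominant collective motion. Re-running the
command with the same seed reproduces every output byte for byte.

Each stage is also available separately (`rnacontactdyn simulate`,
`contacts`, `energies`, `descriptors`, `geometry`, `pairs`) with
`--input`/`--params`/`--window START:END`/`--threshold`/`--blocks` flags,
and the same functionality is importable from Python
(`rnacontactdyn.contacts.build_series`, `energy.four_group_decomposition`,
`descriptors.pca`, `geometry.geometry_profiles`,
`pairing.detect_triples`, …).

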