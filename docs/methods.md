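# Methods

`ubikin` implements two linked analyses of kinase ubiquitination: a
proteomics-side classification and enrichment analysis of ubiquitination
sites across the human kinome, and a structure-side analysis of molecular
dynamics (MD) ensembles of the ZAP-70 kinase domain with and without an
attached ubiquitin moiety. This note describes the models and procedures,
their tunable parameters, the synthetic-data generators used for testing,
and the numerical and design choices that were genuinely open.

## 1. Proteasome-sensitivity classification

A ubiquitination site is detected as a diGly remnant on a lysine and
quantified as a log2 fold-change (L2FC) with an adjusted p-value for each
experimental comparison. The classifier consumes MG-132 (proteasome
inhibitor) comparisons:

- **sensitive** — abundance at least two-fold greater with MG-132, i.e.
  L2FC ≥ 1.0 in the applicable comparison. The boundary L2FC = 1.0 counts as
  sensitive ("at least two-fold").
- **insensitive** — change below two-fold (L2FC < 1.0).
- **neither** — calls conflict across cell lines or conditions.
- **unknown** — no MG-132 quantification. Missing values are never imputed.

If the site's ubiquitination is itself significantly HIV-dependent (positive
L2FC with adjusted p below α in the HIV comparison; α = 0.05 by default,
the conventional threshold for MSstats-adjusted p-values), only the +HIV
MG-132 comparison is consulted, because the ubiquitination level without HIV
may be too low to quantify reliably.

'Neither' and 'unknown' sites enter the *all sites* denominator of the
composition summary but no sensitivity-specific row; this keeps the rows
disjoint.

## 2. Site composition summaries and enrichment

For each category (sensitive, insensitive, all) the summary reports the
fraction of sites on the kinase domain, on any folded domain, at a conserved
residue, at a conserved modification position, within four residues of a
phosphosite, and within four residues of a phosphorylation hot spot. "Near"
is within ±4 residues, boundary inclusive. Domain membership comes from
1-based inclusive range annotations; a site on a protein without annotations
counts as off-domain (with a warning).

Conservation derives from a user-supplied multiple sequence alignment of
kinase domains (FASTA or Clustal; the package does not run an aligner):

- a **conserved residue** is an alignment column where the same amino acid
  (lysine, for ubiquitination) occurs in strictly more than 40 entries — the
  threshold is configurable since kinome alignments vary in size;
- a **conserved modification** is a reference-mapped column where strictly
  more than 5 *distinct* kinases carry the modification (duplicate sites on
  one kinase count once).

Cross-kinase transfer uses the alignment's residue↔column maps: a site maps
to the reference residue (PKA or ZAP-70 numbering) occupying the same
column, and is omitted when the reference has a gap there. Mapping is
transitive-consistent by construction. Positional density profiles count
mapped sites per reference position, normalized over the kinase-domain range
so each category's profile sums to 1.

Enrichment against chance uses two tools:

- **Two-proportion test** — Pearson's chi-square test of equal proportions
  with Yates continuity correction, written to agree with R's `prop.test`
  for two groups to full precision: the correction term is capped at
  |p₁ − p₂| / (1/n₁ + 1/n₂), so identical observed proportions give a
  statistic of exactly 0 and p = 1.
- **Random-lysine null** — the expected fraction of randomly chosen lysines
  (across all supplied kinase sequences) that would be conserved, near a
  phosphosite, or near a hot spot, computed either by exact enumeration of
  the full lysine pool or by seeded Monte-Carlo sampling.

## 3. Trajectory metrics

Coordinates are read from multi-model PDB (the only supported trajectory
format; conversion from binary formats is the user's job), in Å, with
residue numbers taken directly from the PDB residue field — ZAP-70 numbering
(K369, D379, K476, …) is never re-indexed.

Named metrics monitored per snapshot:

- **C-helix position** — F349 Cα to D379 Cβ distance (preset
  `chelix_position`). Larger values mean the C-helix has swung away from the
  N-lobe, disrupting the active conformation.
- **Substrate-groove closure** — N348 Cα to W501 Cα distance (preset
  `groove`).
- **K369–E386 salt bridge** — minimum of NZ–OE1 and NZ–OE2 distances, with a
  "formed" flag at ≤ 4.0 Å.
- **C-helix order** — number of residues in 380–393 (14 residues) assigned a
  helical code.

### Kabsch–Sander secondary structure

Backbone hydrogen bonds are scored with the electrostatic model
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, bonded iff
E < −0.5 kcal/mol. Amide hydrogens are used when present in the topology and
otherwise placed 1.00 Å from N along the preceding C=O direction (the
classic convention); the N-terminal residue and prolines have no donor.
n-turns (n = 3, 4, 5) come from CO(i)→NH(i+n) bonds; two consecutive
4-turns give 'H' over the spanned residues, with the analogous rules for 'G'
and 'I'; bridge patterns give 'B' (isolated) or 'E' (ladders); isolated
turns give 'T'; everything else 'C'; priority H > E > B > G > I > T > C.
Chain breaks (C(i)–N(i+1) > 2.5 Å) split the turn bookkeeping; residues
missing backbone atoms are coded 'C' and logged. Bend ('S') is not
assigned; when reading external secondary-structure series, 'S' and the
no-assignment markers ('0', '.') normalize to 'C'.

The implementation is validated residue-for-residue against mdtraj's DSSP on
synthetic helix, strand and sheet fixtures (agreement is 100% on all three;
the acceptance threshold is ≥ 95% to allow segment-terminus differences).

"Helical conformation" counts code 'H' only by default; a configuration
option widens it to {H, G, I} since 3₁₀/π codes at helix termini are a
borderline case the metric definition leaves open. Both modes are exposed.

### Contact maps

A residue pair is in contact when their centers of mass are within 10 Å.
The map entry is the fraction of evaluated snapshots in contact, pooled over
all member simulations of an ensemble, with snapshots taken every 100 ps
(converted through each trajectory's timestep). Distance metrics and
histograms, in contrast, use every snapshot (1 ps).

### SASA

Solvent-accessible surface area uses the Shrake–Rupley algorithm: a
deterministic golden-spiral quadrature of 960 points per atom (doubling the
points changes the result by < 0.5%), probe radius 1.4 Å, Bondi van der
Waals radii. Shrake–Rupley was chosen over neighbor-overlap approximations
because it is exactly specifiable and its quadrature error is directly
controllable; absolute areas are therefore not comparable to LCPO-based
values, and only relative/ordering properties are asserted. By default every
atom of the frame occludes, so a kinase-domain selection is shadowed by an
attached moiety; the occluder set is configurable because tool conventions
differ on this point.

## 4. Ensemble statistics

Snapshots within one 10-ns simulation are temporally correlated, so
hypothesis tests never treat snapshots as independent. Instead the mean (or,
as a sensitivity analysis, the median) of each independent simulation is one
data point, and two constructs are compared with the two-sided Wilcoxon
rank-sum test. The p-value is exact when the combined sample size is ≤ 50
with no ties, and otherwise uses the normal approximation with tie and
continuity corrections — at the study design of 32 simulations per construct
the approximation branch applies. Degenerate input (all values identical)
returns p = 1 with a warning.

Distribution views pool all snapshots of all simulations of a construct with
equal weight; the histogram records counts, per-bin probabilities (summing
to 1), the pooled median, and an optional crystal-structure reference value.
Bin width defaults to Freedman–Diaconis on the pooled values and is
recorded in the output. Threshold summaries (e.g. the fraction of the
ensemble keeping ≥ 10 of 14 C-helix residues helical) use an inclusive
boundary.

## 5. Synthetic data: what it emulates and what it does not

Every generator is a pure function of its spec and seed; per-simulation
streams derive from (seed, group, simulation index), so outputs are bitwise
reproducible.

- **Site tables** — 200 kinases × 4 sites by default, with planted category
  probabilities defaulting to the observed kinome composition (47% on the
  kinase domain, 72% on a folded domain, 11% near a phosphosite) and a
  12.7% / 12.2% sensitive/insensitive split (the remainder unknown), the
  proportions observed in the merged site catalogue. MG-132 fold-changes
  are drawn so the classifier reproduces the planted call (L2FC uniform on
  [1, 3] for sensitive, [−1, 0.99) for insensitive, absent for unknown).
  Planted truth travels with each record, giving an exact bookkeeping oracle.
- **Ideal helix / strand** — poly-alanine backbones built by natural
  extension (NeRF) with bond lengths N–Cα 1.458, Cα–C 1.525, C–N 1.329,
  C=O 1.231 Å, standard bond angles, ω = 180°; φ = −57°, ψ = −47° yields the
  i→i+4 hydrogen bonds of an α-helix, φ = −120°, ψ = +120° an extended
  strand. The antiparallel sheet fixture applies the sheet dyad (180°
  rotation about the sheet normal) at 5.8 Å separation and 3.0 Å register,
  parameters chosen for clean ladder hydrogen bonds.
- **Two-domain ensemble** — two rigid six-residue pseudo-domains joined by a
  three-residue tether whose direction and extension are resampled per
  frame; one carbon pseudo-atom per residue so the exact contact fraction is
  computable by brute force.
- **Metric series** — stationary AR(1) noise (default ρ = 0.5, σ = 1 Å)
  around a 10 Å baseline, the minimal emulation of within-trajectory
  correlation; group B adds a location shift.

None of these emulate force-field physics, water, or realistic kinase
dynamics. Passing tests therefore demonstrate the *correctness of the
computations* (classification logic, alignment bookkeeping, DSSP energies,
contact counting, test calibration) — not that real MD ensembles would show
any particular biological effect.

## 6. Problem sizes and calibration

The test suite and acceptance script use deliberately small problems chosen
to exercise every code path: 12-residue fixtures for DSSP, 4 simulations ×
25 frames for contact-map exactness (which is exact at any size), 32 × 100
AR(1) frames per construct for the end-to-end comparison (matching the
32-simulation study design), 1000 replicates for the type-I calibration
(standard error ≈ 0.7 percentage points at α = 0.05), and 100 random 2×2
tables for the two-proportion cross-check against R.

## 7. Known limitations

- The DSSP implementation omits the bend ('S') state and β-bulge merging;
  on idealized fixtures this is invisible, on irregular real structures it
  would produce occasional C-for-S and B-for-E differences from reference
  implementations.
- The two-proportion test covers the two-group case only (the only one the
  analysis uses).
- PDB parsing supports standard fixed-column ATOM/HETATM/MODEL records;
  exotic records (insertion codes, altlocs) are not handled.
- The exact/approximate rank-sum switch is a fixed rule (combined n ≤ 50,
  no ties); R's `wilcox.test` uses per-group n < 50, so for group sizes
  between 26 and 49 per group the branch taken can differ from R's. At the
  32-vs-32 study design both give the same branch only when ties are
  present; p-values from the two branches differ negligibly at these sizes.
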