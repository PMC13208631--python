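# Methods

## Weighted electronegativity coefficient of variation (wMEE_CV)

For a mineral with nominal formula counts w₁ … w_k over elements with
Pauling electronegativities χ₁ … χ_k, let W = Σwᵢ. The statistic is

- weighted mean χ̄ = Σ wᵢχᵢ / W,
- weighted sample variance s² = Σ wᵢ(χᵢ − χ̄)² / (W − 1),
- wMEE_CV = s / χ̄.

The W − 1 divisor makes the weighted form identical to expanding the
formula into an explicit atom list and taking the ordinary sample SD;
the oregonite example (SD 0.166, not the population value 0.148) pins
this choice down. Consequences worth knowing:

- single-element formulas (native Fe, Ni) return exactly 0;
- the statistic is *not* invariant under multiplying all subscripts by a
  constant (FeO ≠ Fe₂O₂), because the effective atom count enters the
  divisor — this is intentional and tested;
- formulas with total atom count ≤ 1 return 0 rather than dividing by a
  non-positive degrees-of-freedom term.

### Formula grammar

Element symbols with optional subscripts (integers, decimals, or exact
fractions `a/b`), parenthesised groups with multipliers, comma groups for
shared-occupancy sites, hydration dots, and variable terms:

- `(Fe,Ni)9` splits the site multiplicity equally: Fe 9/2, Ni 9/2. Equal
  split is the only symmetric convention when occupancies are unstated.
- `(Fe,Ni)1+xS` evaluates at a nominal x (default 0, the end-member).
- `·nH2O` (also `*`, or `.` immediately before `nH2O`) adds water
  stoichiometry as constituent H and O atoms. A `.` anywhere else is a
  decimal point (`Fe0.5O`).
- Counts are exact `fractions.Fraction` values internally, so
  parse→render→parse round trips are exact even for thirds.

Unknown element symbols and unbalanced parentheses are parse errors
naming the offending token/position. Elements without an accepted
Pauling value are absent from the bundled table and raise a lookup error
rather than being imputed.

### Hard-acid/base range ratio (MHR)

Records for one metal are split on a boolean flag — does the formula
contain any element classed hard acid or hard base (bundled, editable
Pearson-style element-level table; oxygen is the canonical hard base).
MHR = (max − min wMEE_CV among flagged records) / (max − min among
unflagged records). The native metallic record supplies the 0 endpoint
of the unflagged stratum. A zero denominator range is an error (ratio
undefined); a zero numerator returns ratio 0.

## Bipartite mineral–element networks

Nodes are mineral species (weight = locality count, colour value =
wMEE_CV) and elements, optionally split by redox state with labels like
`Fe3+` / `Fe_unknown`. Edges are unweighted incidences, so a mineral's
degree equals its number of distinct element(-redox) labels. The age
filter keeps records with maximum known age strictly greater than the
threshold (2.5 or 3.5 Ga are the deep-time windows of interest).
Community detection is Louvain modularity maximisation over the whole
graph (node types are not distinguished), with explicit `seed` (default
1) and `resolution` (default 1) parameters; the reported modularity is
recomputed from the returned partition. Layout is Fruchterman–Reingold,
seeded, and carries no analytical meaning.

## Coordination-sphere extraction

A metal site is any hetero residue whose chemical-component code appears
in the bundled ligand registry (Fe, Ni and mixed NiFe centres). The
sphere at cutoff r (default 5 Å) contains every standard amino-acid
residue with ≥ 1 atom whose minimum distance to *any* ligand atom is
≤ r. Decisions embedded here:

- distance is the all-atom minimum (hydrogens included when present); a
  `metal_atoms_only` flag restricts the search to the ligand's Fe/Ni
  atoms for sensitivity analysis;
- waters and non-amino-acid hetero groups are never sphere members;
  covalently coordinating residues (Cys on an Fe–S cluster) are;
- modified residues map to canonical parents via an editable alias table
  (MSE→MET, SEC→CYS, …); unmappable residues are excluded;
- multi-model files: first model only; altlocs: highest-occupancy
  conformer;
- a site with an empty sphere is flagged (NaN statistics, zero vector)
  and excluded from aggregation, not an error.

Hydropathy uses the Kyte–Doolittle scale (bundled data file): per-sphere
mean and sample SD (SD 0 for singletons). Frequency vectors are
normalized counts over the 20 canonical amino acids in the fixed order
`ACDEFGHIKLMNPQRSTVWY`.

## Cohort statistics

Site profiles are averaged, unweighted, to one row per (structure, metal
class) so proteins with many metal centres are not over-represented.
Mixed NiFe centres count toward the Ni class by default (they are the
signature Ni-enzyme active sites); `class_rule` allows `fe` or `dual`.

PCA is mean-centred with no variance scaling — the inputs are fractions
on a common scale, so unit-variance scaling would inflate rare residues.
Component signs are fixed by making each component's largest-magnitude
loading positive. With all components retained the explained-variance
ratios sum to 1 and the centred data reconstruct exactly; identical rows
(zero variance) are rejected.

Welch's t-test (two-sided, Welch–Satterthwaite df) compares one
amino-acid fraction (cysteine by default) between Fe and Ni rows, either
globally or restricted to the shared enzyme families (ACS, CODH,
NiFe-hydrogenases). Both groups need ≥ 2 rows; zero variance in both
groups is returned as a flagged degenerate result. Exactly two planned
comparisons are reported; no multiple-testing correction is applied.

## Synthetic-data generator

`make_structure` writes minimal PDB files: idealised ligand geometries
(correct atom identities, bond-scale distances, no claim of physical
realism) and residues as backbone+anchor atom sets (N, CA, C, O, CB)
marching outward along a random ray, placed by bisection so the realised
minimum ligand distance equals the requested distance within 0.01 Å.
Placements are rejected and re-drawn on inter-residue clashes (< 1.5 Å)
or atomic overlap with the ligand (< 1.2 Å), with an error after 100
attempts. Output is byte-identical for identical specs.

`make_cohort` / `sample_cohort_vectors` emulate the statistical
structure of an Fe-vs-Ni contrast: per-structure compositions are drawn
from Dirichlet distributions around group profiles whose cysteine
fractions differ by the planted effect (defaults: 30 structures per
group, effect 0.15 on a Ni baseline of 0.10, concentration 50 — a
moderate within-group spread that keeps vectors strictly interior; 12
residues per written sphere plus one out-of-cutoff decoy). The
file-writing path realises the drawn composition as residue placements
2.2–4.8 Å from the ligand. What this does *not* emulate: real secondary
structure, correlated residue geometry, crystallographic noise, or the
family structure of real PDB cohorts — passing tests demonstrate the
statistical machinery and the extraction logic, not curation of real
structures.

`make_mineral_table` embeds oregonite and the native metals plus random
small-integer formulas; its truth column comes from an independent
brute-force atom-expansion oracle, not from the weighted closed form it
is used to test.

## Problem sizes and numerics

The test suite and the reproduction script run on synthetic inputs sized
for a laptop: 100 random structures for the extraction-oracle
equivalence, 200 cohort replicates for power and 1000 for type-I
calibration, networks of ≤ 12 nodes for the brute-force modularity
cross-check. Comparisons against printed three-decimal values use
|Δ| ≤ 5×10⁻⁴; exact-arithmetic claims (round trips, oracle agreement)
use 10⁻¹² or exact equality. CSV outputs use 6-significant-digit floats
so reruns are byte-stable.

## Limitations

- Full-cohort numbers from the literature (PC1 variance share 77.1%, the
  cysteine p-values, the 181-structure count, mineral-occurrence
  percentages) require the external Mineral Evolution Database export
  and the curated PDB set; they ship only as flagged annotations
  (`data/external_reference_values.json`) and are not recomputed.
- The HSAB table is an element-level simplification; redox-state-specific
  classes (Fe²⁺ vs Fe³⁺) collapse to one class per element. The table is
  a plain-text data file and can be edited without code changes.
- The formula grammar covers nominal IMA-style formulas; site-occupancy
  notation beyond equal-split comma groups, charge superscripts, and
  structural markup are out of scope.
- No coordination-geometry or bond-order analysis; the sphere is purely
  distance-based.
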