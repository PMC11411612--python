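# Methods

## Scope and model

`drugspace` implements a descriptor-based profiling pipeline for oral
small-molecule drug libraries. The scientific question it serves is
whether, and how, compounds violating classical drug-likeness limits
(Lipinski's rule of 5) differ from compliant ones — in size,
lipophilicity, hydrogen bonding, flexibility and 3D shape — and how
those properties move over approval periods.

The pipeline has four layers: dataset I/O and exclusions, per-molecule
2D descriptors and rule classification, conformer-ensemble 3D shape, and
group statistics. A synthetic-library generator with planted ground
truth closes the loop for testing.

## Dataset handling

Input is a CSV with one row per compound (id, name, SMILES, approval
year, indication, exclusion flag/reason). Rows whose SMILES fail to
parse are retained but flagged as excluded with reason
`descriptor-failure`, so the identity
`|parsed| = |analysis set| + |excluded|` always holds. Exclusions are
data-driven (a flag column), never hard-coded compound names. Salts and
solvates are reduced to the largest organic (carbon-containing, most
heavy atoms) fragment before any descriptor computation, and the choice
is recorded per record (`desalted`). The verbatim input SMILES is kept
alongside a canonical form; all downstream keys use the canonical form.

## 2D descriptor conventions

Conventions change reported summary tables, so they are pinned in a
`DescriptorConfig` that is attached to every output table:

* **HBD/HBA** default to the rule-of-5 convention: donors are the N/O
  atoms carrying at least one hydrogen; acceptors are all N and O atoms.
  This is the convention under which classic acceptor limits (HBA ≤ 10)
  were defined. The toolkit's pharmacophoric definitions are available
  via `hbond_convention="pharmacophore"`.
* **Rotatable bonds** default to the strict SMARTS definition (amide C–N
  excluded); the loose variant is a config switch.
* **clogP** is the Wildman–Crippen atomic-contribution estimate. Any
  other estimator shifts lipophilicity-dependent percentages by roughly
  a unit digit, which is why the estimator is recorded in metadata.
* **Fsp³** defaults to sp³ carbons / carbons (the standard saturation
  definition). Because "sp³ atoms" is sometimes counted over all heavy
  atoms, that variant is provided behind `fsp3_denominator="heavy"`; the
  carbon-based default is the one used in all shipped summaries.
* **Stereocentres** count atoms where chirality is possible, assigned or
  not.

Molecular weight is the sum of isotope-averaged atomic masses including
implicit hydrogens.

## Classification

* **Lipinski assessment**: strict inequalities MWt > 500, clogP > 5,
  HBD > 5, HBA > 10; a compound *fails* iff it violates two or more.
  Violation counts are monotone in each descriptor.
* **Derived rules**: per-descriptor order statistics of the analysis set
  at a configurable percentile (default 90th), using the same quantile
  rule as the summary tables. Reported at MWt integer / clogP one
  decimal precision.
* **Macrocycles**: largest perceived ring ≥ 12 atoms, evaluated directly
  on ring-perception output rather than an extended-SMARTS ring-size
  dialect, for portability. Fused small rings (naphthalene's 10-atom
  perimeter) do not count; tests cross-check against a
  minimum-cycle-basis graph oracle.
* **Ionisation classes**: counts of acid and base substructure matches,
  deduplicated by matched-atom overlap (the two O–H arms of one
  phosphonic acid count once; guanidine claims its atoms before the
  amidine pattern can re-match them). Net charge = bases − acids maps to
  neutral / mono-acid / mono-base / zwitterion-or-other /
  multi-charged. The default SMARTS sets (carboxylic, sulfonic/sulfinic,
  phosphonic acids, acyl-sulfonamide, tetrazole; aliphatic 1°/2°/3°
  amines excluding amides and anilines, amidine, guanidine) are shipped
  as editable data: class populations are convention-dependent, and any
  comparison across datasets should state the pattern set used. No pKa
  prediction is attempted; this is a structure-count heuristic.

## Conformers and 3D shape

Ensembles are embedded with ETKDGv3 using random initial coordinates,
small-ring torsion terms, a 0.1 Å RMS pruning threshold (heavy-atom),
up to 1000 embedding attempts and a fixed seed; identical
(molecule, seed) inputs give bit-identical coordinates. Ensemble size
follows the rotatable-bond rule: 50 conformers for ≤ 7 rotatable bonds,
200 for 8–12, 300 above 12. Each conformer is relaxed with MMFF94
(default 200 iterations, configurable) and its final energy recorded in
kcal/mol. Per-batch reproducibility uses one global seed plus a stable
per-molecule offset (CRC32 of the canonical SMILES), so adding compounds
to a batch does not reshuffle the ensembles of the others.

Principal moments of inertia are the eigenvalues of the mass-weighted
inertia tensor about the centre of mass (isotope-averaged masses,
hydrogens explicit), sorted I₁ ≤ I₂ ≤ I₃; a unit-mass variant exists
behind a flag for comparison with geometry-only conventions. The
normalised ratios NPR1 = I₁/I₃ and NPR2 = I₂/I₃ satisfy
0 ≤ NPR1 ≤ NPR2 ≤ 1 and NPR1 + NPR2 ≥ 1 (rigid-body triangle with rod,
disc and sphere corners).

Ensemble properties are Boltzmann-averaged at T = 300 K with
wᵢ ∝ exp(−Eᵢ/k_BT). The Boltzmann constant is expressed in
kcal mol⁻¹ K⁻¹ (0.0019872041) to match MMFF94 energies — a units
mismatch here is the classic silent bug, so the constant lives next to
the averaging code and the tests pin its closed-form consequences
(ΔE = k_B·300·ln 2 gives exact 2:1 weights). Energies are shifted by
their minimum before exponentiation for numerical stability. NPRs are
averaged per conformer (average of ratios, not ratio of averaged
moments), and both the Boltzmann average and the lowest-energy
conformer's NPRs are reported, since either may be wanted for shape
maps.

## Statistics

Summaries report mean, sample SD (n−1) and 50/75/90th percentiles. The
quantile rule defaults to the (n+1)-based empirical quantile (numpy's
`weibull` method), the default of common statistics desktops; the
`linear` interpolation variant is a config option. Correlations are
squared Pearson r, with zero-variance input an explicit error.

All-pairs group comparisons use the Tukey–Kramer HSD:
q = |mᵢ − mⱼ| / √((s²/2)(1/nᵢ + 1/nⱼ)) with pooled within-group variance
s² on N − k degrees of freedom, referred to the studentized-range
distribution. The Kramer standard error keeps the test valid for
unequal group sizes; adjusted p-values come from the studentized-range
survival function (scipy), with the critical value cached because the
ppf is expensive. Degenerate zero-variance groups yield q = ∞ (different
means) or q = 0 (equal) rather than a crash. Tests validate the
implementation three ways: against an independent implementation
(statsmodels), against a permutation null of the maximum studentized
range on frozen small samples, and by simulating the family-wise type-I
error on a 3-group null (1000 replicates), which must sit within
Monte-Carlo error of the nominal 5%.

Temporal trends bin records into approval periods (default 2000–2009,
2010–2019, 2020–2022), reporting approvals, Lipinski-fail counts and
rates, and per-descriptor means per bin; counts are conserved under
re-binning and years outside all bins are an error listing offenders.

## Synthetic library generator

The generator assembles molecules from a curated fragment grammar —
ring cores, linkers and capping groups joined at labelled attachment
points — which guarantees syntactic and valence validity; random SMILES
strings are never used. Planted properties are enforced by
construction *and* verified with the package's own classifiers
(resampling on mismatch), so the emitted ground-truth labels are exact:

* approval years uniform over the window, with per-period Lipinski
  fail-rate targets realised as Bernoulli draws;
* macrocycles built as explicit ≥ 12-membered rings mixing methylenes,
  ethers and ring amides (the donor/acceptor pattern typical of
  macrocyclic natural products); lipophilic fail-class macrocycles use
  larger, carbon-rich rings;
* ionisation classes planted via acid/base capping groups, with
  ionisable fragments excluded from the neutral pools;
* molecular weight steered per record so the running library mean tracks
  the target mean (fails are drawn around a higher mass with lipophilic
  fragment pools, passes around a compensating lower mass).

Defaults emulate a post-exclusion oral-approval study set: n = 371, MWt
mean 432 Da (SD 159), macrocycle fraction 10/371, period fail rates
12%/20%/18%, and an ionisation mix of 60% neutral / 15% mono-acid /
15% mono-base / 10% zwitterion-or-other — the class mix is our own
choice of a realistic oral-drug profile, since class populations depend
on the SMARTS convention. MWt is the hard-steered moment (realised mean
within ±10% of target, typically much closer); clogP, HBD/HBA and
rotatable-bond targets are soft — the pools are built so their realised
means land in a realistic range, but they are not feedback-controlled.
Infeasible targets (e.g. mean MWt 100 with 10 acceptors) raise before
generation.

What the generator does *not* emulate: real substructural diversity and
medicinal-chemistry idiom (it reuses a modest fragment vocabulary),
correlated descriptor structure beyond what the grammar induces,
stereochemistry, tautomer subtleties, or the actual identity of any
approved drug. Passing tests therefore demonstrate that the pipeline
recovers planted distributional truth and satisfies its mathematical
invariants — not that any specific literature value would be reproduced
on a real dataset, which requires supplying that dataset.

## Problem sizes and numerical choices

The shipped test suite and the acceptance script run the 2D pipeline at
n = 371 (seconds) and exercise the 3D layer on a 20-compound library of
modest size (mean MWt ≈ 330), our chosen demonstration scale for
ensemble work on a single CPU; a full-library 3D run at ensemble sizes
of 50–300 conformers per molecule is a batch job, not a desk
computation, and is intentionally out of scope for the automated
checks. Other defaults: MMFF94 optimisation capped at 200 iterations;
pruning RMS heavy-atom (all-atom configurable); Boltzmann averaging at
300 K; HSD α = 0.05.

## Known limitations

* clogP-dependent quantities inherit the Wildman–Crippen estimator's
  biases and can shift at the unit digit across toolkit versions.
* Ionisation classes are substructure counts, not pKa-based charge
  states at pH 7.4; zwitterion/other is a catch-all.
* Macrocycle detection follows perceived (SSSR-style) rings; exotic
  fused/bridged topologies where the smallest-ring basis is ambiguous
  may be classified differently by other toolkits.
* Conformer ensembles sample the MMFF94 gas-phase landscape; no solvent
  model or free-energy correction is applied, so shape conclusions are
  protocol-dependent.
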