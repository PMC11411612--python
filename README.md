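# drugspace

Physicochemical property profiling of oral drug libraries: rule-of-5
descriptors, conformer-ensemble 3D shape, and the comparison statistics
used to ask whether compounds outside classical "drug-like" property
space are becoming more common.

`drugspace` is aimed at medicinal/computational chemists who analyse
approved-drug or project compound sets. Given a compound table (id, name,
SMILES, approval year, indication, exclusion flag), it computes:

* **2D descriptors** — molecular weight (MWt), Wildman–Crippen clogP,
  hydrogen-bond donors/acceptors in the rule-of-5 convention
  (donors = N/O atoms bearing H, acceptors = all N + O), rotatable bonds
  (strict SMARTS), aromatic ring count, Fsp³ (sp³ carbons / carbons),
  stereocentres, ring and atom counts.
* **Classification** — Lipinski's rule of 5 (fail ⇔ two or more of
  MWt > 500, clogP > 5, HBD > 5, HBA > 10; strict inequalities),
  dataset-derived percentile rules (per-descriptor order statistics at a
  chosen percentile, 90th by default), macrocycle detection (any
  perceived ring of ≥ 12 atoms) and ionisation classes from acid/base
  substructure counts (net charge = bases − acids).
* **3D shape** — ETKDG conformer ensembles (0.1 Å RMS pruning, seeded,
  ensemble size 50/200/300 by rotatable-bond count), MMFF94 optimisation
  and energies, principal moments of inertia I₁ ≤ I₂ ≤ I₃ from the
  mass-weighted inertia tensor, and normalised ratios
  NPR1 = I₁/I₃, NPR2 = I₂/I₃ Boltzmann-averaged at 300 K with weights
  wᵢ ∝ exp(−Eᵢ/k_BT).
* **Statistics** — mean/SD/percentile summary tables ((n+1)-based
  quantiles by default), pairwise r² correlations, Tukey–Kramer HSD
  all-pairs comparisons with the Kramer unequal-n standard error, and
  approval-period trend tables.
* **Synthetic libraries** — a fragment-grammar generator that builds
  valid, unique molecules with *planted* ground truth (macrocycle
  fraction, ionisation classes, per-period Lipinski fail rates, target
  MWt distribution), so the whole pipeline is testable without any
  proprietary dataset.

## Worked example

```python
from drugspace import GeneratorSpec, generate_library, derive_percentile_rules
from drugspace.pipeline import profile_records
from drugspace.stats import summary_table

records = generate_library(GeneratorSpec(n=150, seed=8))
profile = profile_records(records)
print(summary_table(profile, ("mwt", "clogp", "hbd", "hba")).round(2))
print(derive_percentile_rules(profile).rounded())
```

prints

```
         mean     std      n     p50     p75     p90
mwt    430.92  141.34  150.0  435.59  484.38  614.86
clogp    4.77    2.82  150.0    4.25    6.15    8.28
hbd      1.41    0.96  150.0    1.00    2.00    3.00
hba      5.79    2.54  150.0    6.00    8.00    9.00
{'mwt': 615, 'clogp': 8.3, 'hbd': 3, 'hba': 9}
```

i.e. this 150-compound library averages 431 Da and clogP 4.8, and the
rule-of-5-style limits *derived from it* (the 90th percentile of each
descriptor — the construction behind the original cutoffs) are
MWt < 615, clogP < 8.3, HBD < 3, HBA < 9. The `examples/` directory has
one short script per capability (profiling, pass/fail comparison and
trends, conformer shape, macrocycles/ionisation); each prints the
numbers it computes with a line on what they mean.

A thin CLI mirrors the pipeline stages:

```bash
drugspace synth --n 371 --seed 7 --out lib.csv
drugspace load lib.csv --out analysis.csv
drugspace descriptors analysis.csv --out profile.csv
drugspace report profile.csv --out report/
```

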