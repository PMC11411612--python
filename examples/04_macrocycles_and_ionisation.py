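"""Macrocycle detection and ionisation-class assignment.

Classifies a handful of molecules by largest perceived ring size
(macrocycle = ring of >= 12 atoms) and by net ionisation class from
acid/base substructure counts, then shows the class mix of a synthetic
library.
"""

from rdkit import RDLogger

from drugspace import (
    GeneratorSpec,
    generate_library,
    ionisation_class,
    is_macrocycle,
)
from drugspace.pipeline import profile_records

RDLogger.DisableLog("rdApp.*")

examples = {
    "cyclododecane": "C1CCCCCCCCCCC1",
    "naphthalene": "c1ccc2ccccc2c1",
    "12-membered lactone": "O=C1CCCCCCCCCCO1",
    "glycine": "NCC(=O)O",
    "ibuprofen-like acid": "CC(C)Cc1ccc(C(C)C(=O)O)cc1",
    "tertiary amine": "CCN(CC)CC",
}
for name, smiles in examples.items():
    ion = ionisation_class(smiles)
    print(f"{name:22s} macrocycle={is_macrocycle(smiles)!s:5s} "
          f"acids={ion.acid_groups} bases={ion.base_groups} "
          f"class={ion.net_class.value}")
# naphthalene's 10-atom perimeter is fused 6-rings, so it is NOT a macrocycle

profile = profile_records(generate_library(GeneratorSpec(n=150, seed=6)))
print("\nionisation-class mix of a 150-compound synthetic library:")
print(profile.ionisation_class.value_counts(normalize=True).round(2).to_string())
print(f"macrocycles: {int(profile.macrocycle.sum())}")
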