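"""End-to-end 2D profiling: descriptors plus classification columns."""

from __future__ import annotations

import pandas as pd
from rdkit import Chem

from .classify import ionisation_class, is_macrocycle, lipinski_assess
from .descriptors import DEFAULT_CONFIG, DescriptorConfig, descriptor_table


def profile_records(
    records, config: DescriptorConfig = DEFAULT_CONFIG
) -> pd.DataFrame:
    """One row per compound: 2D descriptors, Lipinski verdict, macrocycle
    flag and ionisation class.

    Records whose descriptors fail are kept with ``descriptor_failure``
    set and NaN descriptor values, mirroring how unscorable compounds are
    reported rather than dropped.
    """
    df = descriptor_table(records, config)
    violations, fails, macro, net_class = [], [], [], []
    for _, row in df.iterrows():
        if row["descriptor_failure"]:
            violations.append(pd.NA)
            fails.append(pd.NA)
            macro.append(pd.NA)
            net_class.append(pd.NA)
            continue
        assessment = lipinski_assess(
            mwt=row["mwt"], clogp=row["clogp"], hbd=row["hbd"], hba=row["hba"]
        )
        violations.append(assessment.violation_count)
        fails.append(assessment.fails)
        mol = Chem.MolFromSmiles(row["smiles"])
        macro.append(is_macrocycle(mol))
        net_class.append(ionisation_class(mol).net_class.value)
    df["lipinski_violations"] = violations
    df["lipinski_fail"] = fails
    df["macrocycle"] = macro
    df["ionisation_class"] = net_class
    return df
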