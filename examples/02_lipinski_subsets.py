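"""Compare Lipinski passes against fails and track fail rates over time.

Profiles a synthetic library, splits it by the two-or-more-violations
verdict, runs a Tukey-Kramer comparison of molecular weight between the
subsets, and bins fail counts by approval period.
"""

from rdkit import RDLogger

from drugspace import GeneratorSpec, generate_library, subset_compare, temporal_trend
from drugspace.pipeline import profile_records

RDLogger.DisableLog("rdApp.*")

profile = profile_records(generate_library(GeneratorSpec(n=200, seed=4)))

labels = profile.lipinski_fail.map({True: "fail", False: "pass"}).to_numpy()
summaries, comparison = subset_compare(profile, labels, "mwt")
print("MWt by Lipinski verdict:")
print(summaries[["mean", "std", "n"]].round(1))
row = comparison.comparisons.iloc[0]
print(
    f"\nTukey-Kramer: q = {row.q:.2f}, adjusted p = {row.p_adj:.2e}, "
    f"significant at alpha=0.05: {row.significant}"
)
# fails are by construction heavier, so the difference should be large

print("\nLipinski fails per approval period:")
print(temporal_trend(profile).round(1).to_string(index=False))
# n = approvals per period; fail_pct = share violating >=2 rules
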