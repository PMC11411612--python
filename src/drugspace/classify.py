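"""Rule-based classification: Lipinski assessment, percentile-derived
rules, macrocycle detection and ionisation-class assignment.

Lipinski's rule of 5 flags poor oral absorption as more likely when two or
more of {MWt > 500 Da, clogP > 5, HBD > 5, HBA > 10} hold; all four
comparisons are strict.  The same thresholds can instead be *derived* from
a dataset as the 90th percentile of each descriptor, which is how the
original limits were obtained.

A macrocycle is a molecule whose perceived ring system contains a ring of
12 or more atoms.  Ionisation classes are assigned from counts of acidic
and basic substructure matches: the net charge estimate is
(bases - acids), so a single carboxylic acid gives net -1 (monoacid) and a
single aliphatic amine net +1 (monobase).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from rdkit import Chem


@dataclass(frozen=True)
class LipinskiAssessment:
    over_mwt: bool
    over_clogp: bool
    over_hbd: bool
    over_hba: bool

    @property
    def violation_count(self) -> int:
        return int(self.over_mwt) + int(self.over_clogp) + int(self.over_hbd) + int(
            self.over_hba
        )

    @property
    def fails(self) -> bool:
        return self.violation_count >= 2


def lipinski_assess(
    descriptors=None,
    *,
    mwt: float | None = None,
    clogp: float | None = None,
    hbd: int | None = None,
    hba: int | None = None,
) -> LipinskiAssessment:
    """Assess the four rules (strict inequalities: >500, >5, >5, >10).

    Accepts either a :class:`~drugspace.descriptors.Descriptors2D` (or any
    object with mwt/clogp/hbd/hba attributes) or the four values as
    keywords.
    """
    if descriptors is not None:
        mwt, clogp = descriptors.mwt, descriptors.clogp
        hbd, hba = descriptors.hbd, descriptors.hba
    if None in (mwt, clogp, hbd, hba):
        raise ValueError("mwt, clogp, hbd and hba are all required")
    return LipinskiAssessment(
        over_mwt=mwt > 500,
        over_clogp=clogp > 5,
        over_hbd=hbd > 5,
        over_hba=hba > 10,
    )


def is_macrocycle(molecule: Chem.Mol | str, min_ring_size: int = 12) -> bool:
    """True iff the perceived ring set contains a ring of >= 12 atoms.

    Works on the smallest-set-of-smallest-rings perception, so fused small
    rings (e.g. naphthalene's 10-atom perimeter) do not count.
    """
    if isinstance(molecule, str):
        molecule = Chem.MolFromSmiles(molecule)
        if molecule is None:
            raise ValueError("unparseable SMILES")
    ri = molecule.GetRingInfo()
    return any(len(ring) >= min_ring_size for ring in ri.AtomRings())


class NetClass(enum.Enum):
    NEUTRAL = "neutral"
    MONOACID = "monoacid"
    MONOBASE = "monobase"
    ZWITTERION = "zwitterion/other"
    MULTI_ACID = "multi-acid"
    MULTI_BASE = "multi-base"


# Ionisable-group SMARTS, shipped as editable data.  Order matters: earlier
# patterns claim their atoms first, so guanidine must precede amidine and a
# basic amine pattern never re-counts atoms already matched as part of a
# larger group.
DEFAULT_ACID_SMARTS: dict[str, str] = {
    "carboxylic_acid": "[CX3](=O)[OX2H1]",
    "sulfonic_acid": "[SX4](=O)(=O)[OX2H1]",
    "sulfinic_acid": "[SX3](=O)[OX2H1]",
    "phosphonic_acid": "[PX4](=O)[OX2H1]",
    "acyl_sulfonamide": "[CX3](=O)[NX3H1][SX4](=O)=O",
    "tetrazole": "c1nnn[nH]1",
    "tetrazole_tautomer": "c1nn[nH]n1",
}

DEFAULT_BASE_SMARTS: dict[str, str] = {
    "guanidine": "[NX3][CX3](=[NX2])[NX3]",
    "amidine": "[NX3][CX3]=[NX2]",
    "primary_amine": "[NX3;H2;$(N[CX4]);!$(NC=O);!$(NS(=O)=O)]",
    "secondary_amine": "[NX3;H1;$(N([CX4])[CX4]);!$(NC=O);!$(NS(=O)=O)]",
    "tertiary_amine": "[NX3;H0;$(N([CX4])([CX4])[CX4]);!$(NC=O);!$(N=O)]",
}


@dataclass(frozen=True)
class IonisationClass:
    acid_groups: int
    base_groups: int
    net_class: NetClass

    @property
    def net_charge(self) -> int:
        return self.base_groups - self.acid_groups


def _count_matches(mol: Chem.Mol, patterns: dict[str, str], claimed: set) -> int:
    """Count non-overlapping substructure matches, claiming their atoms."""
    n = 0
    for smarts in patterns.values():
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:  # pragma: no cover - guards bad user-supplied SMARTS
            raise ValueError(f"invalid SMARTS: {smarts!r}")
        for match in mol.GetSubstructMatches(patt):
            atoms = set(match)
            if atoms & claimed:
                continue
            claimed |= atoms
            n += 1
    return n


def ionisation_class(
    molecule: Chem.Mol | str,
    acid_patterns: dict[str, str] | None = None,
    base_patterns: dict[str, str] | None = None,
) -> IonisationClass:
    """Assign an ionisation class from acid/base substructure counts.

    Overlapping matches are deduplicated by matched-atom set, so e.g. the
    two O-H matches of one phosphonic acid count once.  Every molecule
    receives exactly one class, so classes partition any input set.
    """
    if isinstance(molecule, str):
        molecule = Chem.MolFromSmiles(molecule)
        if molecule is None:
            raise ValueError("unparseable SMILES")
    claimed: set = set()
    acids = _count_matches(molecule, acid_patterns or DEFAULT_ACID_SMARTS, claimed)
    bases = _count_matches(molecule, base_patterns or DEFAULT_BASE_SMARTS, claimed)
    net = bases - acids
    if net == 0:
        cls = NetClass.NEUTRAL if acids == 0 else NetClass.ZWITTERION
    elif net == -1:
        cls = NetClass.MONOACID
    elif net == 1:
        cls = NetClass.MONOBASE
    elif net <= -2:
        cls = NetClass.MULTI_ACID
    else:
        cls = NetClass.MULTI_BASE
    return IonisationClass(acid_groups=acids, base_groups=bases, net_class=cls)


@dataclass(frozen=True)
class DerivedRules:
    """Dataset-derived descriptor limits at a chosen percentile."""

    mwt: float
    clogp: float
    hbd: float
    hba: float
    percentile: float = 90.0

    def rounded(self) -> dict:
        """Thresholds at reporting precision (MWt integer, clogP 1 d.p.)."""
        return {
            "mwt": round(self.mwt),
            "clogp": round(self.clogp, 1),
            "hbd": round(self.hbd),
            "hba": round(self.hba),
        }


def derive_percentile_rules(
    descriptors, percentile: float = 90.0, method: str = "weibull"
) -> DerivedRules:
    """Derive rule-of-5-style limits as per-descriptor order statistics.

    ``descriptors`` is a DataFrame with mwt/clogp/hbd/hba columns or an
    iterable of objects exposing those attributes.  The default quantile
    rule is the (n+1)-based empirical quantile (numpy's ``weibull``
    method); ``method="linear"`` selects the common interpolation variant.
    """
    if hasattr(descriptors, "columns"):
        cols = {k: np.asarray(descriptors[k], dtype=float) for k in
                ("mwt", "clogp", "hbd", "hba")}
    else:
        items = list(descriptors)
        cols = {
            k: np.array([getattr(d, k) for d in items], dtype=float)
            for k in ("mwt", "clogp", "hbd", "hba")
        }
    n = len(next(iter(cols.values())))
    if n < 2:
        raise ValueError("need at least 2 compounds to derive percentile rules")
    thresholds = {
        k: float(np.percentile(v, percentile, method=method)) for k, v in cols.items()
    }
    return DerivedRules(percentile=percentile, **thresholds)
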