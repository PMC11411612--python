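"""2D physicochemical descriptors.

Computes the four rule-of-5 descriptors (MWt, clogP, HBD, HBA) plus the
flexibility/saturation descriptors commonly profiled alongside them:
rotatable bonds, aromatic ring count, Fsp3, stereocentres, ring count and
non-carbon / aromatic atom counts.

Conventions matter here and are therefore explicit and configurable:

* Hydrogen bonding defaults to the rule-of-5 convention — donors are the
  N/O atoms bearing at least one hydrogen, acceptors are *all* N and O
  atoms.  The pharmacophoric definitions used by RDKit's CalcNumHBD/HBA
  are available behind ``hbond_convention="pharmacophore"``.
* Rotatable bonds default to the strict SMARTS definition (amide C–N
  bonds excluded); ``rotatable_bonds="loose"`` switches to the permissive
  pattern.
* Fsp3 defaults to the Lovering definition (sp3 carbons / carbons); the
  all-heavy-atom variant is available behind ``fsp3_denominator="heavy"``.
* clogP is the Wildman–Crippen atomic-contribution estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors


class DescriptorError(ValueError):
    """Raised when a molecule cannot produce a descriptor vector."""


@dataclass(frozen=True)
class DescriptorConfig:
    """Pins the descriptor conventions; recorded in output metadata."""

    hbond_convention: str = "lipinski"  # or "pharmacophore"
    rotatable_bonds: str = "strict"  # or "loose"
    fsp3_denominator: str = "carbon"  # or "heavy"

    def __post_init__(self):
        if self.hbond_convention not in ("lipinski", "pharmacophore"):
            raise ValueError(f"unknown hbond convention {self.hbond_convention!r}")
        if self.rotatable_bonds not in ("strict", "loose"):
            raise ValueError(f"unknown rotatable-bond variant {self.rotatable_bonds!r}")
        if self.fsp3_denominator not in ("carbon", "heavy"):
            raise ValueError(f"unknown fsp3 denominator {self.fsp3_denominator!r}")


DEFAULT_CONFIG = DescriptorConfig()


@dataclass
class Descriptors2D:
    mwt: float
    clogp: float
    hbd: int
    hba: int
    rotatable_bonds: int
    aromatic_rings: int
    fsp3: float
    stereocentres: int
    ring_count: int
    non_carbon_atoms: int
    aromatic_atoms: int
    config: DescriptorConfig = field(default=DEFAULT_CONFIG, repr=False)

    def as_dict(self) -> dict:
        d = asdict(self)
        d.pop("config")
        return d


def _as_mol(molecule: Chem.Mol | str) -> Chem.Mol:
    if isinstance(molecule, str):
        mol = Chem.MolFromSmiles(molecule)
        if mol is None:
            raise DescriptorError(f"unparseable SMILES: {molecule!r}")
        return mol
    if molecule is None or molecule.GetNumAtoms() == 0:
        raise DescriptorError("empty molecule")
    return molecule


def lipinski_hbd(mol: Chem.Mol) -> int:
    """Rule-of-5 donors: N or O atoms carrying at least one hydrogen."""
    return sum(
        1
        for a in mol.GetAtoms()
        if a.GetSymbol() in ("N", "O") and a.GetTotalNumHs() > 0
    )


def lipinski_hba(mol: Chem.Mol) -> int:
    """Rule-of-5 acceptors: every nitrogen and oxygen atom."""
    return sum(1 for a in mol.GetAtoms() if a.GetSymbol() in ("N", "O"))


def fsp3(molecule: Chem.Mol | str, denominator: str = "carbon") -> float:
    """Fraction of sp3 atoms.

    ``denominator="carbon"`` gives sp3 carbons / carbons (the standard
    saturation measure); ``"heavy"`` counts sp3 hybridised heavy atoms of
    any element over all heavy atoms.
    """
    mol = _as_mol(molecule)
    sp3 = Chem.HybridizationType.SP3
    if denominator == "carbon":
        carbons = [a for a in mol.GetAtoms() if a.GetSymbol() == "C"]
        if not carbons:
            raise DescriptorError("Fsp3 undefined: molecule has no carbon atoms")
        return sum(1 for a in carbons if a.GetHybridization() == sp3) / len(carbons)
    if denominator == "heavy":
        heavy = [a for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
        if not heavy:
            raise DescriptorError("Fsp3 undefined: molecule has no heavy atoms")
        return sum(1 for a in heavy if a.GetHybridization() == sp3) / len(heavy)
    raise ValueError(f"unknown denominator {denominator!r}")


def compute_descriptors(
    molecule: Chem.Mol | str, config: DescriptorConfig = DEFAULT_CONFIG
) -> Descriptors2D:
    """Full 2D descriptor vector for one molecule.

    Deterministic for a fixed molecule and configuration; raises
    :class:`DescriptorError` for empty or unparseable input.
    """
    mol = _as_mol(molecule)

    if config.hbond_convention == "lipinski":
        hbd, hba = lipinski_hbd(mol), lipinski_hba(mol)
    else:
        hbd = rdMolDescriptors.CalcNumHBD(mol)
        hba = rdMolDescriptors.CalcNumHBA(mol)

    strict = (
        rdMolDescriptors.NumRotatableBondsOptions.Strict
        if config.rotatable_bonds == "strict"
        else rdMolDescriptors.NumRotatableBondsOptions.NonStrict
    )
    rb = rdMolDescriptors.CalcNumRotatableBonds(mol, strict)

    stereo = len(
        Chem.FindMolChiralCenters(
            mol, includeUnassigned=True, useLegacyImplementation=False
        )
    )

    return Descriptors2D(
        mwt=Descriptors.MolWt(mol),
        clogp=Crippen.MolLogP(mol),
        hbd=hbd,
        hba=hba,
        rotatable_bonds=rb,
        aromatic_rings=rdMolDescriptors.CalcNumAromaticRings(mol),
        fsp3=fsp3(mol, config.fsp3_denominator),
        stereocentres=stereo,
        ring_count=rdMolDescriptors.CalcNumRings(mol),
        non_carbon_atoms=sum(
            1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1 and a.GetSymbol() != "C"
        ),
        aromatic_atoms=sum(1 for a in mol.GetAtoms() if a.GetIsAromatic()),
        config=config,
    )


def descriptor_table(
    records, config: DescriptorConfig = DEFAULT_CONFIG
) -> pd.DataFrame:
    """Descriptor vectors for a record collection, one row per compound.

    Accepts an :class:`~drugspace.dataset.AnalysisSet` or any iterable of
    :class:`~drugspace.dataset.DrugRecord`.  Records whose structure fails
    descriptor computation are reported in the ``descriptor_failure``
    column rather than silently dropped.
    """
    rows = []
    for rec in records:
        row = {
            "id": rec.id,
            "name": rec.name,
            "smiles": rec.canonical_smiles or rec.smiles,
            "approval_year": rec.approval_year,
            "indication": rec.indication,
            "descriptor_failure": False,
        }
        try:
            mol = rec.mol()
            if mol is None:
                raise DescriptorError(f"unparseable SMILES for {rec.id}")
            row.update(compute_descriptors(mol, config).as_dict())
        except DescriptorError:
            row["descriptor_failure"] = True
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["descriptor_config"] = asdict(config)
    return df
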