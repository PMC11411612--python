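"""Compound-table I/O and exclusion handling.

A drug library arrives as a CSV with one row per approved compound
(identifier, name, SMILES, approval year, indication class and an
exclusion flag).  Parsing validates every SMILES; rows that fail to parse
are kept but flagged as excluded with reason ``descriptor-failure`` so that
``|parsed| == |analysis set| + |excluded|`` holds exactly.  Salts and
solvates are reduced to the largest organic fragment before any descriptor
is computed, and a canonical SMILES is stored alongside the verbatim input
so downstream keys are well defined.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from rdkit import Chem

INDICATION_LABELS = (
    "cancer",
    "nervous system",
    "infection",
    "GI/metabolism",
    "cardiovascular",
    "respiratory/inflammation",
    "other",
)

EXCLUSION_REASONS = (
    "not-absorbed-GI",
    "combination-of-older-drugs",
    "descriptor-failure",
)


class DatasetError(ValueError):
    """Raised for unreadable, empty or structurally invalid compound tables."""


@dataclass
class DrugRecord:
    """One compound: structure, approval metadata and exclusion status."""

    id: str
    name: str
    smiles: str
    approval_year: int
    indication: str = "other"
    excluded: bool = False
    exclusion_reason: str | None = None
    canonical_smiles: str | None = None
    desalted: bool = False

    def mol(self) -> Chem.Mol | None:
        """Parent molecule (largest organic fragment), or None if unparseable."""
        if self.canonical_smiles is not None:
            return Chem.MolFromSmiles(self.canonical_smiles)
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:
            return None
        parent, _ = largest_fragment(mol)
        return parent


@dataclass
class AnalysisSet:
    """The post-exclusion record collection plus provenance of the cuts."""

    records: list[DrugRecord]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from the canonical field names to CSV column headers."""

    id: str = "id"
    name: str = "name"
    smiles: str = "smiles"
    approval_year: str = "approval_year"
    indication: str = "indication"
    excluded: str = "excluded"
    exclusion_reason: str = "exclusion_reason"


def largest_fragment(mol: Chem.Mol) -> tuple[Chem.Mol, bool]:
    """Return (largest organic fragment, whether anything was stripped).

    Fragments are ranked by heavy-atom count with carbon-containing
    fragments preferred, so counter-ions (Na+, Cl-) and water never win.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol, False

    def rank(frag: Chem.Mol) -> tuple[int, int]:
        has_c = any(a.GetSymbol() == "C" for a in frag.GetAtoms())
        return (int(has_c), frag.GetNumHeavyAtoms())

    best = max(frags, key=rank)
    Chem.SanitizeMol(best)
    return best, True


def _truthy(value) -> bool:
    if isinstance(value, bool):
        return value
    if pd.isna(value):
        return False
    return str(value).strip().lower() in {"1", "true", "yes", "y"}


def parse_dataset(
    path: str | Path,
    columns: ColumnMap | None = None,
    year_min: int = 2000,
    year_max: int = 2022,
) -> list[DrugRecord]:
    """Read a compound CSV into :class:`DrugRecord` objects.

    Every row yields a record.  SMILES that RDKit cannot parse are flagged
    ``excluded`` with reason ``descriptor-failure`` rather than dropped, so
    the caller can account for every input row.  Years outside
    ``[year_min, year_max]`` raise.
    """
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"no such file: {path}")
    columns = columns or ColumnMap()
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise DatasetError(f"empty dataset: {path}") from exc
    if df.empty:
        raise DatasetError(f"empty dataset: {path}")

    required = [columns.id, columns.name, columns.smiles, columns.approval_year]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DatasetError(f"missing required column(s): {missing}")

    records: list[DrugRecord] = []
    for _, row in df.iterrows():
        year = int(row[columns.approval_year])
        if not (year_min <= year <= year_max):
            raise DatasetError(
                f"approval year {year} outside window {year_min}-{year_max} "
                f"(id={row[columns.id]})"
            )
        excluded = (
            _truthy(row[columns.excluded]) if columns.excluded in df.columns else False
        )
        reason = None
        if columns.exclusion_reason in df.columns and not pd.isna(
            row[columns.exclusion_reason]
        ):
            reason = str(row[columns.exclusion_reason])
        smiles = str(row[columns.smiles])
        mol = Chem.MolFromSmiles(smiles)
        canonical = None
        desalted = False
        if mol is None:
            excluded = True
            reason = reason or "descriptor-failure"
        else:
            parent, desalted = largest_fragment(mol)
            canonical = Chem.MolToSmiles(parent)
        indication = "other"
        if columns.indication in df.columns and not pd.isna(row[columns.indication]):
            indication = str(row[columns.indication])
        records.append(
            DrugRecord(
                id=str(row[columns.id]),
                name=str(row[columns.name]),
                smiles=smiles,
                approval_year=year,
                indication=indication,
                excluded=excluded,
                exclusion_reason=reason,
                canonical_smiles=canonical,
                desalted=desalted,
            )
        )
    return records


def apply_exclusions(records: list[DrugRecord], source: str = "") -> AnalysisSet:
    """Drop flagged records, preserving order, and log per-reason counts."""
    kept = [r for r in records if not r.excluded]
    reasons = Counter(
        r.exclusion_reason or "unspecified" for r in records if r.excluded
    )
    ids = [r.id for r in kept]
    if len(set(ids)) != len(ids):
        dupes = [i for i, c in Counter(ids).items() if c > 1]
        raise DatasetError(f"duplicate ids in analysis set: {dupes}")
    if not kept:
        warnings.warn("all records excluded; analysis set is empty", stacklevel=2)
    return AnalysisSet(
        records=kept,
        provenance={
            "source": source,
            "n_input": len(records),
            "n_kept": len(kept),
            "n_excluded": len(records) - len(kept),
            "exclusion_counts": dict(reasons),
        },
    )


def write_structures(analysis_set: AnalysisSet, path: str | Path) -> None:
    """Write the set as an SDF (V2000), one record per compound.

    Carries id / name / approval_year as SD properties so the file
    round-trips through :func:`read_structures`.
    """
    path = Path(path)
    writer = Chem.SDWriter(str(path))
    try:
        for rec in analysis_set:
            mol = rec.mol()
            if mol is None:
                raise DatasetError(f"record {rec.id} has no valid structure")
            mol = Chem.Mol(mol)
            mol.SetProp("_Name", rec.name)
            mol.SetProp("id", rec.id)
            mol.SetProp("name", rec.name)
            mol.SetProp("approval_year", str(rec.approval_year))
            mol.SetProp("indication", rec.indication)
            writer.write(mol)
    finally:
        writer.close()


def read_structures(path: str | Path) -> list[DrugRecord]:
    """Read an SDF written by :func:`write_structures` back into records."""
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"no such file: {path}")
    if path.stat().st_size == 0:
        return []
    records = []
    for mol in Chem.SDMolSupplier(str(path)):
        if mol is None:
            continue
        smiles = Chem.MolToSmiles(mol)
        records.append(
            DrugRecord(
                id=mol.GetProp("id"),
                name=mol.GetProp("name"),
                smiles=smiles,
                approval_year=int(mol.GetProp("approval_year")),
                indication=mol.GetProp("indication")
                if mol.HasProp("indication")
                else "other",
                canonical_smiles=smiles,
            )
        )
    return records
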