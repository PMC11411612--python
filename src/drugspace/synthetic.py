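"""Synthetic drug-library generation with planted ground truth.

Molecules are assembled from a curated fragment grammar (ring cores,
linkers and capping groups joined at labelled attachment points), which
guarantees chemical validity, rather than sampled as random SMILES
strings.  The generator plants the properties the analysis pipeline is
supposed to recover: approval years with per-period Lipinski fail-rate
targets, a macrocycle fraction (rings of >= 12 atoms built explicitly),
ionisation classes (acid/base caps chosen per class) and a target
molecular-weight distribution.

Every planted property is verified against the package's own classifiers
during generation (with resampling on mismatch), so the emitted library's
ground-truth labels are exact, while realised descriptor *distributions*
approximate the targets within the spec tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors

from .classify import NetClass, ionisation_class, is_macrocycle, lipinski_assess
from .dataset import INDICATION_LABELS, DrugRecord
from .descriptors import compute_descriptors

# --------------------------------------------------------------------------
# Fragment grammar (shipped as data).  Two-point fragments enter at [*:1]
# and continue at [*:2]; caps have a single [*:1].
# --------------------------------------------------------------------------

RING_CORES = (
    "[*:1]c1ccc([*:2])cc1",        # 1,4-phenylene
    "[*:1]c1ccc([*:2])cn1",        # pyridine
    "[*:1]c1ncc([*:2])cn1",        # pyrimidine
    "[*:1]c1ccc([*:2])s1",         # thiophene
    "[*:1]c1ccc([*:2])o1",         # furan
    "[*:1]c1cc([*:2])ccc1C",       # toluene core
    "[*:1]C1CCC([*:2])CC1",        # cyclohexane
    "[*:1]C1CCC([*:2])CO1",        # tetrahydropyran
    "[*:1]C1CC([*:2])C1",          # cyclobutane
)

LINKERS = (
    "[*:1]C[*:2]",
    "[*:1]CC[*:2]",
    "[*:1]CCC[*:2]",
    "[*:1]O[*:2]",
    "[*:1]OC[*:2]",
    "[*:1]C(=O)N[*:2]",            # amide (excluded from strict RB count)
    "[*:1]NC(=O)[*:2]",
    "[*:1]S(=O)(=O)N[*:2]",
    "[*:1]C(C)[*:2]",
)

NEUTRAL_CAPS = (
    "[*:1]C",
    "[*:1]OC",
    "[*:1]F",
    "[*:1]Cl",
    "[*:1]O",                      # hydroxyl: +1 HBD
    "[*:1]C#N",
    "[*:1]C(C)C",
    "[*:1]C(N)=O",                 # primary amide: HBD/HBA, not basic
    "[*:1]S(C)(=O)=O",
)

LIPOPHILIC_CAPS = (
    "[*:1]c1ccccc1",
    "[*:1]c1ccc(Cl)cc1",
    "[*:1]c1ccc(C(F)(F)F)cc1",
    "[*:1]C(F)(F)F",
    "[*:1]CCCCC",
    "[*:1]c1ccc2ccccc2c1",         # naphthyl
)

ACID_CAPS = (
    "[*:1]C(=O)O",
    "[*:1]CC(=O)O",
    "[*:1]S(=O)(=O)O",
    "[*:1]c1nnn[nH]1",             # tetrazole
)

BASE_CAPS = (
    "[*:1]CN",                     # primary aliphatic amine
    "[*:1]CCNC",                   # secondary
    "[*:1]CCN(C)C",                # tertiary
    "[*:1]CN1CCCCC1",              # N-alkyl piperidine
)


class InfeasibleSpecError(ValueError):
    """The requested property targets cannot be realised chemically."""


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for a synthetic oral-drug library.

    Defaults emulate a 371-compound post-exclusion approval set: mean MWt
    432 Da (SD 159), ~3% macrocycles, period fail rates 12%/20%/18% for
    2000-2009 / 2010-2019 / 2020-2022, and a realistic ionisation-class
    mix for oral drugs (mostly neutral, balanced mono-acids/bases).
    """

    n: int = 371
    seed: int = 0
    mwt_mean: float = 432.0
    mwt_sd: float = 159.0
    clogp_mean: float = 3.4
    hbd_mean: float = 1.9
    hba_mean: float = 5.8
    rb_mean: float = 6.0
    fraction_macrocyclic: float = 10 / 371
    class_fractions: dict = field(
        default_factory=lambda: {
            NetClass.NEUTRAL: 0.60,
            NetClass.MONOACID: 0.15,
            NetClass.MONOBASE: 0.15,
            NetClass.ZWITTERION: 0.10,
        }
    )
    year_range: tuple[int, int] = (2000, 2022)
    bin_fail_rates: dict = field(
        default_factory=lambda: {
            (2000, 2009): 0.12,
            (2010, 2019): 0.20,
            (2020, 2022): 0.18,
        }
    )
    tolerance: float = 0.10

    def validate(self) -> None:
        if self.n < 1:
            raise InfeasibleSpecError("n must be >= 1")
        if not (0 <= self.fraction_macrocyclic <= 1):
            raise InfeasibleSpecError("fraction_macrocyclic must be in [0, 1]")
        total = sum(self.class_fractions.values())
        if not np.isclose(total, 1.0) or any(
            f < 0 for f in self.class_fractions.values()
        ):
            raise InfeasibleSpecError("class fractions must be >= 0 and sum to 1")
        for rate in self.bin_fail_rates.values():
            if not (0 <= rate <= 1):
                raise InfeasibleSpecError("fail rates must be in [0, 1]")
        if self.mwt_mean < 150:
            raise InfeasibleSpecError(
                f"target mean MWt {self.mwt_mean} below grammar minimum (~150 Da)"
            )
        # each N/O contributes >= 14 Da, so the HBA target bounds the MWt floor
        if self.mwt_mean < 14 * self.hba_mean:
            raise InfeasibleSpecError(
                f"target mean MWt {self.mwt_mean} infeasible with "
                f"{self.hba_mean} hydrogen-bond acceptors"
            )


# --------------------------------------------------------------------------
# Fragment assembly
# --------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _frag(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"grammar fragment does not parse: {smiles!r}")
    return mol


@lru_cache(maxsize=None)
def _frag_mw(smiles: str) -> float:
    """Approximate mass contribution of a fragment (dummies as H)."""
    mol = Chem.RWMol(_frag(smiles))
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetAtomicNum(1)
            atom.SetAtomMapNum(0)
    Chem.SanitizeMol(mol)
    return Descriptors.MolWt(mol) - 1.008 * smiles.count("[*:")


def _relabel(mol: Chem.Mol, src: int = 2, dst: int = 1) -> Chem.Mol:
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0 and atom.GetAtomMapNum() == src:
            atom.SetAtomMapNum(dst)
    return mol


def _has_port(mol: Chem.Mol, label: int = 1) -> bool:
    return any(
        a.GetAtomicNum() == 0 and a.GetAtomMapNum() == label for a in mol.GetAtoms()
    )


def _activate_port(mol: Chem.Mol) -> bool:
    """Expose a port as [*:1]; parked head ports carry map 9."""
    if _has_port(mol, 1):
        return True
    if _has_port(mol, 9):
        _relabel(mol, 9, 1)
        return True
    return False


def _join(core: Chem.Mol, frag_smiles: str) -> Chem.Mol:
    """Zip the core's open [*:1] port to a fragment's [*:1] port.

    A two-point fragment leaves its [*:2] port open, which is relabelled
    to [*:1] so chaining can continue.
    """
    frag = Chem.Mol(_frag(frag_smiles))
    zipped = Chem.molzip(Chem.CombineMols(core, frag))
    Chem.SanitizeMol(zipped)
    return _relabel(zipped)


def _cap_remaining(mol: Chem.Mol) -> Chem.Mol:
    """Close any open attachment points with hydrogen."""
    rw = Chem.RWMol(mol)
    for atom in rw.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetAtomicNum(1)
            atom.SetAtomMapNum(0)
    Chem.SanitizeMol(rw)
    return Chem.RemoveHs(rw)


def _macrocycle_core(
    rng: np.random.Generator, ring_size: int, n_amide_max: int | None = None
) -> Chem.Mol:
    """A >=12-membered ring with two open attachment points ([*:1], [*:9]).

    Ring composition mixes methylenes, ethers and ring amides (which add
    the donors/acceptors typical of natural-product macrocycles) while
    avoiding basic ring nitrogens.
    """
    tokens = ["C"] * ring_size
    if n_amide_max is None:
        n_amide_max = max(1, ring_size // 6)
    n_amide = int(rng.integers(0, n_amide_max + 1))
    n_ether = int(rng.integers(0, max(1, ring_size // 6) + 1))
    interior = list(range(1, ring_size - 1))
    rng.shuffle(interior)
    used: set[int] = set()
    free_needed = 2  # keep room for the attachment points
    placed = 0
    for pos in interior:
        if placed >= n_amide or len(used) + 2 > len(interior) - free_needed:
            break
        if pos in used or pos + 1 in used or pos + 1 >= ring_size - 1:
            continue
        tokens[pos] = "C(=O)"
        tokens[pos + 1] = "N"
        used |= {pos, pos + 1}
        placed += 1
    placed = 0
    for pos in interior:
        if placed >= n_ether or len(used) + 1 > len(interior) - free_needed:
            break
        if pos in used or (pos - 1) in used or (pos + 1) in used:
            continue
        tokens[pos] = "O"
        used.add(pos)
        placed += 1
    free = [p for p in interior if p not in used]
    tokens[free[0]] = "C([*:1])"
    tokens[free[1]] = "C([*:9])"
    smiles = tokens[0] + "1" + "".join(tokens[1:]) + "1"
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:  # pragma: no cover - grammar guarantees validity
        raise RuntimeError(f"macrocycle grammar produced invalid SMILES: {smiles}")
    return mol


def _class_caps(net_class: NetClass, rng: np.random.Generator) -> list[str]:
    if net_class == NetClass.MONOACID:
        return [str(rng.choice(ACID_CAPS))]
    if net_class == NetClass.MONOBASE:
        return [str(rng.choice(BASE_CAPS))]
    if net_class == NetClass.ZWITTERION:
        return [str(rng.choice(ACID_CAPS)), str(rng.choice(BASE_CAPS))]
    return []


def _assemble(
    rng: np.random.Generator,
    target_mw: float,
    net_class: NetClass,
    macrocycle: bool,
    lipophilic: bool,
) -> Chem.Mol:
    """Chain rings and linkers up to ~target_mw, then cap."""
    caps = _class_caps(net_class, rng)
    cap_pool = LIPOPHILIC_CAPS if lipophilic else NEUTRAL_CAPS
    budget = target_mw - sum(_frag_mw(c) for c in caps)

    if macrocycle:
        if lipophilic:
            # big, carbon-rich rings so the planted Lipinski fail is
            # reachable even when both ports carry ionisable caps
            ring_size = int(rng.integers(26, 35))
            mol = _macrocycle_core(rng, ring_size, n_amide_max=1)
        else:
            ring_size = int(rng.integers(12, 17))
            mol = _macrocycle_core(rng, ring_size)
    else:
        ring = str(rng.choice(RING_CORES))
        mol = Chem.Mol(_frag(ring))
        _relabel(mol, 1, 9)  # park the head port for a cap
        _relabel(mol, 2, 1)
        spent = _frag_mw(ring)
        chain_pool = RING_CORES + (LIPOPHILIC_CAPS if lipophilic else ())
        while spent + 170 < budget and _has_port(mol, 1):
            linker = str(rng.choice(LINKERS))
            nxt = str(rng.choice(chain_pool))
            if nxt.count("[*:") == 1 and len(caps) >= 2:
                nxt = str(rng.choice(RING_CORES))  # keep both ports for caps
            mol = _join(mol, linker)
            mol = _join(mol, nxt)
            spent += _frag_mw(linker) + _frag_mw(nxt)
            if nxt.count("[*:") == 1:
                break  # one-point group terminated the chain

    if rng.random() < 0.85:
        caps = caps + [str(rng.choice(cap_pool))]
    for cap in caps:
        if not _activate_port(mol):
            break
        mol = _join(mol, cap)
    return _cap_remaining(mol)


def _guaranteed_fail(rng: np.random.Generator) -> Chem.Mol:
    """Fallback constructor for a certain Lipinski fail (MWt and clogP)."""
    n_units = int(rng.integers(4, 7))
    mol = Chem.Mol(_frag("[*:1]c1ccc([*:2])cc1"))
    _relabel(mol, 1, 9)
    _relabel(mol, 2, 1)
    for _ in range(n_units):
        mol = _join(mol, str(rng.choice(("[*:1]C[*:2]", "[*:1]CC[*:2]"))))
        mol = _join(mol, str(rng.choice(("[*:1]c1ccc([*:2])cc1",
                                         "[*:1]c1cc([*:2])ccc1Cl"))))
    mol = _join(mol, "[*:1]C(F)(F)F")
    return _cap_remaining(mol)


# --------------------------------------------------------------------------
# Library generation
# --------------------------------------------------------------------------

_INDICATION_WEIGHTS = (0.25, 0.23, 0.19, 0.10, 0.09, 0.05, 0.09)


def _year_bin(year: int, bins) -> tuple[int, int]:
    for lo, hi in bins:
        if lo <= year <= hi:
            return (lo, hi)
    raise ValueError(f"year {year} outside all fail-rate bins")


def generate_library(spec: GeneratorSpec) -> list[DrugRecord]:
    """Generate ``spec.n`` unique, valid drug records with planted labels.

    Deterministic for a fixed seed.  Each record's planted macrocycle
    flag, ionisation class and Lipinski verdict are verified with the
    package's own classifiers before acceptance.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    classes = list(spec.class_fractions)
    class_p = np.array([spec.class_fractions[c] for c in classes], dtype=float)
    class_p = class_p / class_p.sum()
    y_lo, y_hi = spec.year_range

    fail_mw = max(620.0, spec.mwt_mean + 200.0)
    # the chain builder systematically stops short of its mass budget;
    # offset the target draws accordingly
    assembly_offset = 90.0

    records: list[DrugRecord] = []
    seen: set[str] = set()
    running_mw = 0.0
    for idx in range(spec.n):
        year = int(rng.integers(y_lo, y_hi + 1))
        fail_rate = spec.bin_fail_rates[_year_bin(year, spec.bin_fail_rates)]
        want_fail = bool(rng.random() < fail_rate)
        want_macro = bool(rng.random() < spec.fraction_macrocyclic)
        net_class = classes[int(rng.choice(len(classes), p=class_p))]
        indication = str(
            rng.choice(INDICATION_LABELS, p=np.array(_INDICATION_WEIGHTS))
        )

        # steer each record's mass target so the running library mean
        # tracks the requested mean despite the pass/fail mixture
        needed = spec.mwt_mean * (idx + 1) - running_mw
        mol = None
        d = None
        for attempt in range(60):
            if want_fail:
                target = float(
                    rng.normal(max(fail_mw, needed) + 40 * attempt, 80)
                )
            else:
                base = float(np.clip(needed, 170, 495))
                target = float(
                    np.clip(
                        rng.normal(base + assembly_offset, spec.mwt_sd * 0.7),
                        170,
                        560,
                    )
                )
            if attempt >= 40 and want_fail and not want_macro:
                candidate = _guaranteed_fail(rng)
            else:
                candidate = _assemble(
                    rng, target, net_class, want_macro, lipophilic=want_fail
                )
            d = compute_descriptors(candidate)
            if lipinski_assess(d).fails != want_fail:
                continue
            if is_macrocycle(candidate) != want_macro:
                continue
            if ionisation_class(candidate).net_class != net_class:
                continue
            smiles = Chem.MolToSmiles(candidate)
            if smiles in seen:
                continue
            mol = candidate
            break
        if mol is None:
            raise RuntimeError(
                f"could not realise planted properties for record {idx} "
                f"(fail={want_fail}, macrocycle={want_macro}, class={net_class})"
            )
        smiles = Chem.MolToSmiles(mol)
        seen.add(smiles)
        running_mw += d.mwt
        records.append(
            DrugRecord(
                id=f"SYN-{idx:04d}",
                name=f"synthetic-{idx:04d}",
                smiles=smiles,
                approval_year=year,
                indication=indication,
                canonical_smiles=smiles,
            )
        )
    return records


def records_to_csv(records: list[DrugRecord], path: str | Path) -> None:
    """Write records in the CSV schema that :func:`parse_dataset` reads."""
    pd.DataFrame(
        {
            "id": [r.id for r in records],
            "name": [r.name for r in records],
            "smiles": [r.smiles for r in records],
            "approval_year": [r.approval_year for r in records],
            "indication": [r.indication for r in records],
            "excluded": [r.excluded for r in records],
            "exclusion_reason": [r.exclusion_reason for r in records],
        }
    ).to_csv(path, index=False)


# --------------------------------------------------------------------------
# Hand-verified fixture molecules
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FixtureMolecule:
    name: str
    smiles: str
    expected: dict


def fixture_molecules() -> dict[str, FixtureMolecule]:
    """Small molecules with hand-computed descriptor expectations.

    The expectations were derived by hand (atomic-mass sums, atom/bond
    counts under the rule-of-5 conventions) and anchor the unit tests of
    the descriptor, classification and shape modules.
    """
    fixtures = [
        FixtureMolecule(
            "ethanol",
            "CCO",
            {
                "mwt": 46.07,
                "hbd": 1,
                "hba": 1,
                "rotatable_bonds": 0,
                "aromatic_rings": 0,
                "fsp3": 1.0,
                "net_class": NetClass.NEUTRAL,
            },
        ),
        FixtureMolecule(
            "benzene",
            "c1ccccc1",
            {
                "mwt": 78.11,
                "hbd": 0,
                "hba": 0,
                "aromatic_rings": 1,
                "fsp3": 0.0,
                "aromatic_atoms": 6,
                "macrocycle": False,
            },
        ),
        FixtureMolecule(
            "aspirin",
            "CC(=O)Oc1ccccc1C(=O)O",
            {"mwt": 180.16, "hbd": 1, "hba": 4, "aromatic_rings": 1},
        ),
        FixtureMolecule(
            "cyclohexane",
            "C1CCCCC1",
            {"fsp3": 1.0, "macrocycle": False, "ring_count": 1},
        ),
        FixtureMolecule(
            "cyclododecane",
            "C1CCCCCCCCCCC1",
            {"macrocycle": True, "ring_count": 1, "fsp3": 1.0},
        ),
        FixtureMolecule(
            "naphthalene",
            "c1ccc2ccccc2c1",
            {"macrocycle": False, "aromatic_rings": 2, "aromatic_atoms": 10},
        ),
        FixtureMolecule(
            "acetic_acid",
            "CC(=O)O",
            {"net_class": NetClass.MONOACID, "acid_groups": 1, "base_groups": 0},
        ),
        FixtureMolecule(
            "ethylamine",
            "CCN",
            {"net_class": NetClass.MONOBASE, "acid_groups": 0, "base_groups": 1},
        ),
        FixtureMolecule(
            "ethylbenzene",
            "CCc1ccccc1",
            {"fsp3": 0.25, "aromatic_rings": 1},
        ),
    ]
    out = {}
    for fx in fixtures:
        if Chem.MolFromSmiles(fx.smiles) is None:  # pragma: no cover
            warnings.warn(f"fixture {fx.name} failed to parse", stacklevel=2)
            continue
        out[fx.name] = fx
    return out
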