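"""Conformer-ensemble generation and force-field optimisation.

Ensembles are embedded with the knowledge-based distance-geometry
algorithm (ETKDGv3), with an RMS pruning threshold of 0.1 Å, up to 1000
embedding attempts, random initial coordinates, small-ring torsion terms
and a fixed random seed, then relaxed with the MMFF94 force field, which
also supplies the per-conformer energies (kcal/mol) used for Boltzmann
weighting downstream.

The number of conformers requested per molecule follows the
rotatable-bond rule of Ebejer et al.: 50 for <=7 rotatable bonds, 200 for
8-12, and 300 above 12.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolDescriptors


class EmbeddingError(RuntimeError):
    """3D embedding or force-field setup failed for a molecule."""


def conformer_count_rule(rotatable_bonds: int) -> int:
    """Ensemble size from the rotatable-bond count: 50 / 200 / 300."""
    if rotatable_bonds < 0:
        raise ValueError("rotatable bond count must be non-negative")
    if rotatable_bonds <= 7:
        return 50
    if rotatable_bonds <= 12:
        return 200
    return 300


def molecule_seed(global_seed: int, canonical_smiles: str) -> int:
    """Per-molecule embedding seed: global seed offset by a stable hash.

    Keeps every molecule's ensemble reproducible and independent of which
    other compounds are in the batch.
    """
    offset = zlib.crc32(canonical_smiles.encode("utf-8"))
    return int((int(global_seed) + offset) % (2**31 - 1)) or 1


@dataclass
class ConformerEnsemble:
    """Embedded (optionally optimised) conformers of one molecule.

    ``mol`` carries explicit hydrogens and one RDKit conformer per kept
    embedding; ``energies`` is populated (kcal/mol, MMFF94) by
    :func:`optimise_ensemble`.
    """

    mol: Chem.Mol
    mol_id: str
    seed: int
    n_requested: int
    prune_rms: float = 0.1
    energies: np.ndarray | None = None
    optimised: bool = False
    metadata: dict = field(default_factory=dict)

    @property
    def n_kept(self) -> int:
        return self.mol.GetNumConformers()

    def coordinates(self, conf_id: int) -> np.ndarray:
        return np.asarray(self.mol.GetConformer(conf_id).GetPositions())

    def masses(self) -> np.ndarray:
        return np.array([a.GetMass() for a in self.mol.GetAtoms()])


def generate_ensemble(
    molecule: Chem.Mol | str,
    seed: int,
    mol_id: str = "",
    n_conformers: int | None = None,
    prune_rms: float = 0.1,
    max_attempts: int = 1000,
) -> ConformerEnsemble:
    """Embed a pruned conformer ensemble (deterministic for a fixed seed).

    ``n_conformers`` defaults to :func:`conformer_count_rule` applied to
    the molecule's strict rotatable-bond count.  Raises
    :class:`EmbeddingError` if no conformer can be embedded — such
    molecules are treated as descriptor failures upstream, not crashes.
    """
    if isinstance(molecule, str):
        molecule = Chem.MolFromSmiles(molecule)
        if molecule is None:
            raise EmbeddingError("unparseable SMILES")
    if molecule is None or molecule.GetNumAtoms() == 0:
        raise EmbeddingError("empty molecule")

    if n_conformers is None:
        rb = rdMolDescriptors.CalcNumRotatableBonds(
            molecule, rdMolDescriptors.NumRotatableBondsOptions.Strict
        )
        n_conformers = conformer_count_rule(rb)

    molh = Chem.AddHs(molecule)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    params.pruneRmsThresh = float(prune_rms)
    params.maxIterations = int(max_attempts)
    params.useRandomCoords = True
    params.useSmallRingTorsions = True
    conf_ids = AllChem.EmbedMultipleConfs(molh, numConfs=n_conformers, params=params)
    if len(conf_ids) == 0:
        raise EmbeddingError(
            f"embedding failed after {max_attempts} attempts for {mol_id or Chem.MolToSmiles(molecule)}"
        )
    return ConformerEnsemble(
        mol=molh,
        mol_id=mol_id or Chem.MolToSmiles(molecule),
        seed=int(seed),
        n_requested=n_conformers,
        prune_rms=prune_rms,
        metadata={"embed": "ETKDGv3", "max_attempts": max_attempts},
    )


def mmff_energies(ensemble: ConformerEnsemble) -> np.ndarray:
    """MMFF94 single-point energies (kcal/mol) of the current geometries."""
    mol = ensemble.mol
    props = AllChem.MMFFGetMoleculeProperties(mol, mmffVariant="MMFF94")
    if props is None:
        raise EmbeddingError(f"MMFF94 parameters missing for {ensemble.mol_id}")
    energies = []
    for conf in mol.GetConformers():
        ff = AllChem.MMFFGetMoleculeForceField(mol, props, confId=conf.GetId())
        energies.append(ff.CalcEnergy())
    return np.array(energies)


def optimise_ensemble(
    ensemble: ConformerEnsemble, max_iters: int = 200
) -> ConformerEnsemble:
    """Relax every conformer with MMFF94 and record its final energy.

    Returns a new ensemble (the input is not modified) whose per-conformer
    energy is never above the pre-optimisation energy beyond convergence
    noise.
    """
    if ensemble.n_kept == 0:
        raise EmbeddingError("cannot optimise an empty ensemble")
    mol = Chem.Mol(ensemble.mol)
    results = AllChem.MMFFOptimizeMoleculeConfs(
        mol, mmffVariant="MMFF94", maxIters=int(max_iters)
    )
    energies = np.array([e for _, e in results])
    if not np.all(np.isfinite(energies)):
        raise EmbeddingError(f"MMFF94 setup failed for {ensemble.mol_id}")
    out = replace(ensemble, mol=mol, energies=energies, optimised=True)
    out.metadata = dict(ensemble.metadata, forcefield="MMFF94", max_iters=max_iters)
    return out


def min_pairwise_rms(ensemble: ConformerEnsemble, heavy_only: bool = True) -> float:
    """Smallest pairwise conformer RMS (Å); checks the pruning invariant."""
    mol = Chem.RemoveHs(Chem.Mol(ensemble.mol)) if heavy_only else Chem.Mol(
        ensemble.mol
    )
    ids = [c.GetId() for c in mol.GetConformers()]
    if len(ids) < 2:
        return float("inf")
    best = float("inf")
    for i, ci in enumerate(ids):
        for cj in ids[i + 1 :]:
            rms = AllChem.GetConformerRMS(mol, ci, cj, prealigned=False)
            best = min(best, rms)
    return best
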