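"""Principal moments of inertia, NPR shape ratios and Boltzmann averaging.

For a rigid body the moment of inertia about an axis is I = sum_i m_i r_i^2
with r_i the perpendicular distance of atom i from the axis.  The three
principal moments I1 <= I2 <= I3 are the eigenvalues of the mass-weighted
inertia tensor about the centre of mass.  The normalised principal moment
ratios NPR1 = I1/I3 and NPR2 = I2/I3 place every molecule in a triangle
whose corners are rod (0, 1), disc (0.5, 0.5) and sphere (1, 1).

Conformer-ensemble properties are Boltzmann-averaged at T = 300 K with
weights proportional to exp(-E_i / kB T); energies are MMFF94 kcal/mol, so
kB is expressed in kcal mol^-1 K^-1 to match.  The NPRs are averaged per
conformer (average of ratios, not ratio of averaged moments).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Boltzmann constant in kcal/(mol K): must match MMFF94 energy units.
KB_KCAL_PER_MOL_K = 0.0019872041


def moments_of_inertia(
    coordinates: np.ndarray, masses: np.ndarray
) -> tuple[float, float, float]:
    """Principal moments (amu A^2), sorted ascending.

    Eigenvalues of the inertia tensor about the centre of mass; invariant
    under rigid translation and rotation of the coordinates.
    """
    coords = np.asarray(coordinates, dtype=float)
    m = np.asarray(masses, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] == 0:
        raise ValueError("coordinates must be a non-empty (n, 3) array")
    if m.shape != (coords.shape[0],):
        raise ValueError("masses must match the number of atoms")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    total = m.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    r = coords - (m[:, None] * coords).sum(axis=0) / total
    # I = sum_i m_i (|r_i|^2 Id - r_i r_i^T)
    tensor = np.einsum("i,ij,ik->jk", m, r, r)
    tensor = np.eye(3) * np.trace(tensor) - tensor
    i1, i2, i3 = np.linalg.eigvalsh(tensor)
    return float(max(i1, 0.0)), float(max(i2, 0.0)), float(max(i3, 0.0))


def npr(i1: float, i2: float, i3: float) -> tuple[float, float]:
    """Normalised principal moment ratios (I1/I3, I2/I3)."""
    if not (i1 <= i2 <= i3):
        raise ValueError("moments must be sorted ascending")
    if i3 <= 0:
        raise ValueError("NPR undefined: largest moment is zero (point mass?)")
    return i1 / i3, i2 / i3


def boltzmann_weights(
    energies: np.ndarray, temperature: float = 300.0
) -> np.ndarray:
    """Normalised conformer weights w_i ∝ exp(-E_i / kB T).

    Energies in kcal/mol are shifted by their minimum before
    exponentiation for numerical stability, which leaves the normalised
    weights unchanged.
    """
    e = np.asarray(energies, dtype=float)
    if e.ndim != 1 or e.size == 0:
        raise ValueError("energies must be a non-empty 1-D array")
    if temperature <= 0:
        raise ValueError("temperature must be positive (K)")
    x = -(e - e.min()) / (KB_KCAL_PER_MOL_K * temperature)
    w = np.exp(x)
    return w / w.sum()


def boltzmann_average(
    values: np.ndarray, energies: np.ndarray, temperature: float = 300.0
) -> float:
    """Boltzmann-weighted ensemble average of a per-conformer property."""
    v = np.asarray(values, dtype=float)
    e = np.asarray(energies, dtype=float)
    if v.shape != e.shape:
        raise ValueError("values and energies must have equal length")
    w = boltzmann_weights(e, temperature)
    return float(np.dot(w, v))


@dataclass
class ShapeDescriptors:
    """Per-conformer and ensemble-averaged PMI/NPR shape of one molecule."""

    mol_id: str
    pmi: np.ndarray  # (n_conf, 3), sorted ascending per conformer
    npr1: np.ndarray
    npr2: np.ndarray
    energies: np.ndarray
    temperature: float
    npr1_boltzmann: float
    npr2_boltzmann: float
    npr1_lowest_energy: float
    npr2_lowest_energy: float

    @property
    def n_conformers(self) -> int:
        return len(self.npr1)

    @property
    def min_energy(self) -> float:
        return float(self.energies.min())


def ensemble_shape(
    ensemble, temperature: float = 300.0, use_masses: bool = True
) -> ShapeDescriptors:
    """Shape descriptors of an optimised conformer ensemble.

    Uses isotope-averaged atomic masses (hydrogens are explicit in the 3D
    structures); ``use_masses=False`` switches to unit weights for
    comparison with geometry-only conventions.
    """
    if ensemble.energies is None:
        raise ValueError("ensemble has no energies; run optimise_ensemble first")
    n = ensemble.n_kept
    if n == 0:
        raise ValueError("empty ensemble")
    masses = ensemble.masses() if use_masses else np.ones(ensemble.mol.GetNumAtoms())
    pmi = np.empty((n, 3))
    npr1 = np.empty(n)
    npr2 = np.empty(n)
    conf_ids = [c.GetId() for c in ensemble.mol.GetConformers()]
    for k, cid in enumerate(conf_ids):
        i1, i2, i3 = moments_of_inertia(ensemble.coordinates(cid), masses)
        pmi[k] = (i1, i2, i3)
        npr1[k], npr2[k] = npr(i1, i2, i3)
    e = np.asarray(ensemble.energies, dtype=float)
    lowest = int(np.argmin(e))
    return ShapeDescriptors(
        mol_id=ensemble.mol_id,
        pmi=pmi,
        npr1=npr1,
        npr2=npr2,
        energies=e,
        temperature=temperature,
        npr1_boltzmann=boltzmann_average(npr1, e, temperature),
        npr2_boltzmann=boltzmann_average(npr2, e, temperature),
        npr1_lowest_energy=float(npr1[lowest]),
        npr2_lowest_energy=float(npr2[lowest]),
    )
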