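"""Inertia moments, NPR triangle and Boltzmann averaging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit.Chem import rdMolDescriptors
from scipy.spatial.transform import Rotation

from drugspace import (
    KB_KCAL_PER_MOL_K,
    boltzmann_average,
    boltzmann_weights,
    ensemble_shape,
    generate_ensemble,
    moments_of_inertia,
    npr,
    optimise_ensemble,
)


def test_point_mass_moments_hand_cases():
    # two unit masses at (+-1, 0, 0): I = 0 about the axis, 2 about the others
    assert moments_of_inertia(
        [[1.0, 0, 0], [-1.0, 0, 0]], [1.0, 1.0]
    ) == pytest.approx((0.0, 2.0, 2.0))
    # four unit masses at the corners of a square in the xy plane
    square = [[1.0, 1, 0], [1, -1, 0], [-1, 1, 0], [-1, -1, 0]]
    assert moments_of_inertia(square, np.ones(4)) == pytest.approx((4.0, 4.0, 8.0))
    # a single point mass anywhere has zero moments
    assert moments_of_inertia([[3.0, -2.0, 5.0]], [12.0]) == pytest.approx(
        (0.0, 0.0, 0.0)
    )


def test_moments_input_validation():
    with pytest.raises(ValueError):
        moments_of_inertia(np.empty((0, 3)), np.empty(0))
    with pytest.raises(ValueError):
        moments_of_inertia([[0.0, 0, 0]], [0.0])  # zero total mass
    with pytest.raises(ValueError):
        moments_of_inertia([[np.inf, 0, 0]], [1.0])


def test_moments_rigid_motion_invariance():
    """Rotations and translations leave the principal moments unchanged."""
    rng = np.random.default_rng(5)
    coords = rng.normal(size=(15, 3)) * 3.0
    masses = rng.uniform(1.0, 16.0, size=15)
    reference = np.array(moments_of_inertia(coords, masses))
    for rot in Rotation.random(10, rng=np.random.default_rng(8)):
        shifted = rot.apply(coords) + rng.normal(size=3) * 50.0
        moved = np.array(moments_of_inertia(shifted, masses))
        assert np.allclose(moved, reference, rtol=1e-8, atol=1e-8)


@pytest.mark.parametrize(
    "moments,expected",
    [
        ((0.0, 2.0, 2.0), (0.0, 1.0)),   # rod
        ((4.0, 4.0, 8.0), (0.5, 0.5)),   # disc
        ((8.0, 8.0, 8.0), (1.0, 1.0)),   # sphere
    ],
)
def test_npr_canonical_shapes(moments, expected):
    assert npr(*moments) == pytest.approx(expected)


def test_npr_errors():
    with pytest.raises(ValueError, match="sorted"):
        npr(3.0, 2.0, 1.0)
    with pytest.raises(ValueError, match="zero"):
        npr(0.0, 0.0, 0.0)  # single atom


def test_boltzmann_average_basics():
    assert boltzmann_average([5.0], [123.4]) == 5.0
    assert boltzmann_average([1.0, 3.0], [2.0, 2.0]) == pytest.approx(2.0)
    # delta E = kB T ln 2 makes the weights exactly 2:1
    delta = KB_KCAL_PER_MOL_K * 300.0 * np.log(2.0)
    assert boltzmann_average([0.0, 1.0], [0.0, delta]) == pytest.approx(1.0 / 3.0)


def test_boltzmann_temperature_limits():
    values = np.array([0.2, 0.7, 0.4])
    energies = np.array([1.0, 3.0, 2.0])
    assert boltzmann_average(values, energies, temperature=1e9) == pytest.approx(
        values.mean(), abs=1e-4
    )
    assert boltzmann_average(values, energies, temperature=1e-3) == pytest.approx(
        0.2, abs=1e-12
    )


def test_boltzmann_average_bounded_and_weights_valid():
    rng = np.random.default_rng(17)
    for _ in range(25):
        n = int(rng.integers(1, 12))
        values = rng.normal(size=n)
        energies = rng.uniform(0, 50, size=n)
        w = boltzmann_weights(energies)
        assert w.sum() == pytest.approx(1.0)
        order = np.argsort(energies)
        assert np.all(np.diff(w[order]) <= 1e-12)  # non-increasing in energy
        avg = boltzmann_average(values, energies)
        assert values.min() - 1e-12 <= avg <= values.max() + 1e-12


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    st.lists(
        st.tuples(
            st.floats(-100, 100, allow_nan=False),
            st.floats(0, 200, allow_nan=False),
        ),
        min_size=1,
        max_size=10,
    ),
    st.floats(1.0, 1e4),
)
def test_boltzmann_average_is_a_convex_combination(pairs, temperature):
    values = np.array([v for v, _ in pairs])
    energies = np.array([e for _, e in pairs])
    avg = boltzmann_average(values, energies, temperature)
    assert values.min() - 1e-9 <= avg <= values.max() + 1e-9
    w = boltzmann_weights(energies, temperature)
    assert w.sum() == pytest.approx(1.0)


def test_boltzmann_input_validation():
    with pytest.raises(ValueError):
        boltzmann_average([1.0, 2.0], [1.0])
    with pytest.raises(ValueError):
        boltzmann_average([], [])
    with pytest.raises(ValueError):
        boltzmann_weights([1.0], temperature=0.0)


def test_ensemble_shape_matches_toolkit_and_triangle():
    """Drug-like ensemble: NPRs agree with the toolkit and sit in the
    rod-disc-sphere triangle."""
    ens = optimise_ensemble(
        generate_ensemble("CC(=O)Oc1ccccc1C(=O)O", seed=11, mol_id="aspirin")
    )
    sd = ensemble_shape(ens)
    assert sd.n_conformers == ens.n_kept
    # cross-check one conformer against the toolkit's independent NPR code
    cid = ens.mol.GetConformers()[0].GetId()
    assert sd.npr1[0] == pytest.approx(
        rdMolDescriptors.CalcNPR1(ens.mol, confId=cid), rel=1e-6
    )
    assert sd.npr2[0] == pytest.approx(
        rdMolDescriptors.CalcNPR2(ens.mol, confId=cid), rel=1e-6
    )
    for n1, n2 in [(sd.npr1_boltzmann, sd.npr2_boltzmann),
                   (sd.npr1_lowest_energy, sd.npr2_lowest_energy)]:
        assert 0.0 <= n1 <= n2 <= 1.0 + 1e-12
        assert n1 + n2 >= 1.0 - 1e-12
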