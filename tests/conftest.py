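"""Shared fixtures: simulated datasets at several scales.

The "fast" configuration keeps the full beam and crystal model but
shrinks the detector, which raises the corner resolution limit and cuts
the reflection count per pattern by more than an order of magnitude —
unit tests exercise the same physics on far fewer reflections.
"""

from __future__ import annotations

import copy

import numpy as np
import pytest

from stillref.geometry import (
    BeamModel,
    DetectorModel,
    SymmetryGroup,
    UnitCell,
)
from stillref.simulate import SimulationConfig, simulate_dataset


def fast_config(**overrides) -> SimulationConfig:
    """Full physics, small detector (few hundred reflections per pattern)."""
    defaults = dict(
        n_patterns=10,
        detector=DetectorModel(30.0, 50.0),
        seed=1234,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def paper_beam() -> BeamModel:
    return BeamModel(8.0, bandwidth_frac=5e-4, convergence_rad=1e-3)


@pytest.fixture(scope="session")
def paper_cell() -> UnitCell:
    return UnitCell(144.2, 113.78)


@pytest.fixture(scope="session")
def laue_r32() -> SymmetryGroup:
    return SymmetryGroup.from_spacegroup("R 3 2:R")


@pytest.fixture(scope="session")
def small_dataset():
    """Noisy dataset, small detector: 12 patterns with default 0.1% errors."""
    return simulate_dataset(fast_config(n_patterns=12, seed=7))


@pytest.fixture(scope="session")
def noiseless_dataset():
    """No noise, no basis perturbation: the exact-recovery regime."""
    return simulate_dataset(
        fast_config(n_patterns=15, seed=3, noise_sigma=0.0, basis_error_max_frac=0.0)
    )


@pytest.fixture(scope="session")
def noiseless_perturbed_dataset():
    """No noise but 0.1% basis errors: geometry-refinement test bed."""
    return simulate_dataset(fast_config(n_patterns=10, seed=5, noise_sigma=0.0))


@pytest.fixture()
def small_dataset_copy(small_dataset):
    ds = copy.copy(small_dataset)
    ds.patterns = copy.deepcopy(small_dataset.patterns)
    return ds


@pytest.fixture()
def noiseless_dataset_copy(noiseless_dataset):
    ds = copy.copy(noiseless_dataset)
    ds.patterns = copy.deepcopy(noiseless_dataset.patterns)
    return ds


@pytest.fixture()
def noiseless_perturbed_copy(noiseless_perturbed_dataset):
    ds = copy.copy(noiseless_perturbed_dataset)
    ds.patterns = copy.deepcopy(noiseless_perturbed_dataset.patterns)
    return ds


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240001)
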