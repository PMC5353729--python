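"""Shared fixtures: one default synthetic dataset per test session."""

from __future__ import annotations

import pytest

from chsfam.pipeline import extract_all_con1, reference_from_labeled
from chsfam.simulate import SimConfig, simulate_family


@pytest.fixture(scope="session")
def default_dataset():
    """The 12-species default dataset (seed 1), shared read-only."""
    return simulate_family(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_con1(default_dataset):
    return extract_all_con1(default_dataset.records)


@pytest.fixture(scope="session")
def default_reference(default_dataset):
    return reference_from_labeled(default_dataset.reference)
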