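import numpy as np
import pytest

from hicrit import (
    EffectSpec,
    make_node_annotation,
    plant_random_edges,
    simulate_connectomes,
    simulate_subjects,
)


@pytest.fixture(scope="session")
def cohort77():
    """Default-sized synthetic cohort with all categorical levels present."""
    df = simulate_subjects(77, seed=0)
    assert df["race"].nunique() == 3 and df["sex"].nunique() == 2
    return df


@pytest.fixture(scope="session")
def annotation212():
    return make_node_annotation()


@pytest.fixture(scope="session")
def small_annotation():
    """30-node connectome (435 edges) for fast end-to-end exercises."""
    return make_node_annotation({"networks": {"DMN": 12, "ASN": 10, "LECN": 8}})


@pytest.fixture(scope="session")
def null_panel(cohort77, small_annotation):
    """Panel with no planted worry signal."""
    spec = EffectSpec(planted={}, noise_sd=0.3)
    return simulate_connectomes(cohort77, small_annotation, spec, seed=101)


@pytest.fixture(scope="session")
def planted_panel(small_annotation):
    """Moderate-signal panel: 40 of 435 edges at 0.3 Fisher-Z per SD of worry."""
    subjects = simulate_subjects(150, seed=5)
    spec = plant_random_edges(435, 40, 0.3, seed=6, noise_sd=0.3)
    panel = simulate_connectomes(subjects, small_annotation, spec, seed=7)
    return subjects, panel, frozenset(spec.planted)
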