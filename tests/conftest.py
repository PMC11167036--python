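"""Shared fixtures: scaled-down synthetic cohorts and tiny hand-made matrices."""

import numpy as np
import pandas as pd
import pytest

from txharmony.simulate import SimConfig, StudyTemplate, generate_multistudy_counts


def small_cohort_config(seed: int = 0, **overrides) -> SimConfig:
    """A 6-study cohort with the default sample sizes but a small gene universe."""
    defaults = dict(
        n_genes=400,
        n_signal_genes=30,
        n_correlated_blocks=5,
        block_size=10,
        pseudogene_fraction=0.1,
        seed=seed,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


def tiny_two_study_config(seed: int = 0, **overrides) -> SimConfig:
    """Two modest studies for fast unit tests that need real count structure."""
    studies = (
        StudyTemplate("ST1", "M1", 8, 8, "C57BL/6J", (16,), "F", "ribo_depletion"),
        StudyTemplate("ST2", "M2", 10, 10, "BALB/c", (10,), "F", "ribo_depletion"),
    )
    defaults = dict(
        studies=studies,
        n_genes=200,
        n_signal_genes=20,
        n_correlated_blocks=3,
        block_size=8,
        pseudogene_fraction=0.1,
        seed=seed,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    bundles, truth = generate_multistudy_counts(small_cohort_config(seed=7))
    return bundles, truth


@pytest.fixture(scope="session")
def tiny_cohort():
    bundles, truth = generate_multistudy_counts(tiny_two_study_config(seed=3))
    return bundles, truth


@pytest.fixture()
def separable_xy():
    """Two-gene linearly separable toy (20 samples)."""
    rng = np.random.default_rng(0)
    n = 20
    y = np.array([0] * 10 + [1] * 10)
    X = pd.DataFrame(
        {
            "gA": y * 4.0 + rng.normal(0, 0.3, n),
            "gB": rng.normal(0, 1.0, n),
        },
        index=[f"s{i}" for i in range(n)],
    )
    return X, y
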