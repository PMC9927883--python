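"""Shared fixtures: small synthetic cohorts and helper builders."""

from __future__ import annotations

import numpy as np
import pytest

from eegsift.atlas import make_atlas
from eegsift.cohort import CohortConfig, EffectSpec, generate_cohort

FS = 128.0


def small_labels(n: int) -> tuple[str, ...]:
    return tuple(make_atlas()[:n])


def make_gaussian_table(seed: int, n_per_class: int = 60, n_features: int = 200,
                        n_informative: int = 10, d: float = 1.5):
    """Feature table with the first ``n_informative`` columns shifted by d."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    X = rng.standard_normal((n, n_features))
    y = np.array([0] * n_per_class + [1] * n_per_class)
    X[y == 1, :n_informative] += d
    return X, y


@pytest.fixture(scope="session")
def tiny_cohort():
    """10-subject, 4-region, 40-s cohort with two strong planted effects."""
    labels = small_labels(4)
    cfg = CohortConfig(
        n_controls=5, n_patients=5, duration_s=40.0, n_regions=4,
        region_labels=labels, seed=11,
        effect_specs=(
            EffectSpec("abs_psd", "alpha", labels[0], 2.0),
            EffectSpec("coupling", "alpha", (labels[1], labels[2]), 2.0),
        ),
    )
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
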