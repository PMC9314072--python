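"""Shared fixtures: micro example matrices and seeded random MPM draws."""

from __future__ import annotations

import numpy as np
import pytest

from demres.mpm import MPMRecord
from demres.nullsim import NullSimConfig, random_mpm


@pytest.fixture
def iteroparous_2x2() -> MPMRecord:
    """Two-stage matrix with a self-loop: irreducible, primitive, ergodic."""
    return MPMRecord(
        species_name="Testus iteroparus",
        population_id="iter_1",
        kingdom="animal",
        mat_A=np.array([[0.2, 1.6], [0.4, 0.5]]),
    )


@pytest.fixture
def semelparous_2x2() -> MPMRecord:
    """Two-stage single-loop matrix (imprimitive): U/F split supplied."""
    return MPMRecord(
        species_name="Testus semelparus",
        population_id="semel_1",
        kingdom="animal",
        mat_U=np.array([[0.0, 0.0], [0.5, 0.0]]),
        mat_F=np.array([[0.0, 4.0], [0.0, 0.0]]),
    )


def draw_valid_mpms(n: int, seed: int, max_dim: int = 8) -> list[MPMRecord]:
    """Seeded admissible random MPMs with dimensions in [2, max_dim]."""
    cfg = NullSimConfig(n_matrices=n, dim_range=(2, max_dim), seed=seed)
    rng = np.random.default_rng(seed)
    return [
        random_mpm(int(rng.integers(2, max_dim + 1)), cfg, seed=i) for i in range(n)
    ]
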