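"""Shared fixtures: small synthetic cohorts and toy matrices.

Heavier cohort fixtures are session-scoped; everything is seeded so the
suite is fully deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from sersdisc.preprocess import GridSpec, snv_normalize
from sersdisc.synthetic_data import (
    CohortSpec,
    PeakSpec,
    preset_plasma,
    preset_serum,
    simulate_cohort,
)
from sersdisc.types import CONTROL, PATIENT, SpectralDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def plasma_dataset():
    """Default plasma cohort (14 controls / 27 patients), SNV-normalized."""
    return snv_normalize(simulate_cohort(preset_plasma(seed=1)))


@pytest.fixture(scope="session")
def serum_dataset():
    """Default serum cohort (14 controls / 29 patients), SNV-normalized."""
    return snv_normalize(simulate_cohort(preset_serum(seed=1)))


@pytest.fixture
def small_cohort_spec():
    """A fast 3-peak cohort on a short grid for structural tests."""
    return CohortSpec(
        n_control=6,
        n_patient=8,
        specimen="plasma",
        peaks=(
            PeakSpec(center=450.0, base_amplitude=1.0),
            PeakSpec(center=520.0, base_amplitude=0.6, class_effect=1.5),
            PeakSpec(center=600.0, base_amplitude=0.5, class_effect=0.6),
        ),
        grid=GridSpec(400.0, 700.0, 1.0),
        seed=7,
    )


def make_dataset(matrix, labels, grid=None, specimen="plasma"):
    matrix = np.asarray(matrix, dtype=float)
    n, p = matrix.shape
    return SpectralDataset(
        grid=np.arange(p, dtype=float) if grid is None else grid,
        matrix=matrix,
        labels=np.asarray(labels, dtype=object),
        specimen=specimen,
        sample_ids=np.array([f"S{i:02d}" for i in range(n)], dtype=object),
    )


@pytest.fixture
def toy_1d_dataset():
    """Four 1-D samples: controls at −1, −2; patients at +1, +2."""
    return make_dataset(
        np.array([[-1.0], [-2.0], [1.0], [2.0]]),
        [CONTROL, CONTROL, PATIENT, PATIENT],
    )
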