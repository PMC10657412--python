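"""Shared fixtures: synthetic cohorts and a small trained checkpoint.

Everything is generated programmatically at test time; the trained fixture
is session-scoped because several evaluation/survival tests reuse it.
"""

from __future__ import annotations

import numpy as np
import pytest

from tdnode.cohort import Cohort, PatientRecord, split_train_test
from tdnode.config import TrainConfig
from tdnode.simulate import SimConfig, simulate_trial
from tdnode.training import train


@pytest.fixture(scope="session")
def sim_cohort():
    """A 60-patient three-arm synthetic trial with ground truth."""
    cohort, truth = simulate_trial(SimConfig(n_patients=60, seed=7))
    return cohort, truth


@pytest.fixture(scope="session")
def tiny_checkpoint(sim_cohort):
    """A briefly trained reduced-width model on 48 of the 60 patients.

    Long enough to produce informative metrics, short enough for the test
    suite; the split and everything downstream is seed-determined.
    """
    cohort, truth = sim_cohort
    train_c, test_c = split_train_test(cohort, 0.8, seed=5)
    ckpt = train(train_c, TrainConfig.desk(epochs=6, seed=1))
    return ckpt, train_c, test_c, truth


@pytest.fixture()
def toy_records():
    """Hand-sized records with known structure (not simulator output)."""
    rng = np.random.default_rng(3)
    records = []
    for i in range(10):
        times = np.concatenate([[-4.0], np.sort(rng.uniform(3.0, 70.0, size=5))])
        y0 = rng.uniform(30.0, 90.0)
        sld = np.abs(
            y0 * np.exp(-0.01 * np.maximum(times, 0.0))
            * (1.0 + 0.05 * rng.standard_normal(times.size))
        )
        records.append(PatientRecord(f"t{i:02d}", times, sld, arm=f"arm{i % 3 + 1}"))
    return records


@pytest.fixture()
def toy_cohort(toy_records):
    return Cohort(records=toy_records, tag="toy")
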