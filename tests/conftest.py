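import numpy as np
import pytest

from banditref.cohort import CohortConfig, generate_cohort
from banditref.inference import PopulationParams
from banditref.task import SubjectDataset, TrialRecord, default_schedule


def make_dataset(choices, outcomes, subject_id="s0", condition="soothe", block_length=40):
    trials = [
        TrialRecord(
            subject_id=subject_id,
            condition=condition,
            trial_index=t,
            block_index=t // block_length,
            choice="A" if c == 0 else "B",
            outcome=int(o),
        )
        for t, (c, o) in enumerate(zip(choices, outcomes))
    ]
    return SubjectDataset(subject_id, condition, trials)


@pytest.fixture(scope="session")
def small_cohort():
    """20 regular subjects (10 per condition), 200 trials, fixed seed."""
    pop = PopulationParams.from_natural_medians(0.8, 1.3, -0.3, sigma=0.3)
    cfg = CohortConfig(n_subjects_per_condition=10, population=pop, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def schedule():
    return default_schedule()
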