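import numpy as np
import pytest

from fediowa.data_model import ChoiceSequence, LabDataset, split_lab, truncate_pool
from fediowa.synthetic_cohort import canonical_profiles, generate_pool


def make_record(subject_id="s1", lab_id=1, choices=(1, 2, 3, 4), rewards=None, losses=None):
    choices = np.asarray(choices)
    T = len(choices)
    return ChoiceSequence(
        subject_id,
        lab_id,
        choices,
        np.full(T, 100.0) if rewards is None else np.asarray(rewards, float),
        np.zeros(T) if losses is None else np.asarray(losses, float),
    )


def make_lab(lab_id, n, T=10, seed=0):
    rng = np.random.default_rng(seed)
    return LabDataset(
        lab_id=lab_id,
        records=[
            make_record(f"lab{lab_id}_s{i}", lab_id, rng.integers(1, 5, T))
            for i in range(n)
        ],
        native_T=T,
    )


@pytest.fixture(scope="session")
def quarter_pool():
    """Quarter-scale canonical synthetic pool, truncated and split 80/20."""
    pool = truncate_pool(generate_pool(canonical_profiles(0.25), seed=1), 95)
    train_sets, test_sets = [], []
    for i, ds in enumerate(pool):
        tr, te = split_lab(ds, 0.8, seed=i)
        train_sets.append(tr)
        test_sets.append(te)
    return train_sets, test_sets


@pytest.fixture(scope="session")
def cl_quarter_model(quarter_pool):
    """Centralized model trained with the full 250-epoch budget on the
    quarter-scale pool (shared across the behavioral acceptance checks)."""
    from fediowa.collab_training import TrainPlan, train_centralized

    train_sets, _ = quarter_pool
    return train_centralized(train_sets, TrainPlan(paradigm="CL", seed=3))


@pytest.fixture(scope="session")
def tiny_pool():
    """10 labs of 2 subjects, 10 trials each — for schedule/exposure checks."""
    return [make_lab(lab, 2, T=10, seed=lab) for lab in range(1, 11)]
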