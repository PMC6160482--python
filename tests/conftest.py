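import numpy as np
import pytest

from emfspeech import SyntheticConfig, generate_cohort
from emfspeech.data import make_table
from emfspeech.emf import EMFDataset


@pytest.fixture
def tiny_table():
    """One subject, three utterances, two features; feature f1 == valence."""
    return make_table(
        ["s1"] * 6,
        [-1, -1, 0, 0, 1, 1],
        {"f1": [-1.0, -1.0, 0.0, 0.0, 1.0, 1.0], "f2": [0.3, -0.2, 0.1, 0.4, -0.1, 0.2]},
    )


@pytest.fixture
def small_cohort():
    """A small but complete synthetic cohort (fast to analyse end to end)."""
    cfg = SyntheticConfig(
        n_td=10, n_nos=3, n_sli=3, n_ad=3,
        utterances_per_valence=(6, 5, 5),
        n_signal=4, n_nuisance=4,
        seed=7,
    )
    return generate_cohort(cfg)


def random_emf_dataset(rng: np.random.Generator, n0: int = 15, n1: int = 15, n_features: int = 12) -> EMFDataset:
    """Random two-class EMF dataset for DFS/classifier tests."""
    d0 = rng.standard_normal((n0, n_features))
    d1 = rng.standard_normal((n1, n_features)) + rng.normal(0, 1, n_features)
    d = np.vstack([d0, d1])
    labels = np.array([0] * n0 + [3] * n1)
    return EMFDataset(
        D=d,
        Y=(labels > 0).astype(int),
        L=labels,
        subject_ids=tuple(f"s{i}" for i in range(n0 + n1)),
        column_names=tuple(f"b{k}" for k in range(n_features)),
    )
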