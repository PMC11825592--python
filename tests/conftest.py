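import numpy as np
import pytest

from connectocentric import (
    AnalysisConfig,
    CohortSpec,
    ConnectomeCentralityModel,
    RawConnectome,
    generate_cohort,
)


def make_connectome(counts, waytotals=None, labels=None, subject_id="sub-000"):
    counts = np.asarray(counts)
    n = counts.shape[0]
    if labels is None:
        labels = tuple(f"n{i}" for i in range(n))
    if waytotals is None:
        waytotals = counts.sum(axis=1).astype(float)
        waytotals[waytotals == 0] = 1.0
    return RawConnectome(
        subject_id=subject_id,
        labels=tuple(labels),
        counts=counts,
        waytotals=np.asarray(waytotals, dtype=float),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A compact planted-effect cohort reused across model-level tests."""
    spec = CohortSpec(
        n_nodes=30,
        n_group_a=12,
        n_group_b=8,
        n_unlabeled=2,
        degree_effect_d=1.0,
        duration_rho=0.5,
        seed=7,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_model(small_cohort):
    config = AnalysisConfig(n_permutations=2000, seed=11)
    return ConnectomeCentralityModel.from_cohort(small_cohort, config)
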