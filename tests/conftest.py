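import numpy as np
import pytest

from tfmirror.ts_data import StudyCollection


def make_collection(
    n_subjects=3,
    J=4,
    D=1,
    S=0,
    T=12,
    seed=0,
    intervention_onset=5,
    intervention_duration=3,
):
    """Small regular-grid collection with a pulse intervention."""
    rng = np.random.default_rng(seed)
    subjects = [f"S{i + 1}" for i in range(n_subjects)]
    abundances, interventions, covariates, time_grid = {}, {}, {}, {}
    for subj in subjects:
        abundances[subj] = rng.gamma(2.0, 2.0, size=(J, T))
        w = np.zeros((D, T))
        w[:, intervention_onset : intervention_onset + intervention_duration] = 1.0
        interventions[subj] = w
        covariates[subj] = rng.integers(0, 2, size=S).astype(float)
        time_grid[subj] = np.arange(T, dtype=float)
    return StudyCollection(
        subjects=subjects,
        abundances=abundances,
        interventions=interventions,
        covariates=covariates,
        taxa=[f"tax{j + 1}" for j in range(J)],
        intervention_names=[f"w{d + 1}" for d in range(D)],
        covariate_names=[f"z{s + 1}" for s in range(S)],
        time_grid=time_grid,
    )


@pytest.fixture
def small_collection():
    return make_collection()


@pytest.fixture
def covariate_collection():
    return make_collection(n_subjects=4, S=1, seed=1)
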