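import numpy as np
import pandas as pd
import pytest

import hydroadvisor as ha

#: tight search space for fast, deterministic test fits
FAST_SPACE = {
    "max_depth": (4, 6),
    "learning_rate": (0.1, 0.2),
    "n_estimators": (150, 250),
    "subsample": (0.9, 1.0),
}


class AdditiveStub:
    """Stand-in model with a known additive form: a*water + b*weight + c."""

    features = ["plain_water", "weight"]

    def __init__(self, a=-0.1, b=0.5, c=800.0):
        self.a, self.b, self.c = a, b, c

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        return (
            self.a * rows["plain_water"].to_numpy(float)
            + self.b * rows["weight"].to_numpy(float)
            + self.c
        )


@pytest.fixture(scope="session")
def noisefree_params():
    return ha.PhysiologyParams(uosm_noise_sd_log=0.0)


@pytest.fixture(scope="session")
def small_cohort():
    return ha.generate_cohort(ha.CohortSpec(n_participants=120, seed=11))


@pytest.fixture(scope="session")
def small_split(small_cohort):
    filtered, _ = ha.apply_eligibility_filters(small_cohort)
    return ha.split_by_participant(filtered, 0.75, seed=11)


@pytest.fixture(scope="session")
def fitted_model(small_split):
    return ha.fit_surrogate(
        small_split.train_rows,
        ha.DEFAULT_ALLOWED_FEATURES,
        "gbt",
        hyperparameter_space=FAST_SPACE,
        cv_folds=3,
        n_search=3,
        seed=11,
    )


@pytest.fixture
def stub_model():
    return AdditiveStub()
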