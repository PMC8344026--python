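import logging

import numpy as np
import pytest
from hypothesis import settings

from gomprisk import CauseModel, GompertzParams
from gomprisk.cohort import CohortConfig, ContinuousCovariate

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(autouse=True)
def _quiet_logs():
    """Silence expected generator/fit warnings (plateau capping etc.)."""
    logging.getLogger("gomprisk").setLevel(logging.ERROR)
    yield
    logging.getLogger("gomprisk").setLevel(logging.NOTSET)


def recovery_truth():
    """The standard parameter-recovery ground truth: one standard-normal
    covariate with opposite effects on the two causes, ~4-year censoring."""
    cm1 = CauseModel(GompertzParams(theta=1.2, gamma=-0.4, lam=0.25),
                     ("x",), np.array([0.5]))
    cm2 = CauseModel(GompertzParams(theta=1.0, gamma=-0.6, lam=0.15),
                     ("x",), np.array([-0.3]))
    return cm1, cm2


def recovery_config(n: int, seed: int) -> CohortConfig:
    cm1, cm2 = recovery_truth()
    return CohortConfig(n=n, covariates=(ContinuousCovariate("x", 0.0, 1.0),),
                        cause1=cm1, cause2=cm2, study_years=4.0, seed=seed)


RECOVERY_TRUTH_VECTOR = {
    "cause1:log_theta": np.log(1.2), "cause1:gamma": -0.4,
    "cause1:log_lam": np.log(0.25), "cause1:x": 0.5,
    "cause2:log_theta": 0.0, "cause2:gamma": -0.6,
    "cause2:log_lam": np.log(0.15), "cause2:x": -0.3,
}
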