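import numpy as np
import pytest

import crmkit as ck


@pytest.fixture(scope="session")
def design() -> ck.DesignSpec:
    """The final calibrated five-level design (delta=0.06, sigma=0.265)."""
    return ck.default_design()


@pytest.fixture(scope="session")
def cal() -> ck.CalibrationSpec:
    return ck.CalibrationSpec(delta=0.06, target_theta=0.35, nu=3, K=5)


@pytest.fixture(scope="session")
def skeleton(cal) -> tuple[float, ...]:
    return ck.build_skeleton(cal)


def random_history(rng: np.random.Generator, max_cohorts: int = 7) -> ck.ToxicityHistory:
    """A random complete-cohort history over 5 levels (not engine-constrained)."""
    n_cohorts = int(rng.integers(0, max_cohorts + 1))
    cohorts = [
        (int(rng.integers(1, 6)), int(rng.integers(0, 4))) for _ in range(n_cohorts)
    ]
    return ck.ToxicityHistory.from_cohorts(cohorts)
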