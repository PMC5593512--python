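import numpy as np
import pytest

from banditfit.task import (CohortSpec, WalkConfig, generate_cohort,
                            generate_random_walks, simulate_agent)

WINNING_PARAMS = {"beta": 12.0, "omega": 0.4, "lambda": 0.2,
                  "upsilon": -1.0, "kappa": 0.26}


@pytest.fixture(scope="session")
def walks():
    return generate_random_walks(WalkConfig(seed=7))


@pytest.fixture(scope="session")
def sim_subject(walks):
    """One agent simulated under the five-parameter Bayesian observer."""
    return simulate_agent(walks, "bayes_full", WINNING_PARAMS, seed=11,
                          subject_id="simA")


@pytest.fixture(scope="session")
def rw_cohort():
    """Small RW cohort for fitting tests (6 subjects x 120 trials)."""
    cohort = CohortSpec(n_subjects=6, model="rw", seed=21)
    walk = WalkConfig(n_trials=120, seed=22)
    return generate_cohort(cohort, walk)
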