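import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import ineqddm as iq

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

#: Reduced sampler settings for unit tests (full defaults are exercised in
#: the acceptance suite).
FAST = dict(chains=2, burn_in=400, draws=400)

TABLE2_PARAMS = iq.DDMParams(
    alpha=2.16, z=0.543, tau=0.591, betas={"sr": -0.93, "di": 0.371, "ai": 0.254}
)


@pytest.fixture(scope="session")
def table2_params():
    return TABLE2_PARAMS


@pytest.fixture(scope="session")
def offers56():
    return iq.task.offers_to_frame(iq.generate_offer_set(3))


@pytest.fixture(scope="session")
def sim_participant(offers56, table2_params):
    """One simulated participant at the population-mean parameters."""
    return iq.simulate_dataset(iq.BEST_SPEC, table2_params, offers56, seed=7)


@pytest.fixture(scope="session")
def fitted_participant(sim_participant):
    """Full-settings posterior fit of the simulated participant."""
    return iq.sample_posterior(
        sim_participant, iq.BEST_SPEC, chains=4, burn_in=2000, draws=2000, seed=1
    )


@pytest.fixture(scope="session")
def cohort63():
    """Synthetic cohort at the default population anchors (63 participants)."""
    return iq.make_cohort(iq.CohortConfig(seed=0))


@pytest.fixture()
def tiny_trials():
    """Hand-built 6-trial table covering accept/reject/timeout."""
    return pd.DataFrame(
        {
            "participant_id": ["p1"] * 6,
            "trial_index": range(6),
            "condition": ["1/9", "1/9", "1/1", "1/1", "7/3", "2/3"],
            "sr_yen": [50, 55, 250, 245, 350, 200],
            "or_yen": [450, 445, 250, 255, 150, 300],
            "choice": ["reject", "accept", "accept", "accept", "accept", "timeout"],
            "rt_s": [1.2, 2.4, 0.9, 1.1, 0.8, np.nan],
            "valid": [True, True, True, True, True, False],
        }
    )
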