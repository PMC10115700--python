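import numpy as np
import pytest

import cdmkit as ck

# Seed fixed a priori for the recovery-scale simulation used across tests.
RECOVERY_SEED = 20260929


@pytest.fixture(scope="session")
def scenario():
    return ck.mental_health_scenario(seed=RECOVERY_SEED)


@pytest.fixture(scope="session")
def recovery(scenario):
    """One recovery-scale simulated data set (N=3000) with its saturated fit."""
    responses, profiles = ck.simulate_scenario(scenario, N=3000)
    fitted = ck.fit_cdm(responses, scenario.Q, structural="saturated", seed=1)
    return scenario, responses, profiles, fitted


@pytest.fixture(scope="session")
def small_fit():
    """A quick K=2 saturated fit used by tests that only need a converged model."""
    rng = np.random.default_rng(5)
    Q = ck.QMatrix(entries=np.array([[1, 0], [1, 0], [1, 0], [0, 1], [0, 1], [0, 1]]))
    items = [
        ck.ItemParameterSet(model_label="GDINA", qvector=Q.qvector(j),
                            probs=np.array([0.15, 0.8]), item_id=Q.item_ids[j])
        for j in range(Q.J)
    ]
    joint = ck.LatentClassDistribution(probs=np.array([0.35, 0.2, 0.15, 0.3]))
    prof = ck.simulate_profiles(800, joint, seed=rng.integers(2**31))
    resp = ck.simulate_responses(prof, items, seed=rng.integers(2**31))
    resp.item_ids = Q.item_ids
    fitted = ck.fit_cdm(resp, Q, structural="saturated", seed=3)
    return Q, items, joint, prof, resp, fitted
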