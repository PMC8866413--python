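import numpy as np
import pandas as pd
import pytest

import coxrisk as cr


@pytest.fixture(scope="session")
def chd_config():
    return cr.default_config("CHD", n_individuals=20_000, seed=7)


@pytest.fixture(scope="session")
def chd_cohort(chd_config):
    return cr.generate_cohort(chd_config)


@pytest.fixture(scope="session")
def chd_eligible(chd_cohort):
    tiers = cr.predictor_tiers("CHD")
    spec = cr.chd_eligibility(require_complete=tiers["genomic_plus"])
    cohort, _ = cr.apply_eligibility(chd_cohort, spec)
    return cohort


@pytest.fixture(scope="session")
def chd_models(chd_eligible):
    tiers = cr.predictor_tiers("CHD")
    return cr.fit_risk_model(
        chd_eligible, tiers["genomic"], horizon=10.0, disease="CHD"
    )


@pytest.fixture
def toy_scores():
    """Small two-model risk comparison with a hand-checkable layout."""
    rng = np.random.default_rng(5)
    n = 400
    event = (rng.random(n) < 0.3).astype(float)
    old = np.clip(0.05 + 0.10 * event + 0.04 * rng.standard_normal(n), 0.001, 0.999)
    new = np.clip(old + 0.03 * event - 0.01 + 0.02 * rng.standard_normal(n),
                  0.001, 0.999)
    return old, new, event


def brute_force_auc(scores, event):
    """O(n^2) pair-count AUC with ties counted one half (oracle)."""
    scores = np.asarray(scores, dtype=float)
    case = scores[np.asarray(event, dtype=float) == 1.0]
    non = scores[np.asarray(event, dtype=float) != 1.0]
    total = 0.0
    for c in case:
        for x in non:
            total += 1.0 if c > x else (0.5 if c == x else 0.0)
    return total / (len(case) * len(non))
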