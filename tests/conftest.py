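import numpy as np
import pandas as pd
import pytest

from icibench import TrialDataset, effect_scenarios, simulate_trial


def make_clinical(n, rng=None, arm=None):
    """Small handmade clinical table satisfying all dataset invariants."""
    rng = rng or np.random.default_rng(0)
    if arm is None:
        arm = np.where(np.arange(n) % 2 == 0, "ICI", "CHEMO")
    return pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(n)],
        "arm": arm,
        "sex": rng.choice(["male", "female"], n),
        "histology": rng.choice(["squamous", "nonsquamous"], n),
        "smoking": rng.choice(["ever", "never"], n),
        "ecog": rng.integers(0, 2, n),
        "tmb": rng.integers(10, 500, n).astype(float),
        "pdl1": rng.uniform(0, 100, n),
        "pfs_time": rng.uniform(0.5, 24, n),
        "pfs_event": rng.integers(0, 2, n),
        "os_time": rng.uniform(0.5, 36, n),
        "os_event": rng.integers(0, 2, n),
        "bor_pd": rng.integers(0, 2, n).astype(float),
    })


@pytest.fixture
def toy_dataset():
    """6-patient two-arm trial without expression."""
    return TrialDataset(make_clinical(6))


@pytest.fixture
def toy_expression_dataset():
    rng = np.random.default_rng(1)
    clin = make_clinical(8, rng)
    expr = pd.DataFrame(rng.standard_normal((12, 8)),
                        index=[f"G{i}" for i in range(12)],
                        columns=clin["patient_id"].tolist())
    return TrialDataset(clin, expr)


@pytest.fixture(scope="session")
def predictive_trial():
    """Mid-size trial with a predictive TMB effect (interaction only)."""
    cfg = effect_scenarios(seed=42, n_patients=300)["predictive_only"]
    return simulate_trial(cfg)


@pytest.fixture(scope="session")
def null_trial():
    cfg = effect_scenarios(seed=42, n_patients=300)["null"]
    return simulate_trial(cfg)
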