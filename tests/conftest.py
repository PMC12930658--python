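import numpy as np
import pandas as pd
import pytest

from memtraj.simulate import SimulationConfig, simulate_cohort


def small_config(seed: int = 0, **kw) -> SimulationConfig:
    """Small but structurally complete cohort for fast unit tests."""
    defaults = dict(n_preclinical_f=20, n_preclinical_m=18, n_mci_f=26,
                    n_mci_m=36, n_robust_controls=120,
                    visits_per_participant=4, seed=seed)
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_config(seed=11))


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size default cohort (78/73/104/146 + controls, 5 visits)."""
    return simulate_cohort(SimulationConfig(seed=7))


def make_controls(n=400, seed=0, beta_age=-0.2, beta_educ=2.0, beta_male=1.0,
                  noise_sd=3.0, base=50.0, test="ravlt_learning"):
    """Hand-built control baselines with known normative structure."""
    rng = np.random.default_rng(seed)
    age = rng.uniform(60, 85, n)
    educ = rng.integers(10, 21, n).astype(float)
    male = rng.integers(0, 2, n)
    score = (base + beta_age * age + beta_educ * educ + beta_male * male
             + rng.normal(0, noise_sd, n))
    return pd.DataFrame({
        "participant_id": np.arange(n),
        "visit_index": 0,
        "age_at_visit": age,
        "sex": np.where(male == 1, "male", "female"),
        "education": educ,
        test: score,
    })
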