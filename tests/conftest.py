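import numpy as np
import pandas as pd
import pytest

from elab import taskgen


@pytest.fixture(scope="session")
def small_cohort():
    """Mixed-class cohort of 10 participants (trials + SVs, no signals)."""
    cfg = taskgen.StudyConfig(n_participants=10, rng_seed=101)
    return taskgen.generate_cohort(cfg)


@pytest.fixture(scope="session")
def threat_trials(small_cohort):
    trials = small_cohort["trials"]
    return trials[trials["trial_type"] == "threat"].reset_index(drop=True)


def make_logistic_trials(
    n_participants: int,
    beta0: float,
    beta_cond: float,
    sd0: float = 0.3,
    sd_cond: float = 0.0,
    n_per_cond: int = 32,
    seed: int = 0,
) -> pd.DataFrame:
    """Trial table from a two-condition hierarchical logistic model."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_participants):
        b0 = rng.normal(0.0, sd0)
        b1 = rng.normal(0.0, sd_cond)
        for cond, c in [("unpredictable", 0.0), ("predictable", 1.0)]:
            eta = beta0 + b0 + (beta_cond + b1) * c
            y = rng.uniform(size=n_per_cond) < 1.0 / (1.0 + np.exp(-eta))
            for k in range(n_per_cond):
                rows.append(
                    {
                        "participant_id": f"s{i:03d}",
                        "condition": cond,
                        "trial_type": "threat",
                        "rt_s": float(rng.lognormal(-0.5, 0.3)),
                        "response": "avoid" if y[k] else "approach",
                    }
                )
    return pd.DataFrame(rows)
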