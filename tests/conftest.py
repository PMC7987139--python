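import numpy as np
import pandas as pd
import pytest

from screenrisk import CohortTable, build_stacked, default_config, fit_pc_cox, simulate_cohort


@pytest.fixture(scope="session")
def cfg20():
    """Default study conditions at a 20,000-woman desk scale."""
    return default_config(n_women=20_000, seed=1)


@pytest.fixture(scope="session")
def sim20(cfg20):
    return simulate_cohort(cfg20)


@pytest.fixture(scope="session")
def stacked20(sim20):
    return build_stacked(sim20.cohort)


@pytest.fixture(scope="session")
def fit20(stacked20):
    return fit_pc_cox(stacked20)


@pytest.fixture(scope="session")
def null_sim():
    """Constant-hazard cohort: all effects zero, lambda = 2.183/1,000 wy."""
    cfg = default_config(n_women=20_000, seed=3)
    cfg = cfg.replace(
        true_log_hr={k: 0.0 for k in cfg.true_log_hr}, baseline_hazard=0.002183
    )
    return cfg, simulate_cohort(cfg)


@pytest.fixture()
def toy_cohort():
    """Hand-built six-woman cohort with every exclusion-free feature used in
    hand tallies: two events, varied covariates, biennial visits."""
    visits = pd.DataFrame(
        [
            # woman 0: two visits, censored (end = 2 + 2)
            ("w0", 0.0, 50.0, 0, "none", "none"),
            ("w0", 2.0, 52.0, 0, "none", "mass"),
            # woman 1: three visits, event at t=5
            ("w1", 0.0, 55.0, 1, "none", "none"),
            ("w1", 2.0, 57.0, 1, "prior_biopsy_unknown", "none"),
            ("w1", 4.0, 59.0, 1, "prior_biopsy_unknown", "calcifications"),
            # woman 2: single visit, censored
            ("w2", 0.0, 61.0, 0, "non_proliferative", "none"),
            # woman 3: single visit, event at t=0.5
            ("w3", 0.0, 66.0, 0, "none", "none"),
            # woman 4: two visits, censored
            ("w4", 0.0, 52.5, 0, "none", "asymmetry"),
            ("w4", 2.0, 54.5, 0, "none", "asymmetry"),
            # woman 5: censored, proliferative BBD
            ("w5", 0.0, 58.0, 1, "proliferative", "none"),
        ],
        columns=[
            "woman_id",
            "visit_time",
            "age_at_visit",
            "family_history",
            "bbd_category",
            "mammo_feature",
        ],
    )
    outcomes = pd.DataFrame(
        {
            "woman_id": ["w0", "w1", "w2", "w3", "w4", "w5"],
            "event": [0, 1, 0, 1, 0, 0],
            "end_time": [4.0, 5.0, 2.0, 0.5, 4.0, 2.0],
        }
    )
    return CohortTable(visits, outcomes)


def stacked_frame(woman_id, landmark, age, fh, bbd, feat, rtime, event):
    """Assemble a stacked-record frame from parallel lists (test helper)."""
    return pd.DataFrame(
        {
            "woman_id": woman_id,
            "landmark_time": landmark,
            "age_at_visit": age,
            "family_history": fh,
            "bbd_category": bbd,
            "mammo_feature": feat,
            "residual_time": rtime,
            "event": event,
        }
    )
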