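import numpy as np
import pandas as pd
import pytest

import peerbayes as pb

M3D_PARAMS = {
    "alpha_uncertain": 20.0,
    "alpha_certain": 5.0,
    "theta_ic": 10.0,
    "theta_slope": 50.0,
    "beta": 0.6,
}


@pytest.fixture(scope="session")
def m3d_params():
    return dict(M3D_PARAMS)


@pytest.fixture(scope="session")
def exp2_design():
    return pb.generate_design(2, seed=0)


@pytest.fixture(scope="session")
def m3d_session(exp2_design, m3d_params):
    """One simulated experiment-2 session of an M3d agent."""
    return pb.simulate_participant(exp2_design, "M3d", m3d_params, seed=1)


@pytest.fixture(scope="session")
def m3d_cohort():
    """Small filtered cohort of M3d agents with heterogeneous parameters."""
    params_list = pb.sample_parameters("M3d", None, 12, seed=5)
    df = pb.simulate_cohort(2, "M3d", params_list, seed=6)
    df = pb.apply_trial_filters(df)
    retained, _ = pb.apply_participant_filters(df)
    return retained


def make_manual_trials(
    n_per_participant=24, n_participants=6, s_mean=0.4, s_sd=0.1, seed=0,
    condition_effect=0.0, confidence_effect=0.0,
):
    """Build trial tables with exactly controlled social-information-use values.

    E2 is constructed from a chosen s via e2 = e1 + s * (p - e1), so the
    regression's data-generating effects are known by construction.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for pid in range(n_participants):
        for i in range(n_per_participant):
            condition = ("uncertain", "certain")[i % 2]
            conf = (i // 2) % 3 + 1
            certainty_code = 0.5 if condition == "certain" else -0.5
            s = (
                s_mean
                + condition_effect * certainty_code
                + confidence_effect * (conf - 2)
                + rng.normal(0, s_sd)
            )
            e1 = float(rng.integers(20, 70))
            p = e1 + 16.0
            e2 = e1 + s * (p - e1)
            rows.append(
                {
                    "participant": pid,
                    "run": i % 3 + 1,
                    "trial_index": i,
                    "condition": condition,
                    "n_shown": 5 if condition == "uncertain" else 45,
                    "peer_confidence": conf,
                    "true_pct": 50.0,
                    "is_filler": False,
                    "missed": False,
                    "e1": e1,
                    "p": p,
                    "e2": e2,
                }
            )
    return pd.DataFrame(rows)
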