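"""Unit and property tests for the beta-count model family."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import peerbayes as pb
from peerbayes.models import (
    MODELS,
    RESPONSE_GRID,
    response_distribution,
)

M2B_PARAMS = {
    "alpha_uncertain": 20.0,
    "alpha_certain": 5.0,
    "theta_ic": 10.0,
    "theta_slope": 50.0,
}


def one_trial(e1=40, p=56, e2=48, condition="uncertain", conf=2, filler=False):
    return pd.Series(
        {
            "condition": condition,
            "n_shown": 5 if condition == "uncertain" else 45,
            "peer_confidence": conf,
            "e1": e1,
            "p": p,
            "e2": e2,
            "is_filler": filler,
            "true_pct": 50.0,
        }
    )


class TestStructure:
    def test_parameter_counts(self):
        expected = {
            "M0": 0, "M1a": 1, "M1b": 2, "M2a": 3, "M2b": 4,
            "M2c": 5, "M3a": 5, "M3b": 6, "M3c": 5, "M3d": 5,
        }
        assert {name: spec.n_params for name, spec in MODELS.items()} == expected

    def test_bounds(self):
        b = MODELS["M3d"].bounds_dict()
        assert b["alpha_uncertain"] == (0.1, 100.0)
        assert b["theta_ic"] == (0.1, 500.0)
        assert b["beta"] == (0.01, 0.99)
        assert MODELS["M2a"].bounds_dict()["theta"] == (0.1, 1000.0)
        assert MODELS["M2c"].bounds_dict()["theta_high"] == (0.1, 1000.0)

    def test_unknown_model_rejected(self):
        with pytest.raises(KeyError):
            pb.get_model("M9")

    def test_out_of_bounds_params_rejected(self):
        with pytest.raises(ValueError):
            pb.models.validate_params("M1a", {"alpha": 200.0})


class TestCountUpdating:
    def test_worked_example_blue_count(self):
        # 45 mushrooms shown, first estimate 20% -> 1 + 0.2*45 = 10 blue
        counts = pb.e1_counts(20, 45)
        assert counts.blue == 10.0
        assert counts.red == 37.0

    def test_zero_perceived_count_gives_unit_prior(self):
        counts = pb.e1_counts(50, 0)
        assert (counts.blue, counts.red) == (1.0, 1.0)

    @pytest.mark.parametrize(
        "model,condition,n,expected",
        [
            ("M0", "certain", 45, 45.0),
            ("M1b", "uncertain", 5, 140.0),  # alpha_uncertain = 28
            ("M1b", "certain", 45, 180.0),  # alpha_certain = 4
        ],
    )
    def test_perceived_n(self, model, condition, n, expected):
        params = {"alpha_uncertain": 28.0, "alpha_certain": 4.0}
        assert pb.perceived_n(model, params, condition, n) == expected

    def test_m1a_alpha_one_equals_m0(self):
        for n in (5, 45):
            for cond in ("uncertain", "certain"):
                assert pb.perceived_n("M1a", {"alpha": 1.0}, cond, n) == pb.perceived_n(
                    "M0", {}, cond, n
                )

    @pytest.mark.parametrize(
        "model,params,conf,expected",
        [
            ("M0", {}, 1, 25.0),
            ("M0", {}, 3, 25.0),
            ("M2b", {"theta_ic": 10.0, "theta_slope": 5.0}, 2, 15.0),
            ("M2b", {"theta_ic": 10.0, "theta_slope": 5.0}, 1, 10.0),
            ("M2c", {"theta_low": 7.0, "theta_medium": 8.0, "theta_high": 9.0}, 3, 9.0),
        ],
    )
    def test_peer_n(self, model, params, conf, expected):
        assert pb.peer_n(model, params, conf) == expected

    def test_posterior_additivity(self):
        post = pb.posterior_counts(pb.BeliefCounts(10, 37), p=60, n_peer=25)
        assert (post.blue, post.red) == (25.0, 47.0)

    def test_posterior_count_conservation(self):
        e1c = pb.e1_counts(35, 140)
        post = pb.posterior_counts(e1c, p=80, n_peer=55)
        assert post.total == pytest.approx(e1c.total + 55)

    def test_zero_peer_count_leaves_prior(self):
        e1c = pb.e1_counts(35, 140)
        post = pb.posterior_counts(e1c, p=80, n_peer=0)
        assert (post.blue, post.red) == (e1c.blue, e1c.red)


class TestResponsePMF:
    def test_flat_beta_uniform(self):
        pmf = pb.response_pmf(pb.BeliefCounts(1, 1))
        assert np.allclose(pmf, 1 / 101)

    def test_linear_density(self):
        pmf = pb.response_pmf(pb.BeliefCounts(2, 1))
        assert np.allclose(pmf, RESPONSE_GRID / RESPONSE_GRID.sum())

    @given(
        blue=st.floats(1.5, 300), red=st.floats(1.5, 300)
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_mode_matches_closed_form(self, blue, red):
        pmf = pb.response_pmf(pb.BeliefCounts(blue, red))
        mode = 100 * (blue - 1) / (blue + red - 2)
        assert abs(int(np.argmax(pmf)) - mode) <= 1

    @pytest.mark.parametrize("model", list(MODELS))
    def test_mixture_rows_normalised_across_lattice(self, model, m3d_session):
        spec = MODELS[model]
        lattice = {
            "alpha": 3.0, "alpha_uncertain": 50.0, "alpha_certain": 0.5,
            "theta": 400.0, "theta_ic": 0.1, "theta_slope": 200.0,
            "theta_low": 1.0, "theta_medium": 30.0, "theta_high": 900.0,
            "beta": 0.7, "beta_uncertain": 0.05, "beta_certain": 0.95,
        }
        params = {name: lattice[name] for name in spec.param_names}
        mix = response_distribution(m3d_session, spec, params)
        assert np.all(mix >= 0)
        assert np.allclose(mix.sum(axis=1), 1.0, atol=1e-9)


class TestStayBias:
    @pytest.mark.parametrize(
        "model,params,conf,cond,expected",
        [
            ("M3a", {"beta": 0.4}, 3, "certain", 0.4),
            ("M3b", {"beta_uncertain": 0.3, "beta_certain": 0.7}, 1, "uncertain", 0.3),
            ("M3b", {"beta_uncertain": 0.3, "beta_certain": 0.7}, 1, "certain", 0.7),
            ("M3c", {"beta": 0.6}, 3, "uncertain", 0.2),
            ("M3d", {"beta": 0.5}, 1, "uncertain", 0.5),
            ("M3d", {"beta": 0.5}, 3, "uncertain", 0.125),
        ],
    )
    def test_stay_weight_forms(self, model, params, conf, cond, expected):
        assert pb.stay_weight(model, params, conf, cond) == pytest.approx(expected)

    def test_stay_weight_rejected_without_stay_mode(self):
        with pytest.raises(ValueError):
            pb.stay_weight("M2b", M2B_PARAMS, 2, "certain")


class TestTrialLikelihood:
    def test_no_stay_model_equals_pmf_entry(self):
        trial = one_trial()
        n_perc = pb.perceived_n("M2b", M2B_PARAMS, trial["condition"], trial["n_shown"])
        n_peer = pb.peer_n("M2b", M2B_PARAMS, trial["peer_confidence"])
        post = pb.posterior_counts(pb.e1_counts(trial["e1"], n_perc), trial["p"], n_peer)
        q = pb.response_pmf(post)
        assert pb.trial_likelihood(trial, "M2b", M2B_PARAMS) == pytest.approx(
            q[trial["e2"]], rel=1e-9
        )

    def test_strong_stay_bias_lower_bound(self):
        trial = one_trial(e2=40, conf=1)
        params = {**M2B_PARAMS, "beta": 0.99}
        assert pb.trial_likelihood(trial, "M3d", params) >= 0.99

    @pytest.mark.parametrize("model", ["M0", "M2b", "M3c", "M3d"])
    def test_enumeration_sums_to_one(self, model):
        params = {**M2B_PARAMS, "beta": 0.5}
        params = {k: params[k] for k in MODELS[model].param_names}
        total = sum(
            pb.trial_likelihood(one_trial(e2=k), model, params) for k in range(101)
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_nll_additivity(self, m3d_session, m3d_params):
        half1 = m3d_session.iloc[:30]
        half2 = m3d_session.iloc[30:]
        total = pb.participant_nll(m3d_session, "M3d", m3d_params)
        assert total == pytest.approx(
            pb.participant_nll(half1, "M3d", m3d_params)
            + pb.participant_nll(half2, "M3d", m3d_params),
            rel=1e-12,
        )

    def test_single_trial_nll(self):
        trial = one_trial()
        df = trial.to_frame().T
        nll = pb.participant_nll(df, "M2b", M2B_PARAMS)
        assert nll == pytest.approx(
            -math.log(pb.trial_likelihood(trial, "M2b", M2B_PARAMS)), rel=1e-12
        )


class TestNesting:
    def test_m0_equals_m1a_at_unit_alpha(self, m3d_session):
        nll0 = pb.participant_nll(m3d_session, "M0", {})
        nll1 = pb.participant_nll(m3d_session, "M1a", {"alpha": 1.0})
        assert nll0 == pytest.approx(nll1, abs=1e-9)

    def test_m1a_equals_m1b_at_shared_alpha(self, m3d_session):
        nll_a = pb.participant_nll(m3d_session, "M1a", {"alpha": 7.0})
        nll_b = pb.participant_nll(
            m3d_session, "M1b", {"alpha_uncertain": 7.0, "alpha_certain": 7.0}
        )
        assert nll_a == pytest.approx(nll_b, abs=1e-9)

    def test_m3a_equals_m3b_at_shared_beta(self, m3d_session):
        p3a = {**M2B_PARAMS, "beta": 0.4}
        p3b = {**M2B_PARAMS, "beta_uncertain": 0.4, "beta_certain": 0.4}
        assert pb.participant_nll(m3d_session, "M3a", p3a) == pytest.approx(
            pb.participant_nll(m3d_session, "M3b", p3b), abs=1e-9
        )

    def test_m2b_at_floor_slope_approaches_m2a(self, m3d_session):
        # theta_slope at its lower bound adds at most 0.2 peer mushrooms
        p2b = {"alpha_uncertain": 20.0, "alpha_certain": 5.0, "theta_ic": 40.0,
               "theta_slope": 0.1}
        p2a = {"alpha_uncertain": 20.0, "alpha_certain": 5.0, "theta": 40.0}
        nll_b = pb.participant_nll(m3d_session, "M2b", p2b)
        nll_a = pb.participant_nll(m3d_session, "M2a", p2a)
        assert nll_b == pytest.approx(nll_a, rel=0.02)

    def test_m3d_small_beta_per_trial_limit(self, m3d_session):
        """With beta -> 0.01 the stay mixture perturbs each trial by <= beta."""
        beta = 0.01
        p3d = {**M2B_PARAMS, "beta": beta}
        nonfiller = m3d_session[~m3d_session["is_filler"]]
        for _, trial in nonfiller.head(20).iterrows():
            l3d = pb.trial_likelihood(trial, "M3d", p3d)
            l2b = pb.trial_likelihood(trial, "M2b", M2B_PARAMS)
            assert abs(l3d - l2b) <= beta + 1e-12


class TestAdviceWeight:
    def test_posterior_mean_weight_monotonic(self):
        """Pure Bayesian weight on advice rises with n_peer, falls with own n."""
        e1, p = 40, 56

        def predicted_s(n_perc, n_peer):
            post = pb.posterior_counts(pb.e1_counts(e1, n_perc), p, n_peer)
            prior = pb.e1_counts(e1, n_perc)
            post_mean = 100 * post.blue / post.total
            prior_mean = 100 * prior.blue / prior.total
            return (post_mean - prior_mean) / (p - prior_mean)

        lattice = [1.0, 5.0, 25.0, 125.0]
        for n_perc in lattice:
            s_vals = [predicted_s(n_perc, n_peer) for n_peer in lattice]
            assert all(np.diff(s_vals) > 0)
        for n_peer in lattice:
            s_vals = [predicted_s(n_perc, n_peer) for n_perc in lattice]
            assert all(np.diff(s_vals) < 0)

    def test_weight_closed_form(self):
        """Posterior-mean weight equals n_peer / (n_peer + n_perc + 2) when the
        prior mean equals E1 (unit-prior correction vanishes)."""
        e1, p, n_perc, n_peer = 50, 66, 30.0, 20.0
        prior = pb.e1_counts(e1, n_perc)
        post = pb.posterior_counts(prior, p, n_peer)
        s_pred = (100 * post.blue / post.total - e1) / (p - e1)
        assert s_pred == pytest.approx(n_peer / (n_peer + n_perc + 2), rel=1e-9)
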