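"""Beta-count Bayesian models of social belief updating.

A participant first estimates the percentage of blue mushrooms from ``N``
observed mushrooms (their first estimate E1), then sees a peer's estimate P
with a confidence rating, and may revise to a second estimate E2.  Each model
treats beliefs as beta distributions over the unknown percentage, built from
pseudo-counts: a unit prior (1 blue + 1 red) plus the mushrooms effectively
contributed by each information source.

The family M0–M3d varies three structural switches:

* ``alpha_mode`` — how the participant's own observation count N is distorted
  into a perceived count (none, a single multiplier alpha, or one multiplier
  per certainty condition);
* ``theta_mode`` — how many mushrooms the peer is assumed to have seen
  (fixed at 25, a free theta, a linear function of peer confidence, or one
  free value per confidence level);
* ``stay_mode`` — an extra non-Bayesian probability mass on repeating E1
  (none, constant beta, one beta per certainty condition, beta divided by the
  confidence level, or beta raised to the confidence level).

The response likelihood is discrete: the posterior beta density is evaluated
on the 101 admissible slider responses 0, 1, ..., 100 % and renormalised, so
that the stay-bias mixture is a proper distribution over responses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import logsumexp, xlog1py, xlogy

__all__ = [
    "MODELS",
    "BeliefCounts",
    "ModelSpec",
    "get_model",
    "perceived_n",
    "e1_counts",
    "peer_n",
    "posterior_counts",
    "response_pmf",
    "stay_weight",
    "trial_likelihood",
    "participant_nll",
    "response_distribution",
    "prepare_trials",
    "nll_prepared",
    "validate_params",
]

#: slider responses k/100 for k = 0..100
RESPONSE_GRID = np.linspace(0.0, 1.0, 101)

#: floor applied to any single-trial likelihood before taking logs
LIKELIHOOD_FLOOR = 1e-12

#: peer observation count assumed by the base model (average of 5 and 45)
DEFAULT_N_PEER = 25.0

UNCERTAIN, CERTAIN = "uncertain", "certain"


@dataclass(frozen=True)
class BeliefCounts:
    """Pseudo-counts of a beta belief; both shapes stay >= 1 (unit prior)."""

    blue: float
    red: float

    @property
    def total(self) -> float:
        return self.blue + self.red


@dataclass(frozen=True)
class ModelSpec:
    """Structural description of one model in the family."""

    name: str
    param_names: tuple[str, ...]
    bounds: tuple[tuple[float, float], ...]
    alpha_mode: str  # none | single | dual
    theta_mode: str  # fixed25 | single | linear | per_level
    stay_mode: str  # none | constant | dual_condition | inverse_conf | power_conf

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def bounds_dict(self) -> dict[str, tuple[float, float]]:
        return dict(zip(self.param_names, self.bounds))


_A = (0.1, 100.0)  # alpha bounds
_T = (0.1, 1000.0)  # free theta bounds (M2a, M2c)
_TL = (0.1, 500.0)  # theta intercept / slope bounds (M2b and descendants)
_B = (0.01, 0.99)  # stay-bias bounds

MODELS: dict[str, ModelSpec] = {
    "M0": ModelSpec("M0", (), (), "none", "fixed25", "none"),
    "M1a": ModelSpec("M1a", ("alpha",), (_A,), "single", "fixed25", "none"),
    "M1b": ModelSpec(
        "M1b", ("alpha_uncertain", "alpha_certain"), (_A, _A), "dual", "fixed25", "none"
    ),
    "M2a": ModelSpec(
        "M2a",
        ("alpha_uncertain", "alpha_certain", "theta"),
        (_A, _A, _T),
        "dual",
        "single",
        "none",
    ),
    "M2b": ModelSpec(
        "M2b",
        ("alpha_uncertain", "alpha_certain", "theta_ic", "theta_slope"),
        (_A, _A, _TL, _TL),
        "dual",
        "linear",
        "none",
    ),
    "M2c": ModelSpec(
        "M2c",
        ("alpha_uncertain", "alpha_certain", "theta_low", "theta_medium", "theta_high"),
        (_A, _A, _T, _T, _T),
        "dual",
        "per_level",
        "none",
    ),
    "M3a": ModelSpec(
        "M3a",
        ("alpha_uncertain", "alpha_certain", "theta_ic", "theta_slope", "beta"),
        (_A, _A, _TL, _TL, _B),
        "dual",
        "linear",
        "constant",
    ),
    "M3b": ModelSpec(
        "M3b",
        (
            "alpha_uncertain",
            "alpha_certain",
            "theta_ic",
            "theta_slope",
            "beta_uncertain",
            "beta_certain",
        ),
        (_A, _A, _TL, _TL, _B, _B),
        "dual",
        "linear",
        "dual_condition",
    ),
    "M3c": ModelSpec(
        "M3c",
        ("alpha_uncertain", "alpha_certain", "theta_ic", "theta_slope", "beta"),
        (_A, _A, _TL, _TL, _B),
        "dual",
        "linear",
        "inverse_conf",
    ),
    "M3d": ModelSpec(
        "M3d",
        ("alpha_uncertain", "alpha_certain", "theta_ic", "theta_slope", "beta"),
        (_A, _A, _TL, _TL, _B),
        "dual",
        "linear",
        "power_conf",
    ),
}


def get_model(name: str | ModelSpec) -> ModelSpec:
    if isinstance(name, ModelSpec):
        return name
    try:
        return MODELS[name]
    except KeyError:
        raise KeyError(f"unknown model {name!r}; choose from {sorted(MODELS)}") from None


def validate_params(model: str | ModelSpec, params: Mapping[str, float]) -> None:
    """Raise ValueError if ``params`` misses a parameter or leaves its bounds."""
    spec = get_model(model)
    for name, (lo, hi) in zip(spec.param_names, spec.bounds):
        if name not in params:
            raise ValueError(f"{spec.name}: missing parameter {name!r}")
        v = float(params[name])
        if not (lo <= v <= hi):
            raise ValueError(f"{spec.name}: {name}={v} outside bounds [{lo}, {hi}]")


# ---------------------------------------------------------------------------
# scalar operations
# ---------------------------------------------------------------------------


def perceived_n(
    model: str | ModelSpec, params: Mapping[str, float], condition: str, n_shown: float
) -> float:
    """Subjectively perceived own observation count N_perceived.

    ``none`` leaves N untouched; ``single`` multiplies by alpha; ``dual``
    multiplies by the condition-specific alpha.
    """
    spec = get_model(model)
    if spec.alpha_mode == "none":
        return float(n_shown)
    if spec.alpha_mode == "single":
        return float(n_shown) * float(params["alpha"])
    key = "alpha_uncertain" if condition == UNCERTAIN else "alpha_certain"
    return float(n_shown) * float(params[key])


def e1_counts(e1: float, n_perceived: float) -> BeliefCounts:
    """Beta pseudo-counts of the first-estimate belief.

    blue = 1 + (E1/100) * N_perceived, red = 1 + (1 - E1/100) * N_perceived;
    the leading 1s are the uniform unit prior.
    """
    if not 0 <= e1 <= 100:
        raise ValueError(f"e1 must be in [0, 100], got {e1}")
    if n_perceived < 0:
        raise ValueError(f"n_perceived must be >= 0, got {n_perceived}")
    frac = e1 / 100.0
    return BeliefCounts(1.0 + frac * n_perceived, 1.0 + (1.0 - frac) * n_perceived)


def peer_n(
    model: str | ModelSpec, params: Mapping[str, float], peer_confidence: int
) -> float:
    """Number of mushrooms the participant behaves as if the peer saw."""
    if peer_confidence not in (1, 2, 3):
        raise ValueError(f"peer_confidence must be 1, 2 or 3, got {peer_confidence}")
    spec = get_model(model)
    if spec.theta_mode == "fixed25":
        return DEFAULT_N_PEER
    if spec.theta_mode == "single":
        return float(params["theta"])
    if spec.theta_mode == "linear":
        return float(params["theta_ic"]) + float(params["theta_slope"]) * (
            peer_confidence - 1
        )
    key = {1: "theta_low", 2: "theta_medium", 3: "theta_high"}[peer_confidence]
    return float(params[key])


def posterior_counts(e1c: BeliefCounts, p: float, n_peer: float) -> BeliefCounts:
    """Add the peer's pseudo-counts to the first-estimate belief."""
    if not 0 <= p <= 100:
        raise ValueError(f"p must be in [0, 100], got {p}")
    frac = p / 100.0
    return BeliefCounts(e1c.blue + frac * n_peer, e1c.red + (1.0 - frac) * n_peer)


def response_pmf(counts: BeliefCounts) -> np.ndarray:
    """Discrete response distribution over the 101 slider options.

    Evaluates the beta density with shapes (blue, red) at k/100 for
    k = 0..100 and normalises the values to sum to one.
    """
    if counts.blue < 1 or counts.red < 1:
        raise ValueError("belief counts must include the unit prior (shapes >= 1)")
    log_pmf = _log_pmf_rows(np.array([counts.blue]), np.array([counts.red]))
    return np.exp(log_pmf[0])


def stay_weight(
    model: str | ModelSpec,
    params: Mapping[str, float],
    peer_confidence: int,
    condition: str,
) -> float:
    """Probability mass placed on repeating E1 regardless of the peer."""
    spec = get_model(model)
    if spec.stay_mode == "none":
        raise ValueError(f"{spec.name} has no stay bias")
    if spec.stay_mode == "constant":
        return float(params["beta"])
    if spec.stay_mode == "dual_condition":
        key = "beta_uncertain" if condition == UNCERTAIN else "beta_certain"
        return float(params[key])
    if spec.stay_mode == "inverse_conf":
        return float(params["beta"]) / peer_confidence
    return float(params["beta"]) ** peer_confidence


# ---------------------------------------------------------------------------
# vectorised likelihood machinery
# ---------------------------------------------------------------------------


def _log_pmf_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-normalised log PMF on the response grid for beta shapes (a, b).

    Shapes are >= 1 by construction, so xlogy/xlog1py handle the grid
    endpoints: a == 1 contributes 0 at x == 0 rather than nan.
    """
    x = RESPONSE_GRID
    with np.errstate(divide="ignore"):
        log_f = xlogy((a - 1.0)[:, None], x[None, :]) + xlog1py(
            (b - 1.0)[:, None], -x[None, :]
        )
    return log_f - logsumexp(log_f, axis=1, keepdims=True)


def prepare_trials(trials: pd.DataFrame) -> dict[str, np.ndarray]:
    """Extract the numeric arrays the likelihood needs, once per table.

    Fitting evaluates the NLL thousands of times on the same trials; pulling
    the columns out of pandas up front keeps each evaluation in pure numpy.
    """
    return {
        "e1": trials["e1"].to_numpy(float) / 100.0,
        "p": trials["p"].to_numpy(float) / 100.0,
        "n_shown": trials["n_shown"].to_numpy(float),
        "conf": trials["peer_confidence"].to_numpy(int),
        "is_unc": trials["condition"].to_numpy() == UNCERTAIN,
        "e1_idx": np.rint(trials["e1"].to_numpy(float)).astype(int),
        "e2_idx": np.rint(trials["e2"].to_numpy(float)).astype(int)
        if "e2" in trials
        else None,
    }


def _trial_shapes(
    prep: dict, spec: ModelSpec, params: Mapping[str, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior beta shapes (a, b) for every trial row."""
    e1 = prep["e1"]
    p = prep["p"]
    n_shown = prep["n_shown"]
    conf = prep["conf"]
    is_unc = prep["is_unc"]

    if spec.alpha_mode == "none":
        n_perc = n_shown
    elif spec.alpha_mode == "single":
        n_perc = n_shown * float(params["alpha"])
    else:
        n_perc = n_shown * np.where(
            is_unc, float(params["alpha_uncertain"]), float(params["alpha_certain"])
        )

    if spec.theta_mode == "fixed25":
        n_peer = np.full_like(n_perc, DEFAULT_N_PEER)
    elif spec.theta_mode == "single":
        n_peer = np.full_like(n_perc, float(params["theta"]))
    elif spec.theta_mode == "linear":
        n_peer = float(params["theta_ic"]) + float(params["theta_slope"]) * (conf - 1)
    else:
        lookup = np.array(
            [np.nan, params["theta_low"], params["theta_medium"], params["theta_high"]],
            dtype=float,
        )
        n_peer = lookup[conf]

    a = 1.0 + e1 * n_perc + p * n_peer
    b = 1.0 + (1.0 - e1) * n_perc + (1.0 - p) * n_peer
    return a, b


def _stay_weights(
    prep: dict, spec: ModelSpec, params: Mapping[str, float]
) -> np.ndarray:
    conf = prep["conf"]
    if spec.stay_mode == "none":
        return np.zeros(len(conf))
    if spec.stay_mode == "constant":
        return np.full(len(conf), float(params["beta"]))
    if spec.stay_mode == "dual_condition":
        return np.where(
            prep["is_unc"], float(params["beta_uncertain"]), float(params["beta_certain"])
        )
    if spec.stay_mode == "inverse_conf":
        return float(params["beta"]) / conf
    return float(params["beta"]) ** conf.astype(float)


def _as_frame(record) -> pd.DataFrame:
    if isinstance(record, pd.DataFrame):
        return record
    if isinstance(record, pd.Series):
        return record.to_frame().T
    return pd.DataFrame([dict(record)])


def response_distribution(
    trials: pd.DataFrame, model: str | ModelSpec, params: Mapping[str, float]
) -> np.ndarray:
    """Full mixture distribution over the 101 responses, one row per trial.

    Row i is (1 - w_i) * PMF_i with the stay mass w_i added at that trial's
    E1 response; rows sum to one.
    """
    spec = get_model(model)
    prep = prepare_trials(_as_frame(trials))
    a, b = _trial_shapes(prep, spec, params)
    q = np.exp(_log_pmf_rows(a, b))
    w = _stay_weights(prep, spec, params)
    mix = (1.0 - w)[:, None] * q
    mix[np.arange(len(q)), prep["e1_idx"]] += w
    return mix


def _trial_likelihoods(
    prep: dict, spec: ModelSpec, params: Mapping[str, float]
) -> np.ndarray:
    a, b = _trial_shapes(prep, spec, params)
    log_q = _log_pmf_rows(a, b)
    e1_idx, e2_idx = prep["e1_idx"], prep["e2_idx"]
    q_e2 = np.exp(log_q[np.arange(len(e2_idx)), e2_idx])
    w = _stay_weights(prep, spec, params)
    like = (1.0 - w) * q_e2
    stay = e2_idx == e1_idx
    like[stay] += w[stay]
    return np.maximum(like, LIKELIHOOD_FLOOR)


def nll_prepared(prep: dict, spec: ModelSpec, params: Mapping[str, float]) -> float:
    """Negative log likelihood on arrays from :func:`prepare_trials`."""
    return float(-np.sum(np.log(_trial_likelihoods(prep, spec, params))))


def trial_likelihood(record, model: str | ModelSpec, params: Mapping[str, float]) -> float:
    """Likelihood of one observed E2 response under the model.

    If E2 repeats E1 the stay mass and the Bayesian probability of restating
    E1 both contribute: w + (1 - w) * q[E1]; otherwise (1 - w) * q[E2].
    """
    spec = get_model(model)
    return float(_trial_likelihoods(prepare_trials(_as_frame(record)), spec, params)[0])


def _fit_mask(trials: pd.DataFrame) -> np.ndarray:
    mask = np.ones(len(trials), dtype=bool)
    if "is_filler" in trials:
        mask &= ~trials["is_filler"].to_numpy(bool)
    if "included" in trials:
        mask &= trials["included"].to_numpy(bool)
    return mask


def participant_nll(
    trials: pd.DataFrame, model: str | ModelSpec, params: Mapping[str, float]
) -> float:
    """Negative log likelihood over a participant's included non-filler trials."""
    spec = get_model(model)
    trials = _as_frame(trials)
    kept = trials[_fit_mask(trials)]
    if len(kept) == 0:
        raise ValueError("participant_nll requires at least one included trial")
    return nll_prepared(prepare_trials(kept), spec, params)
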