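"""Model-based trial-level quantities for neuroimaging parametric regressors.

From each participant's fitted winning-model parameters three quantities are
derived per trial:

* model-based own certainty — the shown mushroom count scaled by the
  condition's fitted alpha (N x alpha_condition), time-locked to the first
  500 ms of the first-estimate prompt;
* model-based peer confidence — the fitted peer count
  theta_ic + theta_slope x (confidence - 1), time-locked to the 4 s social
  information display, non-filler trials only;
* belief update — the Kullback-Leibler divergence between the post-advice
  and pre-advice beta beliefs, evaluated on the discrete 101-point response
  grid, same timing and filler restriction.

A fourth, supplementary regressor exports the trial-wise stay-bias mass
(beta ** confidence).  Values are mean-centered within run over the trials
entering each regressor and written as 3-column event files
(onset, duration, amplitude), one file per run per regressor.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .models import (
    e1_counts,
    get_model,
    peer_n,
    perceived_n,
    response_pmf,
    stay_weight,
)

__all__ = [
    "REGRESSOR_NAMES",
    "model_based_certainty",
    "model_based_peer_confidence",
    "kl_update",
    "stay_bias_weight",
    "simulate_onsets",
    "build_regressor_set",
    "export_events",
]

REGRESSOR_NAMES = ("certainty", "peer_confidence", "kl", "stay_bias")

#: regressors restricted to non-filler trials (peer information on filler
#: trials is deliberately implausible and may engage different processes)
_NONFILLER_ONLY = {"peer_confidence", "kl", "stay_bias"}

#: event durations in seconds: certainty covers the first 500 ms of the E1
#: prompt; the others span the 4 s social-information display
DURATIONS = {"certainty": 0.5, "peer_confidence": 4.0, "kl": 4.0, "stay_bias": 4.0}
_ONSET_COLUMN = {
    "certainty": "e1_onset",
    "peer_confidence": "social_onset",
    "kl": "social_onset",
    "stay_bias": "social_onset",
}

_KL_CLIP = 1e-10


def model_based_certainty(trial, params: Mapping[str, float], model="M3d") -> float:
    """N x alpha_condition for the trial's condition."""
    return perceived_n(model, params, trial["condition"], trial["n_shown"])


def model_based_peer_confidence(trial, params: Mapping[str, float], model="M3d") -> float:
    """theta_ic + theta_slope x (confidence - 1); rejects filler trials."""
    if bool(trial["is_filler"]):
        raise ValueError("peer-confidence regressor is undefined on filler trials")
    return peer_n(model, params, int(trial["peer_confidence"]))


def kl_update(trial, params: Mapping[str, float], model="M3d") -> float:
    """KL divergence of the post-advice belief from the pre-advice belief.

    Both beliefs are beta distributions evaluated on the 101-point response
    grid: the prior centres on E1 with precision from the perceived own
    count, the posterior centres on E2 with precision from the perceived own
    count plus the model-based peer count.  Probabilities are clipped at
    1e-10 and renormalised so the divergence is always finite; the direction
    is KL(posterior || prior), the Bayesian-surprise convention.
    """
    if bool(trial["is_filler"]):
        raise ValueError("KL regressor is undefined on filler trials")
    spec = get_model(model)
    n_perc = perceived_n(spec, params, trial["condition"], trial["n_shown"])
    n_peer = peer_n(spec, params, int(trial["peer_confidence"]))
    prior = response_pmf(e1_counts(float(trial["e1"]), n_perc))
    post = response_pmf(e1_counts(float(trial["e2"]), n_perc + n_peer))
    prior = np.clip(prior, _KL_CLIP, None)
    prior /= prior.sum()
    post = np.clip(post, _KL_CLIP, None)
    post /= post.sum()
    return float(np.sum(post * np.log(post / prior)))


def stay_bias_weight(trial, params: Mapping[str, float], model="M3d") -> float:
    """Trial-wise stay-bias mass (beta ** confidence for the winning model)."""
    if bool(trial["is_filler"]):
        raise ValueError("stay-bias regressor is undefined on filler trials")
    return stay_weight(model, params, int(trial["peer_confidence"]), trial["condition"])


def simulate_onsets(
    df: pd.DataFrame,
    seed: int = 0,
    field_view: float = 10.0,
    e1_to_social: float = 4.0,
    social_to_next: float = 10.0,
    iti_range: tuple[float, float] = (2.0, 6.0),
) -> pd.DataFrame:
    """Attach a plausible event schedule (seconds) per run.

    Each trial contributes a field-viewing period, the E1 prompt, the social
    information display and a jittered inter-trial interval.  Purely a
    stand-in schedule for synthetic sessions; real sessions supply logged
    onsets instead.
    """
    rng = np.random.default_rng(seed)
    df = df.sort_values(["run", "trial_index"]).copy()
    e1_onsets = np.empty(len(df))
    social_onsets = np.empty(len(df))
    pos = 0
    for _, run_df in df.groupby("run", sort=True):
        t = 0.0
        for _ in range(len(run_df)):
            t += field_view
            e1_onsets[pos] = t
            social_onsets[pos] = t + e1_to_social
            t += e1_to_social + social_to_next + rng.uniform(*iti_range)
            pos += 1
    df["e1_onset"] = e1_onsets
    df["social_onset"] = social_onsets
    return df


def build_regressor_set(
    df: pd.DataFrame, params: Mapping[str, float], model: str = "M3d"
) -> pd.DataFrame:
    """Compute raw and run-centered regressor values for every trial.

    Filler-restricted regressors are NaN on filler trials; centering is per
    run and per regressor over the trials that enter it.
    """
    out = df.copy()
    nonfiller = ~out["is_filler"].astype(bool)
    out["certainty_raw"] = [
        model_based_certainty(row, params, model) for _, row in out.iterrows()
    ]
    out["peer_confidence_raw"] = np.nan
    out["kl_raw"] = np.nan
    out["stay_bias_raw"] = np.nan
    nf_rows = out[nonfiller]
    out.loc[nonfiller, "peer_confidence_raw"] = [
        model_based_peer_confidence(row, params, model) for _, row in nf_rows.iterrows()
    ]
    out.loc[nonfiller, "kl_raw"] = [
        kl_update(row, params, model) for _, row in nf_rows.iterrows()
    ]
    out.loc[nonfiller, "stay_bias_raw"] = [
        stay_bias_weight(row, params, model) for _, row in nf_rows.iterrows()
    ]
    for name in REGRESSOR_NAMES:
        raw = out[f"{name}_raw"]
        out[f"{name}_centered"] = raw - raw.groupby(out["run"]).transform("mean")
    return out


def export_events(
    regressor_set: pd.DataFrame,
    which: str,
    out_dir,
    participant=None,
) -> list[Path]:
    """Write 3-column event files (onset, duration, centered amplitude).

    One file per run, named ``<participant>_<run>_<regressor>.txt``, values
    formatted to 6 decimals.  Returns the written paths.
    """
    if which not in REGRESSOR_NAMES:
        raise ValueError(f"unknown regressor {which!r}; choose from {REGRESSOR_NAMES}")
    onset_col = _ONSET_COLUMN[which]
    if onset_col not in regressor_set:
        raise ValueError(f"missing onset column {onset_col!r}; run simulate_onsets "
                         "or supply logged onsets")
    if participant is None:
        ids = regressor_set["participant"].unique()
        if len(ids) != 1:
            raise ValueError("export_events handles one participant at a time")
        participant = ids[0]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    data = regressor_set
    if which in _NONFILLER_ONLY:
        data = data[~data["is_filler"].astype(bool)]
    for run, run_df in data.groupby("run", sort=True):
        path = out_dir / f"{participant}_{run}_{which}.txt"
        amplitudes = _quantize_zero_sum(run_df[f"{which}_centered"].to_numpy(float))
        with open(path, "w") as fh:
            for (_, row), amp in zip(run_df.iterrows(), amplitudes):
                fh.write(f"{row[onset_col]:.6f}\t{DURATIONS[which]:.6f}\t{amp:.6f}\n")
        paths.append(path)
    return paths


def _quantize_zero_sum(values: np.ndarray, decimals: int = 6) -> np.ndarray:
    """Round to the file dialect while keeping the column sum at zero.

    Plain rounding of a zero-mean column can leave a residual of a few
    units-in-last-place; the residual is redistributed to the entries whose
    rounding remainders were largest so the file is zero-mean as written.
    """
    scale = 10.0**decimals
    scaled = values * scale
    floored = np.floor(scaled)
    remainder = scaled - floored
    target = int(round(values.sum() * scale))
    deficit = target - int(floored.sum())
    order = np.argsort(-remainder)
    out = floored.copy()
    out[order[:deficit]] += 1
    return out / scale
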