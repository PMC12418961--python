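"""Per-participant maximum-likelihood fitting and BIC model comparison.

Fitting is two-stage: the negative log likelihood is first evaluated on a
lattice spanning each parameter's bounds (log-spaced for the count-scaling
parameters alpha/theta, linear for the stay-bias beta), and the best lattice
points seed bounded L-BFGS-B refinement.  Model comparison sums each
participant's BIC per model and reports differences to the best model.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .models import ModelSpec, get_model, nll_prepared, participant_nll, prepare_trials

log = logging.getLogger(__name__)

__all__ = [
    "FitConfig",
    "FitResult",
    "ComparisonTable",
    "bic",
    "grid_init",
    "fit_participant",
    "fit_cohort",
    "compare_models",
    "conditional_model_sequence",
]

#: canonical order in which the family was developed
MODEL_ORDER = ("M0", "M1a", "M1b", "M2a", "M2b", "M2c", "M3a", "M3b", "M3c", "M3d")


def bic(nll: float, k: int, n: int) -> float:
    """Bayesian Information Criterion: k * ln(n) + 2 * NLL (lower is better)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return k * float(np.log(n)) + 2.0 * float(nll)


@dataclass(frozen=True)
class FitConfig:
    """Tunable fitting settings; defaults suit a 40-80 trial session."""

    grid_points: int = 5  # lattice points per parameter
    max_grid_evals: int = 10_000  # lattice coarsened until under this cap
    n_starts: int = 3  # refined starting points taken from the lattice
    maxiter: int = 200  # L-BFGS-B iteration cap
    ftol: float = 1e-9


@dataclass
class FitResult:
    participant: object
    model: str
    params: dict[str, float]
    nll: float
    n_trials: int
    bic: float
    converged: bool
    n_restarts_used: int


def _is_log_scaled(name: str) -> bool:
    return not name.startswith("beta")


def _lattice(spec: ModelSpec, points: int) -> list[np.ndarray]:
    axes = []
    for name, (lo, hi) in zip(spec.param_names, spec.bounds):
        if _is_log_scaled(name):
            axes.append(np.geomspace(lo, hi, points))
        else:
            axes.append(np.linspace(lo, hi, points))
    return axes


def _grid_axes(spec: ModelSpec, config: FitConfig) -> list[np.ndarray]:
    points = config.grid_points
    while points > 2 and points**spec.n_params > config.max_grid_evals:
        points -= 1
    return _lattice(spec, points)


def _included_mask(records: pd.DataFrame) -> np.ndarray:
    mask = np.ones(len(records), dtype=bool)
    if "is_filler" in records:
        mask &= ~records["is_filler"].to_numpy(bool)
    if "included" in records:
        mask &= records["included"].to_numpy(bool)
    return mask


def _prepared_included(records: pd.DataFrame) -> dict:
    kept = records[_included_mask(records)]
    if len(kept) == 0:
        raise ValueError("no included trials to fit")
    return prepare_trials(kept)


def _grid_starts(prep: dict, spec: ModelSpec, config: FitConfig) -> list[dict[str, float]]:
    if spec.n_params == 0:
        return [{}]
    axes = _grid_axes(spec, config)
    best: list[tuple[float, dict[str, float]]] = []
    for values in itertools.product(*axes):
        params = dict(zip(spec.param_names, values))
        best.append((nll_prepared(prep, spec, params), params))
    best.sort(key=lambda t: t[0])
    return [params for _, params in best[: config.n_starts]]


def grid_init(
    records: pd.DataFrame,
    model: str | ModelSpec,
    config: FitConfig = FitConfig(),
) -> list[dict[str, float]]:
    """Best lattice points to seed the optimiser, ordered by NLL."""
    spec = get_model(model)
    return _grid_starts(_prepared_included(records), spec, config)


def fit_participant(
    records: pd.DataFrame,
    model: str | ModelSpec,
    config: FitConfig = FitConfig(),
    participant=None,
) -> FitResult:
    """Grid-initialised bounded MLE for one participant under one model."""
    spec = get_model(model)
    if participant is None and "participant" in records:
        ids = records["participant"].unique()
        participant = ids[0] if len(ids) == 1 else None

    prep = _prepared_included(records)
    n_trials = len(prep["e1"])

    starts = _grid_starts(prep, spec, config)
    if spec.n_params == 0:
        nll = nll_prepared(prep, spec, {})
        return FitResult(participant, spec.name, {}, nll, n_trials, bic(nll, 0, n_trials), True, 0)

    def objective(x: np.ndarray) -> float:
        return nll_prepared(prep, spec, dict(zip(spec.param_names, x)))

    best_nll = np.inf
    best_x = np.array([list(s.values()) for s in starts][0], dtype=float)
    converged = False
    used = 0
    for start in starts:
        x0 = np.array([start[name] for name in spec.param_names], dtype=float)
        try:
            res = minimize(
                objective,
                x0,
                method="L-BFGS-B",
                bounds=list(spec.bounds),
                options={"maxiter": config.maxiter, "ftol": config.ftol},
            )
        except Exception as exc:  # pragma: no cover - optimizer failure path
            log.warning("optimizer start failed for %s: %s", spec.name, exc)
            continue
        used += 1
        if res.fun < best_nll:
            best_nll = float(res.fun)
            best_x = np.clip(res.x, [b[0] for b in spec.bounds], [b[1] for b in spec.bounds])
            converged = bool(res.success) or converged
    if not np.isfinite(best_nll):  # all starts failed: report best grid point
        best_nll = participant_nll(records, spec, starts[0])
        best_x = np.array([starts[0][n] for n in spec.param_names])
        log.warning("all optimizer starts failed for %s; returning grid optimum", spec.name)
    params = dict(zip(spec.param_names, (float(v) for v in best_x)))
    return FitResult(
        participant,
        spec.name,
        params,
        best_nll,
        n_trials,
        bic(best_nll, spec.n_params, n_trials),
        converged,
        used,
    )


def fit_cohort(
    df: pd.DataFrame, model: str | ModelSpec, config: FitConfig = FitConfig()
) -> list[FitResult]:
    """Fit every participant in a trial table independently."""
    return [
        fit_participant(grp, model, config, participant=pid)
        for pid, grp in df.groupby("participant")
    ]


@dataclass
class ComparisonTable:
    """Cohort-level BIC comparison across models."""

    total_bic: dict[str, float]
    delta_bic: dict[str, float]
    winner: str
    n_participants: int
    acceptance_path: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": list(self.total_bic),
                "total_bic": list(self.total_bic.values()),
                "delta_bic": [self.delta_bic[m] for m in self.total_bic],
            }
        ).sort_values("delta_bic", ignore_index=True)


def compare_models(
    fits: dict[str, list[FitResult]], replay_sequence: bool = False
) -> ComparisonTable:
    """Sum per-participant BICs per model and rank by the total.

    All models must cover the same participants.  With ``replay_sequence``
    the incremental model-building path is reported: each model is accepted
    only if it beats the last accepted model's total BIC.
    """
    if not fits:
        raise ValueError("no fits supplied")
    participants = None
    totals: dict[str, float] = {}
    for name, results in fits.items():
        ids = sorted(str(r.participant) for r in results)
        if participants is None:
            participants = ids
        elif ids != participants:
            raise ValueError(f"model {name} fitted on a different participant set")
        totals[name] = float(sum(r.bic for r in results))
    best = min(totals.values())
    delta = {m: t - best for m, t in totals.items()}
    winner = min(totals, key=totals.get)

    path: list[str] = []
    if replay_sequence:
        accepted = None
        for name in MODEL_ORDER:
            if name not in totals:
                continue
            if accepted is None or totals[name] < totals[accepted]:
                accepted = name
                path.append(name)
    return ComparisonTable(totals, delta, winner, len(participants or []), path)


def conditional_model_sequence(fits: dict[str, list[FitResult]]) -> list[str]:
    """The accepted-model path of the incremental building procedure."""
    return compare_models(fits, replay_sequence=True).acceptance_path
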