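"""Synthetic mushroom-estimation task: designs, fields, peers, and agents.

Emulates the estimation game in which a participant views either 5
(uncertain condition) or 45 (certain condition) mushrooms, reports a first
estimate E1 of the percentage of blue mushrooms, sees a peer estimate P with
a confidence rating (low/medium/high), and submits a second estimate E2.

Everything downstream (filtering, model fitting, recovery, regressor
construction) runs on the trial tables produced here, so real data are never
required.  All randomness flows through :class:`numpy.random.Generator`
objects derived from explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import models as _models
from .models import CERTAIN, UNCERTAIN, get_model, validate_params

__all__ = [
    "TrialDesign",
    "DesignSet",
    "TRUE_PCTS",
    "DEFAULT_SIM_RANGES",
    "generate_design",
    "sample_fields",
    "sample_peer",
    "simulate_participant",
    "simulate_cohort",
    "sample_parameters",
    "default_ranges",
    "write_trials",
    "read_trials",
]

#: non-filler true percentages per experiment
TRUE_PCTS = {
    1: (12.5, 25.0, 37.5, 50.0, 62.5, 75.0, 87.5),
    2: (12.5, 25.0, 37.5, 62.5, 75.0),
}
#: repetitions of each (condition x confidence x percentage) cell
_CELL_REPS = {1: 1, 2: 2}
_N_FILLER = {1: 12, 2: 15}
N_RUNS = 3
N_SHOWN = {UNCERTAIN: 5, CERTAIN: 45}

#: default uniform simulation ranges per parameter (config-exposed; chosen to
#: bracket plausible fitted values while staying well inside the fit bounds)
DEFAULT_SIM_RANGES: dict[str, tuple[float, float]] = {
    "alpha": (1.0, 50.0),
    "alpha_uncertain": (1.0, 50.0),
    "alpha_certain": (1.0, 50.0),
    "theta": (1.0, 150.0),
    "theta_ic": (1.0, 150.0),
    "theta_slope": (1.0, 150.0),
    "theta_low": (1.0, 150.0),
    "theta_medium": (1.0, 150.0),
    "theta_high": (1.0, 150.0),
    "beta": (0.05, 0.9),
    "beta_uncertain": (0.05, 0.9),
    "beta_certain": (0.05, 0.9),
}

#: columns of the tab-delimited trial-table dialect, in order
TRIAL_COLUMNS = [
    "participant",
    "run",
    "trial_index",
    "condition",
    "n_shown",
    "peer_confidence",
    "true_pct",
    "is_filler",
    "missed",
    "e1",
    "p",
    "e2",
    "s",
]


@dataclass(frozen=True)
class TrialDesign:
    """One planned trial before any responses are realised."""

    trial_index: int
    run: int
    condition: str
    n_shown: int
    peer_confidence: int
    true_pct: float
    is_filler: bool

    def __post_init__(self):
        if self.condition not in (UNCERTAIN, CERTAIN):
            raise ValueError(f"bad condition {self.condition!r}")
        if self.n_shown != N_SHOWN[self.condition]:
            raise ValueError(
                f"n_shown={self.n_shown} inconsistent with {self.condition} condition"
            )
        if self.peer_confidence not in (1, 2, 3):
            raise ValueError(f"bad peer_confidence {self.peer_confidence}")


@dataclass
class DesignSet:
    """Ordered trial plan for one participant session."""

    experiment: int
    trials: list[TrialDesign] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_nonfiller(self) -> int:
        return sum(not t.is_filler for t in self.trials)

    def counts(self) -> pd.Series:
        """Per-cell tally of non-filler trials."""
        df = self.to_frame()
        nf = df[~df["is_filler"]]
        return nf.groupby(["condition", "peer_confidence", "true_pct"]).size()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(t) for t in self.trials])


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def generate_design(experiment: int, seed) -> DesignSet:
    """Build the full factorial design plus filler trials, in seeded order.

    Experiment 1: 2 x 3 x 7 cells once = 42 non-filler trials plus 12
    fillers over 3 rounds.  Experiment 2: 2 x 3 x 5 cells twice = 60
    non-filler trials plus 15 fillers over 3 runs.  Runs are balanced on
    condition; order within a run is randomised by the seed.
    """
    if experiment not in (1, 2):
        raise ValueError(f"experiment must be 1 or 2, got {experiment}")
    rng = _rng(seed)

    cells = []
    for _ in range(_CELL_REPS[experiment]):
        for condition in (UNCERTAIN, CERTAIN):
            for conf in (1, 2, 3):
                for pct in TRUE_PCTS[experiment]:
                    cells.append((condition, conf, pct, False))
    for i in range(_N_FILLER[experiment]):
        condition = (UNCERTAIN, CERTAIN)[i % 2]
        conf = int(rng.integers(1, 4))
        pct = float(np.round(rng.uniform(0, 100), 1))
        cells.append((condition, conf, pct, True))

    # deal to runs round-robin within condition so runs stay balanced
    run_bins: list[list] = [[] for _ in range(N_RUNS)]
    for condition in (UNCERTAIN, CERTAIN):
        group = [c for c in cells if c[0] == condition]
        rng.shuffle(group)
        for i, cell in enumerate(group):
            run_bins[i % N_RUNS].append(cell)

    trials = []
    idx = 0
    for run_id, bin_ in enumerate(run_bins, start=1):
        rng.shuffle(bin_)
        for condition, conf, pct, filler in bin_:
            trials.append(
                TrialDesign(
                    trial_index=idx,
                    run=run_id,
                    condition=condition,
                    n_shown=N_SHOWN[condition],
                    peer_confidence=conf,
                    true_pct=pct,
                    is_filler=filler,
                )
            )
            idx += 1
    return DesignSet(experiment=experiment, trials=trials)


def sample_fields(true_pct: float, n_shown: int, seed) -> tuple[int, int]:
    """Sample the mushrooms seen in the fields and the faithful first estimate.

    The blue count is binomial(n_shown, true_pct/100); E1 is the seen
    proportion expressed as an integer percentage, assuming the participant
    reports exactly what they saw.
    """
    if not 0 <= true_pct <= 100:
        raise ValueError(f"true_pct must be in [0, 100], got {true_pct}")
    if n_shown < 1:
        raise ValueError(f"n_shown must be >= 1, got {n_shown}")
    rng = _rng(seed)
    blue = int(rng.binomial(n_shown, true_pct / 100.0))
    e1 = int(round(100.0 * blue / n_shown))
    return blue, e1


_PEER_OFFSETS = (15, 16, 17, 18)


def sample_peer(e1: int, true_pct: float, is_filler: bool, seed) -> int:
    """Sample a peer estimate P obeying the distance rules.

    Non-filler: |P - E1| between 15 and 18 points, in the direction of the
    true percentage whenever an in-range value exists that way, otherwise in
    the opposite direction.  Filler: either very close (< 3 points) or very
    far (> 40 points) from E1, direction random subject to 0 <= P <= 100.
    """
    if not 0 <= e1 <= 100:
        raise ValueError(f"e1 must be in [0, 100], got {e1}")
    rng = _rng(seed)

    if is_filler:
        far = bool(rng.integers(0, 2))
        offsets = range(41, 101) if far else range(1, 3)
        candidates = [e1 + s * d for d in offsets for s in (-1, 1) if 0 <= e1 + s * d <= 100]
        if not candidates and far:  # e1 mid-scale with no room beyond 40: cannot happen
            candidates = [e1 + s * d for d in range(1, 3) for s in (-1, 1) if 0 <= e1 + s * d <= 100]
        return int(candidates[rng.integers(0, len(candidates))])

    if true_pct > e1:
        direction = 1
    elif true_pct < e1:
        direction = -1
    else:
        direction = int(rng.choice([-1, 1]))

    for sign in (direction, -direction):
        admissible = [e1 + sign * d for d in _PEER_OFFSETS if 0 <= e1 + sign * d <= 100]
        if admissible:
            return int(admissible[rng.integers(0, len(admissible))])
    raise RuntimeError("no admissible peer estimate; impossible for e1 in [0, 100]")


def simulate_participant(
    design: DesignSet,
    model: str,
    params: Mapping[str, float],
    seed,
    participant: int = 0,
) -> pd.DataFrame:
    """Simulate a full session of one model-driven agent.

    For each trial E1 is sampled from the fields, P from the peer rule, and
    E2 from the model's full response mixture (stay mass on E1 plus the
    renormalised beta PMF).  The returned frame carries the generating model
    and parameters in ``attrs`` for recovery studies.
    """
    spec = get_model(model)
    validate_params(spec, params)
    rng = _rng(seed)

    rows = []
    for t in design.trials:
        _, e1 = sample_fields(t.true_pct, t.n_shown, rng)
        p = sample_peer(e1, t.true_pct, t.is_filler, rng)
        rows.append(
            {
                "participant": participant,
                "run": t.run,
                "trial_index": t.trial_index,
                "condition": t.condition,
                "n_shown": t.n_shown,
                "peer_confidence": t.peer_confidence,
                "true_pct": t.true_pct,
                "is_filler": t.is_filler,
                "missed": False,
                "e1": e1,
                "p": p,
            }
        )
    df = pd.DataFrame(rows)

    mix = _models.response_distribution(df, spec, params)
    cum = np.cumsum(mix, axis=1)
    u = rng.random(len(df))
    df["e2"] = (u[:, None] <= cum).argmax(axis=1)

    denom = df["p"] - df["e1"]
    df["s"] = np.where(denom != 0, (df["e2"] - df["e1"]) / denom.replace(0, np.nan), np.nan)
    df.attrs["model"] = spec.name
    df.attrs["params"] = dict(params)
    return df


def sample_parameters(
    model: str,
    ranges: Mapping[str, tuple[float, float]] | None,
    n: int,
    seed,
) -> list[dict[str, float]]:
    """Draw ``n`` independent uniform parameter sets for simulation studies.

    ``ranges`` defaults to :data:`DEFAULT_SIM_RANGES` restricted to the
    model's parameters; every range must lie within the model's fit bounds.
    """
    spec = get_model(model)
    ranges = default_ranges(spec) if ranges is None else dict(ranges)
    rng = _rng(seed)
    for name, (lo, hi) in zip(spec.param_names, spec.bounds):
        rlo, rhi = ranges[name]
        if rlo > rhi:
            raise ValueError(f"inverted range for {name}: [{rlo}, {rhi}]")
        if rlo < lo or rhi > hi:
            raise ValueError(f"range for {name} leaves fit bounds [{lo}, {hi}]")
    return [
        {name: float(rng.uniform(*ranges[name])) for name in spec.param_names}
        for _ in range(n)
    ]


def default_ranges(model: str | object) -> dict[str, tuple[float, float]]:
    spec = get_model(model)
    return {name: DEFAULT_SIM_RANGES[name] for name in spec.param_names}


def simulate_cohort(
    experiment: int,
    model: str,
    params_list: Sequence[Mapping[str, float]],
    seed,
) -> pd.DataFrame:
    """Simulate one agent per parameter set, each with its own seeded design."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(params_list))
    frames = []
    true_params = []
    for pid, (params, child) in enumerate(zip(params_list, children)):
        rng = np.random.default_rng(child)
        design = generate_design(experiment, rng)
        df = simulate_participant(design, model, params, rng, participant=pid)
        frames.append(df)
        true_params.append(dict(params))
    out = pd.concat(frames, ignore_index=True)
    out.attrs["model"] = get_model(model).name
    out.attrs["true_params"] = true_params
    return out


# ---------------------------------------------------------------------------
# trial-table I/O (tab-delimited dialect shared with real-data ingestion)
# ---------------------------------------------------------------------------


def write_trials(df: pd.DataFrame, path) -> None:
    """Write a trial table as tab-delimited text, one row per trial."""
    cols = [c for c in TRIAL_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df.to_csv(path, sep="\t", index=False, columns=cols)


def read_trials(path) -> pd.DataFrame:
    """Read a tab-delimited trial table written by :func:`write_trials`."""
    df = pd.read_csv(path, sep="\t")
    for col in ("is_filler", "missed", "included"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df
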