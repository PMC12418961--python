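"""End-to-end orchestration: simulate -> filter -> fit -> compare -> recover
-> regressors, driven by a serialisable configuration.

Each stage writes plain-text artifacts into the output directory and the run
closes with a manifest (JSON) recording the configuration, seeds, per-file
SHA-256 hashes, exclusion counts and the winning model, so a saved
configuration reproduces a run bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import behavior, fitting, recovery, regressors, synthetic

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

ALL_STAGES = ("simulate", "filter", "regress-behavior", "fit", "compare", "recover", "regressors")


class PipelineError(RuntimeError):
    """A stage failed or its prerequisites were not run."""


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    out_dir: str
    seed: int = 0
    experiment: int = 2
    n_participants: int = 30
    generating_model: str = "M3d"
    model_list: tuple[str, ...] = ("M2b", "M3a", "M3c", "M3d")
    stages: tuple[str, ...] = ALL_STAGES
    sim_ranges: dict | None = None  # None -> synthetic.DEFAULT_SIM_RANGES
    grid_points: int = 5
    n_starts: int = 3
    optimizer_maxiter: int = 200
    recovery_models: tuple[str, ...] = recovery.RECOVERY_MODELS
    recovery_n_per_model: int = 5
    overwrite: bool = False

    def fit_config(self) -> fitting.FitConfig:
        return fitting.FitConfig(
            grid_points=self.grid_points,
            n_starts=self.n_starts,
            maxiter=self.optimizer_maxiter,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("model_list", "stages", "recovery_models"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in canonical order; return the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not config.overwrite:
        raise PipelineError(f"{manifest_path} exists; pass overwrite=True to redo")

    stages = [s for s in ALL_STAGES if s in config.stages]
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "stages_run": stages,
        "files": {},
    }
    trials = None
    fits: dict[str, list[fitting.FitResult]] = {}

    def register(path: Path):
        manifest["files"][path.name] = _sha256(path)

    try:
        if "simulate" in stages:
            params_list = synthetic.sample_parameters(
                config.generating_model,
                config.sim_ranges,
                config.n_participants,
                config.seed,
            )
            trials = synthetic.simulate_cohort(
                config.experiment, config.generating_model, params_list, config.seed + 1
            )
            synthetic.write_trials(trials, out / "trials.tsv")
            register(out / "trials.tsv")

        if "filter" in stages:
            if trials is None:
                raise PipelineError("filter requires the simulate stage (or loaded trials)")
            trials = behavior.apply_trial_filters(trials)
            trials, exclusion_log = behavior.apply_participant_filters(trials)
            reason_counts = (
                trials["exclusion_reason"].value_counts().to_dict()
            )
            manifest["exclusions"] = {
                "trial_reason_counts": {k: int(v) for k, v in reason_counts.items()},
                "participants_excluded": int(exclusion_log["excluded"].sum()),
            }
            synthetic.write_trials(trials, out / "trials_filtered.tsv")
            exclusion_log.to_csv(out / "participant_exclusions.tsv", sep="\t", index=False)
            register(out / "trials_filtered.tsv")
            register(out / "participant_exclusions.tsv")

        if "regress-behavior" in stages:
            if trials is None or "included" not in trials:
                raise PipelineError("regress-behavior requires the filter stage")
            reg = behavior.fit_condition_regression(trials)
            payload = {
                "fixed_effects": reg.fixed_effects.to_dict(orient="index"),
                "random_effect_variances": reg.random_effect_variances,
                "n_participants": reg.n_participants,
                "n_trials": reg.n_trials,
                "converged": reg.converged,
                "random_structure": reg.random_structure,
                "notes": reg.notes,
            }
            (out / "behavior_regression.json").write_text(json.dumps(payload, indent=2))
            register(out / "behavior_regression.json")

        if "fit" in stages:
            if trials is None:
                raise PipelineError("fit requires simulated or loaded trials")
            cfg = config.fit_config()
            for name in config.model_list:
                fits[name] = fitting.fit_cohort(trials, name, cfg)
            payload = {
                name: [dataclasses.asdict(r) for r in results]
                for name, results in fits.items()
            }
            (out / "fits.json").write_text(json.dumps(payload, indent=2, default=str))
            register(out / "fits.json")

        if "compare" in stages:
            if not fits:
                raise PipelineError("compare requires the fit stage")
            table = fitting.compare_models(fits, replay_sequence=True)
            table.to_frame().to_csv(out / "comparison.tsv", sep="\t", index=False)
            (out / "comparison.json").write_text(
                json.dumps(
                    {
                        "total_bic": table.total_bic,
                        "delta_bic": table.delta_bic,
                        "winner": table.winner,
                        "acceptance_path": table.acceptance_path,
                    },
                    indent=2,
                )
            )
            manifest["winner"] = table.winner
            register(out / "comparison.tsv")
            register(out / "comparison.json")

        if "recover" in stages:
            conf = recovery.model_recovery(
                models=config.recovery_models,
                n_per_model=config.recovery_n_per_model,
                ranges=config.sim_ranges,
                seed=config.seed + 2,
                experiment=config.experiment,
            )
            conf.matrix.to_csv(out / "confusion_matrix.tsv", sep="\t")
            register(out / "confusion_matrix.tsv")
            manifest["recovery"] = {
                "n_fitting_procedures": conf.n_fitting_procedures,
                "diagonal": {m: float(conf.matrix.loc[m, m]) for m in conf.matrix.index},
            }

        if "regressors" in stages:
            if trials is None:
                raise PipelineError("regressors require simulated or loaded trials")
            if "M3d" in fits:
                by_pid = {r.participant: r.params for r in fits["M3d"]}
            else:
                raise PipelineError("regressors require M3d fits")
            ev_dir = out / "events"
            used = {}
            for pid, grp in trials.groupby("participant"):
                params = by_pid[pid]
                sched = regressors.simulate_onsets(grp, seed=config.seed + 3)
                reg_set = regressors.build_regressor_set(sched, params)
                for which in regressors.REGRESSOR_NAMES:
                    for path in regressors.export_events(reg_set, which, ev_dir, pid):
                        register(path)
                used[str(pid)] = params
            (out / "events" / "parameters_manifest.json").write_text(
                json.dumps(used, indent=2)
            )
            register(out / "events" / "parameters_manifest.json")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage failed: {exc}") from exc

    manifest["files"] = dict(sorted(manifest["files"].items()))
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
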