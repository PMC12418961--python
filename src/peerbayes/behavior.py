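"""Model-free analysis: social information use, exclusions, mixed regression.

The headline model-free outcome is social information use

    s = (E2 - E1) / (P - E1),

the fraction of the distance toward the peer's estimate covered by the
revision: 0 means the peer was ignored, 1 means the peer was copied.

Trial- and participant-level exclusion rules mirror common practice for this
task: filler and missed trials are dropped, trials where the peer estimate
coincides with E1 leave s undefined, estimates more than 3 SD from their
(condition x true-percentage) cell mean are treated as outliers, s outside
[0, 1] is not a weighted average of E1 and P, and participants who stay with
E1 on more than 70% of evaluable trials carry too little variance to analyse.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

log = logging.getLogger(__name__)

__all__ = [
    "EXCLUSION_REASONS",
    "RegressionResult",
    "social_info_use",
    "group_statistics",
    "apply_trial_filters",
    "apply_participant_filters",
    "fit_condition_regression",
    "code_conditions",
]

#: exclusion precedence, most dominant first
EXCLUSION_REASONS = ("filler", "missed", "no_peer", "outlier_3sd", "s_out_of_range")

STAY_THRESHOLD = 0.70  # participants with stay fraction strictly above are dropped


def social_info_use(e1: float, e2: float, p: float) -> float:
    """s = (E2 - E1) / (P - E1); undefined when P == E1."""
    if p == e1:
        raise ValueError("social information use undefined when p == e1")
    return (e2 - e1) / (p - e1)


def group_statistics(df: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of E1 and E2 per (condition x true_pct) cell.

    Computed over the full ingested cohort (all responded trials), since the
    outlier rule references the group mean of each cell.
    """
    responded = df[~df["missed"].astype(bool)] if "missed" in df else df
    g = responded.groupby(["condition", "true_pct"])
    stats = g.agg(
        e1_mean=("e1", "mean"),
        e1_sd=("e1", "std"),
        e2_mean=("e2", "mean"),
        e2_sd=("e2", "std"),
        n=("e1", "size"),
    )
    return stats.reset_index()


def apply_trial_filters(
    df: pd.DataFrame, group_stats: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Assign ``included`` and ``exclusion_reason`` to every trial.

    Precedence: filler > missed > no_peer > outlier_3sd > s_out_of_range.
    Re-applying the filters is a no-op.  Returns a copy.
    """
    if len(df) == 0:
        raise ValueError("empty cohort")
    # cell statistics refer to the full ingested cohort; they are cached in
    # attrs (as plain records, which pandas attrs can carry) so re-filtering a
    # subset (e.g. after participant exclusion) keeps the cohort-level
    # reference and stays idempotent
    if group_stats is None and "group_stats" in df.attrs:
        group_stats = pd.DataFrame(df.attrs["group_stats"])
    if group_stats is None:
        group_stats = group_statistics(df)
    df = df.copy()
    df.attrs["group_stats"] = tuple(group_stats.to_dict(orient="records"))
    stats = group_stats.set_index(["condition", "true_pct"])

    reason = pd.Series("none", index=df.index, dtype=object)

    s = pd.Series(np.nan, index=df.index)
    peer_ok = df["p"] != df["e1"]
    s[peer_ok] = (df.loc[peer_ok, "e2"] - df.loc[peer_ok, "e1"]) / (
        df.loc[peer_ok, "p"] - df.loc[peer_ok, "e1"]
    )
    df["s"] = s

    keys = pd.MultiIndex.from_frame(df[["condition", "true_pct"]])
    cell = stats.reindex(keys)
    with np.errstate(invalid="ignore", divide="ignore"):
        e1_dev = (df["e1"].to_numpy() - cell["e1_mean"].to_numpy()) / cell["e1_sd"].to_numpy()
        e2_dev = (df["e2"].to_numpy() - cell["e2_mean"].to_numpy()) / cell["e2_sd"].to_numpy()
        outlier = (np.abs(e1_dev) > 3) | (np.abs(e2_dev) > 3)

    # apply in reverse precedence so dominant reasons overwrite weaker ones
    reason[(s < 0) | (s > 1)] = "s_out_of_range"
    reason[outlier] = "outlier_3sd"
    reason[~peer_ok] = "no_peer"
    if "missed" in df:
        reason[df["missed"].astype(bool)] = "missed"
    reason[df["is_filler"].astype(bool)] = "filler"

    df["exclusion_reason"] = reason
    df["included"] = reason == "none"
    return df


def apply_participant_filters(
    df: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop low-variance and flagged participants; return (retained, log).

    A participant is excluded when s == 0 on strictly more than 70% of their
    evaluable non-filler trials (responded, peer distinct from E1), or when a
    ``flagged_misunderstood`` column marks them as not understanding the task.
    """
    records = []
    for pid, grp in df.groupby("participant"):
        evaluable = grp[
            ~grp["is_filler"].astype(bool)
            & ~grp.get("missed", pd.Series(False, index=grp.index)).astype(bool)
            & (grp["p"] != grp["e1"])
        ]
        if len(evaluable) == 0:
            raise ValueError(f"participant {pid} has no evaluable trial")
        stay_frac = float((evaluable["s"] == 0).mean())
        flagged = bool(grp.get("flagged_misunderstood", pd.Series(False)).any())
        excluded = flagged or stay_frac > STAY_THRESHOLD
        reason = (
            "flagged_misunderstood"
            if flagged
            else ("stay_above_70pct" if excluded else "retained")
        )
        records.append(
            {
                "participant": pid,
                "stay_fraction": stay_frac,
                "n_evaluable": len(evaluable),
                "excluded": excluded,
                "reason": reason,
            }
        )
    exclusion_log = pd.DataFrame(records)
    keep = exclusion_log.loc[~exclusion_log["excluded"], "participant"]
    return df[df["participant"].isin(keep)].copy(), exclusion_log


@dataclass
class RegressionResult:
    """Fixed and random effects of the condition-effects mixed regression."""

    fixed_effects: pd.DataFrame  # index term, columns estimate / se / pvalue
    random_effect_variances: dict[str, float]
    n_participants: int
    n_trials: int
    converged: bool
    random_structure: str  # "full" or "intercept_only"
    notes: list[str] = field(default_factory=list)

    def coef(self, term: str) -> float:
        return float(self.fixed_effects.loc[term, "estimate"])


def code_conditions(df: pd.DataFrame) -> pd.DataFrame:
    """Add centered condition codes: certainty -0.5/+0.5, confidence -1/0/+1."""
    df = df.copy()
    df["certainty"] = np.where(df["condition"] == "certain", 0.5, -0.5)
    df["confidence"] = df["peer_confidence"].astype(int) - 2
    return df


def fit_condition_regression(df: pd.DataFrame) -> RegressionResult:
    """Mixed regression of s on certainty, confidence and their interaction.

    By-participant random intercepts and slopes for all three terms; falls
    back to a random-intercept-only model if the full structure fails to
    converge or is singular (logged in ``notes``).
    """
    data = code_conditions(df[df["included"]].copy())
    if data["participant"].nunique() < 2:
        raise ValueError("need at least 2 participants with included trials")

    notes: list[str] = []
    formula = "s ~ certainty * confidence"
    for structure, re_formula in (
        ("full", "~certainty * confidence"),
        ("intercept_only", "~1"),
    ):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                model = smf.mixedlm(
                    formula, data, groups=data["participant"], re_formula=re_formula
                )
                fit = model.fit(reml=True, method="lbfgs", maxiter=200)
            except Exception as exc:  # singular matrix etc.
                notes.append(f"{structure} random structure failed: {exc}")
                continue
        converged = bool(getattr(fit, "converged", False))
        singular = any("singular" in str(w.message).lower() for w in caught)
        if structure == "full" and (not converged or singular):
            notes.append(
                f"full random structure {'did not converge' if not converged else 'singular'};"
                " falling back to random intercepts"
            )
            log.info(notes[-1])
            continue
        fe = pd.DataFrame(
            {
                "estimate": fit.fe_params,
                "se": fit.bse_fe,
                "pvalue": fit.pvalues[fit.fe_params.index],
            }
        )
        cov_re = pd.DataFrame(fit.cov_re)
        re_var = {str(name): float(cov_re.loc[name, name]) for name in cov_re.index}
        return RegressionResult(
            fixed_effects=fe,
            random_effect_variances=re_var,
            n_participants=int(data["participant"].nunique()),
            n_trials=int(len(data)),
            converged=converged,
            random_structure=structure,
            notes=notes,
        )
    raise RuntimeError(f"mixed regression failed to converge: {notes}")
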