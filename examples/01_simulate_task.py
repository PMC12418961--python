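"""Simulate one session of the mushroom-estimation advice task.

Builds the experiment-2 design (60 factorial trials + 15 fillers over 3
runs), lets a Bayesian agent with a stay bias (model M3d) play it, and shows
what the simulated trials look like.
"""

import peerbayes as pb

design = pb.generate_design(experiment=2, seed=42)
print(f"trials: {design.n_trials} total, {design.n_nonfiller} non-filler")
print("per-cell repetitions (condition x confidence x true %):")
print(design.counts().head(6).to_string(), "\n...")

params = {
    "alpha_uncertain": 20.0,  # inflates the 5 seen mushrooms to 100 perceived
    "alpha_certain": 5.0,  # inflates the 45 seen mushrooms to 225 perceived
    "theta_ic": 10.0,  # peer worth 10 mushrooms at low confidence
    "theta_slope": 50.0,  # +50 mushrooms per confidence step
    "beta": 0.6,  # stay bias 0.6 / 0.36 / 0.216 at confidence 1/2/3
}
session = pb.simulate_participant(design, "M3d", params, seed=7)

cols = ["run", "condition", "peer_confidence", "true_pct", "e1", "p", "e2", "s"]
print("\nfirst five non-filler trials:")
print(session[~session["is_filler"]][cols].head().to_string(index=False))

nf = session[~session["is_filler"] & (session["p"] != session["e1"])]
by_cond = nf.groupby("condition")["s"].mean()
by_conf = nf.groupby("peer_confidence")["s"].mean()
print("\nmean social information use s by own certainty:")
print(by_cond.round(3).to_string())
print("mean s by peer confidence:")
print(by_conf.round(3).to_string())
print(
    "\ns is the fraction of the distance to the peer's estimate covered by the"
    "\nrevision: the agent moves further when uncertain (5 mushrooms) and when"
    "\nthe peer reports high confidence."
)
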