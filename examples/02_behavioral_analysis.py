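"""Model-free analysis: exclusions and the condition-effects mixed regression.

Simulates a small cohort of heterogeneous stay-bias agents, applies the
trial- and participant-level exclusion rules, and regresses social
information use on own certainty and peer confidence.
"""

import peerbayes as pb

params_list = pb.sample_parameters("M3d", None, n=15, seed=1)
cohort = pb.simulate_cohort(experiment=2, model="M3d", params_list=params_list, seed=2)

cohort = pb.apply_trial_filters(cohort)
print("trial exclusions:")
print(cohort["exclusion_reason"].value_counts().to_string())

cohort, log = pb.apply_participant_filters(cohort)
print(f"\nparticipants excluded (stay > 70% of trials): {int(log['excluded'].sum())}")

res = pb.fit_condition_regression(cohort)
print("\nfixed effects (s ~ certainty * confidence):")
print(res.fixed_effects.round(4).to_string())
print(f"random-effects structure: {res.random_structure}")
print(
    "\ncertainty is coded -0.5 (uncertain) / +0.5 (certain), confidence"
    "\n-1/0/+1; a negative certainty slope means more advice taking when"
    "\nuncertain, a positive confidence slope means more advice taking from"
    "\nconfident peers."
)
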