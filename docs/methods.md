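# Methods

This note documents the models, the synthetic task, the numerical choices
and the open design decisions behind `peerbayes`, in the spirit of a model
documentation page rather than a results report. Nothing here states an
empirical number that the test suite or `scripts/acceptance.py` does not
itself compute.

## Belief model

A belief about the percentage of blue mushrooms is a beta distribution
parameterised by pseudo-counts `(blue, red)`. Every belief starts from a
unit prior (1 blue + 1 red), so both shapes are always ≥ 1 and the density
is finite everywhere on [0, 1]. The first-estimate belief adds
`(E1/100)·N_perceived` blue and `(1 − E1/100)·N_perceived` red pseudo-counts;
the peer adds `(P/100)·N_peer` and `(1 − P/100)·N_peer` (no extra prior —
the peer contributes evidence, not a belief of their own). The model assumes
E1 faithfully reports the proportion the participant saw, so E1 is not a
free quantity but an observed input.

The response likelihood is **discrete**: the posterior beta density is
evaluated at the 101 slider positions k/100 and renormalised to sum to 1.
Renormalisation (rather than using raw density values) is what makes the
stay-bias mixture a proper probability distribution: the stay mass `w` and
the remaining `(1 − w)` spread over the 101 options sum to exactly 1, which
the test suite checks by brute-force enumeration. A response that repeats E1
can arise either from the stay process or from the Bayesian process landing
on E1, so its likelihood is `w + (1 − w)·q[E1]`.

Numerics: the log PMF is computed with `xlogy`/`xlog1py` so that shape
parameters equal to 1 contribute zero (not NaN) at the grid endpoints, and
normalised with `logsumexp`. Single-trial likelihoods are floored at 1e-12
before taking logs so one impossible-looking response cannot drive a
participant's log likelihood to −∞. E1/E2 are rounded to integers for grid
lookup (slider granularity); real-data ingestion rounds non-integer
responses the same way.

### Parameters and bounds

| parameter | meaning | bounds |
|---|---|---|
| α, α_uncertain, α_certain | multiplier turning shown mushrooms into perceived evidence | [0.1, 100] |
| θ (M2a), θ_low/medium/high (M2c) | mushrooms the peer is assumed to have seen | [0.1, 1000] |
| θ_IC, θ_slope (M2b and M3 family) | peer evidence at low confidence, and its increase per confidence step | [0.1, 500] |
| β (and condition-specific variants) | stay-bias mass | [0.01, 0.99] |

θ_IC near 0 means the peer is ignored at low confidence; α far above 1
means small samples are subjectively inflated. The base model M0 fixes
`N_peer = 25`, the average of the two shown counts. M3b's two β parameters
are keyed to the uncertain (5 mushrooms) and certain (45) conditions.

## Synthetic task

The generator reproduces the experimental structure: experiment 1 crosses
2 certainty conditions × 3 confidence levels × 7 true percentages
(12.5 … 87.5) once (42 trials) plus 12 fillers; experiment 2 crosses
2 × 3 × 5 percentages twice (60 trials) plus 15 fillers. Trials are dealt
round-robin to 3 runs within condition, so runs stay balanced on condition,
then shuffled within run; all order depends only on the seed.

Field sampling is a single binomial draw with `n_shown` trials and success
probability `true_pct/100`; showing the mushrooms across five sub-fields is
statistically equivalent because only the total count enters the model. E1
is the seen proportion as an integer percentage — the model's faithful-report
assumption. The peer estimate lies 15–18 points from E1 (integer offsets),
toward the true percentage whenever such a value fits in [0, 100], otherwise
away from it; filler peers are < 3 or > 40 points away in a random feasible
direction. Peer confidence is assigned by the design independently of P:
the original task drew peers from a database of earlier players, whose
confidence–accuracy coupling is unknown and not emulated — a deliberate
limitation of the simulator. Missed trials and response timeouts are not
simulated; the `missed` flag exists for ingesting real sessions.

Simulated E2 responses are drawn from the model's full mixture distribution,
so simulation and likelihood are two views of the same probability model
(the tests exploit this: simulation frequencies must match likelihood
enumeration).

Default parameter ranges for simulation studies — α ∈ [1, 50],
θ_IC, θ_slope ∈ [1, 150], β ∈ [0.05, 0.9], all uniform — are chosen to
bracket plausible fitted values while staying inside the fit bounds, and are
config-exposed. Passing tests on such cohorts shows the machinery is
correct and identifiable under these conditions, not that any particular
human dataset follows the model.

## Exclusions and the model-free regression

Social information use is `s = (E2 − E1)/(P − E1)`, undefined when P = E1.
Trial-level exclusion reasons are assigned with precedence
filler > missed > no-peer > 3 SD outlier > s outside [0, 1]; the paper-style
3 SD rule compares E1 and E2 to their (condition × true-percentage) cell
mean over the full ingested cohort. The cell statistics are cached on the
table so re-filtering a subset (e.g. after dropping participants) remains
idempotent. Participants whose s equals 0 on strictly more than 70 % of
evaluable non-filler trials are excluded (filler trials do not count toward
the denominator); a `flagged_misunderstood` input column lets users honour
manual comprehension screens, which are inherently qualitative and not an
algorithm.

The condition regression fits `s ~ certainty * confidence` with
by-participant random intercepts and slopes for all three terms
(statsmodels `MixedLM`). Confidence is coded −1/0/+1; certainty is coded
−0.5/+0.5 — a centered unit contrast chosen so the interaction term is
interpretable; users preferring ±1 coding can recode the column. If the
full random structure fails to converge or is singular, the fit falls back
to random intercepts only and records the fallback in the result.

## Fitting, BIC, recovery

Fitting is per participant: the NLL over included non-filler trials is
evaluated on a lattice (default 5 points per parameter, log-spaced for
α/θ, linear for β, coarsened whenever the lattice would exceed 10,000
evaluations — relevant only for the 6-parameter M3b), and the best 3 lattice
points seed L-BFGS-B refinement within bounds. Estimates are clipped to the
bounds, and the reported optimum is a fixed point of the objective to 1e-6.
Fitting is deterministic given the data and settings. BIC is
`k·ln(n) + 2·NLL` with `n` the participant's included non-filler trial
count, summed across participants for model comparison — summing
per-participant BICs is invariant to cohort imbalance and matches the
per-participant fitting unit. The comparison table can also replay the
incremental model-building procedure in which each model is accepted only
if it beats the last accepted model's total.

Model recovery simulates a cohort per generating model, fits every model to
every cohort (9 × 9 = 81 fitting procedures at the default family), and
tallies cohort-level BIC winners into a confusion matrix. Recovery studies
default to a reduced fitting configuration (3 lattice points per parameter,
one refined start, 60 optimiser iterations): hundreds of fits at a small,
measured cost in per-fit precision. Cohort sizes are arguments; the
acceptance study uses 10 simulated participants per generating model and the
parameter-recovery study 50, sizes at which the diagnostics are stable on a
single CPU. Some confusion between M3c and M3d (stay bias linear vs
exponential in confidence) is expected — the mechanisms are near-collinear
over only three confidence levels.

Parameter recovery simulates agents with parameters drawn uniformly from
the default ranges on the experiment-2 design, refits, and reports
per-parameter Pearson correlations between true and fitted values; a
zero-variance true vector yields an undefined correlation, reported as NaN
rather than an arbitrary number.

## Model-based regressors

For neuroimaging, three quantities are derived per trial from the fitted
winning-model parameters: own certainty `N × α_condition` (at the first
500 ms of the E1 prompt), peer confidence `θ_IC + θ_slope·(c − 1)` (at the
4 s social-information display), and the belief update as the KL divergence
between the pre- and post-advice beliefs, plus a supplementary stay-bias
regressor `β^c`. Design decisions where the construction was genuinely
open:

* **KL direction** — KL(posterior ‖ prior), the Bayesian-surprise
  convention for "how much the belief moved".
* **Posterior belief for KL** — centred on the *observed* E2 with precision
  from the model-based total evidence (`N_perceived + N_peer` plus the unit
  prior); this respects the participant's actual response while using the
  model's precision estimates. Users comparing against other
  implementations should check this parameterisation and the direction.
* **Finiteness** — grid probabilities are clipped at 1e-10 and renormalised,
  so KL is finite even when the two beliefs barely overlap. KL is strictly
  positive whenever `N_peer > 0`, even for stay responses, because the
  posterior is narrower than the prior — documented behaviour, not a bug.

The discrete-grid KL agrees with the analytic beta–beta divergence to
within ~2 % for moderate shape parameters (verified in the tests); at very
large shapes the 1 %-grid discretisation becomes the limiting factor.

Values are mean-centered within run over the trials entering each regressor;
peer-confidence, KL and stay-bias regressors exclude filler trials (their
deliberately implausible peer estimates may engage different processes),
while the certainty regressor covers all trials. Event files are 3-column
text (onset, duration, amplitude) at 6 decimals; the centered column is
quantised sum-preservingly so each file is zero-mean exactly as written.
Synthetic sessions get a stand-in onset schedule (field viewing, E1 prompt,
social display, jittered ITI); real sessions supply logged onsets.

## Known limitations

* The simulator's peers have no confidence–accuracy coupling, and E1 is a
  noiseless report of the seen sample; both make synthetic cohorts cleaner
  than human data.
* Only the beta-count family is implemented; alternative families
  (e.g. sequential-sampling models) are out of scope.
* GLM estimation, HRF convolution and all downstream imaging statistics are
  out of scope — the package stops at exported event files.
* The mixed regression's full random structure is often singular on small
  synthetic cohorts; the intercept-only fallback then provides the fixed
  effects.
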