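# Methods

## The model

`arbrl` implements a dual-controller account of choice on a two-stage
Markov decision task, in which a model-based (MB) and a model-free (MF)
reinforcement-learning system learn in parallel and an arbitration process
allocates behavioral control between them according to the reliability of
each system's predictions.

**Task.** Each trial starts in a fixed state S1 with a binary choice
(left/right), transitions to one of four second-stage states (left pair
S2/S3, right pair S4/S5), where a second binary choice leads to one of
eight outcome states carrying colored coins (defaults: red 40, blue 20,
yellow 10 points; all configurable). Within a second-stage state the two
actions share the same outcome pair with reversed transition order. A
trial's reward is goal-conditional: under a *flexible* goal every coin
pays its face value; under *specific(color)* only matching coins pay.
Transition noise is blockwise: the first-listed successor of every
(state, action) is reached with probability 0.9 in low-uncertainty blocks
and 0.5 in high-uncertainty blocks. Blocks of the four condition types
(goal kind x uncertainty) are interleaved pseudo-randomly — uniform draws
constrained so no type occurs more than twice in a row — with lengths
uniform on 3–5 trials (low) and 5–7 (high). A subject's run is one
reward-free pre-training session of 100 trials followed by four main
sessions whose block schedules total at least 80 trials each (80–86 in
practice). The default outcome-color layout was chosen so that the
ideal-agent policy at S1 is untied under every goal at low uncertainty and
different goals favor different first-stage actions; nothing in the model
depends on this particular layout, so it lives entirely in the task config.

**Value learning.** The MB (FORWARD) learner maintains a transition model
T(s,a,s') updated from state prediction errors, SPE = 1 − T(s,a,s_observed),
with learning rate α_MB: the observed successor moves toward 1 by
α_MB·(1−T) and each unobserved successor decays toward 0 by the same rate,
which keeps rows normalized (the decay rule is our completion of the
update; only the observed-successor rule is standard). Action values are
planned by backward induction,
Q_MB(s,a) = Σ_s' T(s,a,s')·(r(s') + max_a' Q_MB(s',a')), with r nonzero
only at outcome states and recomputed under the current goal before every
decision — this replanning is what makes the MB system goal-sensitive.
The MF learner is SARSA with rate α_MF on reward prediction errors,
RPE = r + Q_MF(s',a') − Q_MF(s,a) (bootstrap 0 at outcome states); it is
never replanned on goal changes and so carries habit-like insensitivity to
the task structure. Q_MF carries over across sessions within a subject.

**Reliability.** The MB reliability χ_MB is the normalized inverse index
of dispersion of a conjugate Beta posterior over the probability of
"zero-SPE" events: SPEs in a sliding window of 20 events are classified
zero when ≤ 0.2; with prior counts (1,1) and window counts (n0, n1), each
θ_i gets χ_i = posterior mean / posterior variance =
(a+b)(a+b+1)/b for Beta(a,b), and χ_MB = χ_0/(χ_0+χ_1). Threshold,
window and prior are configurable; they are assumptions, since a graded
T makes exactly-zero SPEs measure-zero. The MF reliability uses the
Pearce–Hall associability Ω tracking the unsigned RPE,
ΔΩ = η(|RPE| − Ω), clipped to [0, RPE_max]; χ_MF = (RPE_max − Ω)/RPE_max
with RPE_max defaulting to the maximum coin value (40).

**Arbitration.** The model choice probability P_MB follows a two-state
transition process, dP_MB/dt = β(1−P_MB) − γP_MB, advanced by one Euler
step (dt = 1) per trial after the outcome. Per-trial resolution was
chosen because trial-wise latents are the model's regressor series; a
per-decision update is a straightforward variant we did not implement.
The rates are decreasing sigmoids of the *other* system's reliability:
β = A_β/(1+exp(B·χ_MF)), γ = A_γ/(1+exp(B·χ_MB)), with per-subject free
amplitudes A_β, A_γ and a fixed shared steepness B. P_MB weights both
value integration, Q_arb = P_MB·Q_MB + (1−P_MB)·Q_MF, and — in the
dynamic-exploitation variants — the softmax inverse temperature.
Choices are softmax in Q_arb with inverse temperature τ (max-subtracted
exponentials; likelihood probabilities floored at 1e-12).

**Choice of B.** The functional form of the rate functions is not fixed
by the model class, only their monotonicity; the amplitude-over-sigmoid
form with one free amplitude per direction is conventional. On this task
the two reliability signals live on systematically different scales
(χ_MF typically ≈ 0.6–0.9 because Ω is small relative to RPE_max, χ_MB
typically ≈ 0.2–0.8, swinging with the blockwise uncertainty condition).
A very steep rate function (e.g. B = 10) amplifies that asymmetry beyond
what the amplitude bounds (A ≤ 5) can rebalance, so P_MB collapses to
≈ 0 for essentially all parameter settings, silencing the MB pathway and
rendering τ_MB unidentifiable; a very shallow one (B ≤ 3) leaves P_MB
pinned near its fixed point with little trial-to-trial movement, so the
dynamic-exploitation variants have nothing to explain. We fix B = 6 by
default — steep enough that block-driven χ_MB swings translate into
substantial within-subject P_MB excursions (sd ≈ 0.1), shallow enough
that the fitted amplitudes can balance the two rates. B remains a config
constant (`ArbConfig.rate_steepness`), not a fitted parameter.

## Model variants and fitting

Five nested variants are fitted: `Arb` (shared learning rate α, fixed τ;
k = 5), `Arb_a` (separate α_MB/α_MF; k = 6), and three dynamic-exploitation
extensions of `Arb_a` in which τ depends on P_MB — logistic
τ = c1 + (c2−c1)/(1+exp(−c3(P_MB−c4))) (k = 9), linear τ = P_MB·c (k = 6),
and weighted τ = P_MB·τ_MB + (1−P_MB)·τ_MF (k = 7). Setting
τ_MB = τ_MF collapses the weighted variant exactly onto the fixed-τ
model, and α_MB = α_MF collapses `Arb_a` onto `Arb`; both nestings are
verified exactly in the test suite.

The likelihood replays a subject's logged experience deterministically —
actions and transitions are read from the log, never sampled — summing
−log P(logged action) over the two decisions of every main trial.
Pre-training trials train the transition model and the SPE history but
contribute no likelihood terms by default (`include_pretraining=True`
adds them, modelling pre-training decisions with the current planner and
zero cached MF values). Observation count for the BIC is the number of
likelihood decisions (2 per main trial). Fitting is multi-start
Nelder–Mead in an unconstrained space mapped onto the parameter boxes by
overflow-safe sigmoids — learning rates and c4 onto (0,1), amplitudes
onto (0,5], τ-like parameters onto (0,50], and the logistic upper bound
parameterized as c2 = c1 + gap to enforce c2 ≥ c1. Restarts (default
128) start from uniform draws on [−2.5, 2.5] per transformed coordinate;
in recovery experiments the generating point is injected as restart 0, so
the returned likelihood can never be worse than the truth's. The start
point of each restart is itself kept as a candidate, guarding against
early termination. Models are compared by BIC = 2·NLL + k·ln n and a
group Bayes factor exp(ΣΔBIC/2) over subjects (reported on the log10
scale, since summed BIC differences produce astronomically large factors).

## Behavioral measures

*Accumulated reward* sums main-session points. *Choice optimality* scores
each decision by the likelihood an omniscient ideal agent — greedy over
exact expected values under the true transition probabilities and current
goal, splitting ties uniformly — assigns to the subject's chosen action
(1 for the unique best action, 1/2 under a tie, 0 otherwise), averaged
over both decisions of all main trials; chance is 0.5. *Choice
consistency* is the fraction of first-stage choices repeating the
previous trial's, computed within sessions only. Calibration curves bin
decisions by the model's probability of choosing right; condition
breakdowns report goal x uncertainty cell means with type-II two-way
ANOVA F tests (F reported as 0 in the degenerate zero-variance case).
Score correlations follow the convention: Pearson for behavioral
measures, Spearman for fitted parameters, which are right-skewed by their
lower bound at 0.

## Synthetic cohort

Each synthetic subject receives an integer CES-D score, uniform on 0–40
by default so both sides of the subclinical cutoff 16 are populated, and
true parameters of the weighted-τ model. Two parameters carry the
depression effect through monotone noisy links: η is linear in the
normalized score on the log-odds scale (intercept −2.0, slope +2.5,
Gaussian noise sd 0.35 before the sigmoid), rising from ≈ 0.12 to ≈ 0.62
across the score range; τ_MB is log-linear between anchors 1.2 (score 0)
and 0.02 (top of range) with log-scale noise sd 0.25. The η link uses a
log-odds rather than softplus transform so that the learning-rate bound
at 1 is respected. All other parameters are drawn independently of the
score: α_MB, α_MF ~ Beta(2,2); τ_MF lognormal(ln 0.15, 0.25);
A_β ~ U(6, 10) and A_γ ~ U(0.6, 2.4) — the asymmetric amplitude ranges
compensate for the asymmetric χ scales above, keeping the two transition
rates comparable so arbitration actually moves (this is also why the
amplitude box extends to 10 rather than a tighter cap: with
χ_MF ≈ 0.75 and B = 6, β = A/(1+e^{B·χ_MF}) stays below 0.07 for A ≤ 5,
too slow to track the block structure).

The regime was calibrated to instantiate the phenomena the analyses are
built to detect, which is the generator's job: link magnitudes put the
cohort's CES-D/behavior correlations around the −0.3 to −0.6 band with
robustly negative signs, and the τ anchors and amplitude ranges put
per-subject evidence for the weighted-τ variant at a few nats above its
BIC penalty — the qualitative regime a decisive group-level model
comparison implies. With timid settings (narrow τ split, sluggish
P_MB) the weighted-τ model is empirically indistinguishable from its
fixed-τ and linear-τ rivals, and the recovery analyses are vacuous.

Pre-training is simulated with uniformly random choices and no rewards
(state-space familiarization: only the transition model and SPE history
update); `pretraining_rewarded=True` switches to fully modeled
pre-training trials.

What the generator does *not* emulate: reaction times and timing
variables, within-subject nonstationarity of parameters, attention
lapses, and any neural observables. Passing recovery and
depression-effect tests therefore demonstrates that the analysis code is
correct and that the effects are recoverable under the model's own
assumptions — not that human data would show them.

## Recovery analyses

*Parameter recovery* simulates a cohort, refits every subject with the
generating model, and reports Spearman correlations between true and
fitted values per parameter. Identifiability is uneven by design of the
model class: τ_MB and the learning rates recover well, while η — whose
only behavioral signature is the volatility it lends to χ_MF and hence to
P_MB — and the τ_MB/τ_MF split are weakly identified at single-subject
trial counts (the within-subject spread of P_MB is small, so the two τ
components trade off against each other with little likelihood cost).
*Model recovery* regenerates cohorts from a chosen variant and records
which variant wins the group-BF comparison. *Behavior recovery*
re-simulates each subject from their fitted parameters (default 100
replications), averages the three behavioral measures over replications,
and correlates them with the source cohort's measures across subjects.
The *depression-effect report* chains the full pipeline (sample ->
simulate -> measure -> fit -> correlate) and reports the five headline
correlations plus the group split at the CES-D cutoff.

## Numerical and scale choices

Likelihood evaluation and simulation run through a compiled (numba)
kernel; the pure-Python agent built from the documented operations is the
reference implementation, and the test suite holds the two routes (plus a
third, independently written dictionary-based replay oracle) to within
1e-9 of each other. Default test and acceptance runs use reduced problem
sizes — e.g. recovery with 15–24 subjects and 8–16 restarts rather than
128 — chosen so the full pipeline remains quick on a single core while
leaving every qualitative conclusion unchanged; the full-scale settings
are plain arguments.

## Known limitations

- The empirical-Bayes reliability hyperparameters (window 20, threshold
  0.2, prior (1,1)) and the rate steepness B are conventions, not fitted;
  conclusions about χ_MB dynamics are conditional on them.
- η and the τ_MB/τ_MF decomposition are weakly identified from ~420
  trials; group-level correlations with fitted η are correspondingly
  noisy.
- The Bayes factor is the BIC approximation, not a marginal likelihood.
- The ideal agent assumes instantaneous knowledge of block changes, so
  measured "optimality" is conservative around block boundaries.
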