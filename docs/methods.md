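# Methods

This note documents the models implemented in `groomchoice`, the choices
made where the underlying methodology leaves latitude, and what the
synthetic-data calibration does and does not establish.

## Dominance: sequential Elo with daily ordinal standardization

Dominance hierarchies are estimated from unidirectional submission
signals (pant grunts in chimpanzees, non-aggressive supplants in
mangabeys). After each decided signal the winner gains and the loser
loses `k * (1 - E)` points, with `E = 1 / (1 + 10^((r_loser - r_winner) /
scale))`. Defaults `start = 1000`, `k = 16`, `scale = 400` are the
conventional rating parameters; they are configuration, not claims. The
update is zero-sum, so the score total is conserved over any event
stream (tested to 1e-9 over 10^5 events).

Only *daily ordinal* ranks feed the analysis: on each day the pool's
scores are ranked, ties get the mean of their ordinal positions, and the
result is scaled so the lowest individual is 0 and the highest 1. Any
strictly monotone transform of the raw ratings therefore leaves the
downstream analysis unchanged, which is why the classical constant-k
update suffices: refinements such as burn-in windows or likelihood-tuned
k would alter scores but not daily orders in any way that matters here.
Decisions on a day use that day's end-of-day scores (rank tables are
daily objects; no intra-day rank updates). Individuals without observed
signals sit at the start score — no imputation — and a singleton rank
pool returns the degenerate value 0.5.

Two views are exposed: the global rank over the whole community and the
relative rank over exactly the individuals present at a decision. By
construction, restricting to the full community reproduces the global
ranks (tested as an identity).

## Affiliation: the Dynamic Dyadic Sociality Index

Each unordered dyad carries a value in (0, 1), started at 0.5.
Socio-positive events (grooming; resting/feeding within 1 m) move the
value a fraction `w` of the remaining distance towards 1, once per
started duration unit (default 60 s — so a 3-minute grooming bout counts
three updates); directed aggression moves it the fraction `w` towards 0,
once per event. Defaults `w = 0.05`, equal behaviour weights. The exact
constants of the published index family are not recoverable from the
source description, so they are explicit configuration with these stated
defaults; the qualitative contract — increases after socio-positive,
decreases after socio-negative, bounded in (0, 1), symmetric in the dyad
— is property-tested.

Choice covariates use the value at the end of the *previous* calendar
day, making the covariate strictly independent of the bout being
analysed. The audience covariate is the maximum of the candidate's
values with the bystanders (present adults minus focal minus candidate);
with no bystanders it is 0.0 plus a degenerate-row flag, encoding "no
strong social partner present" while letting users sensitivity-check the
convention. The party-relative relationship value is the ordinal 0–1
standardization (ties averaged) of the focal's values across the
candidate set; this construction is a documented interpretation, since
the source only states that relative analogues were used.

## Choice-set construction

A grooming record counts as an *initiation* only if the actor was not
groomed by anyone in the preceding 2 minutes (configurable); otherwise it
is treated as a response rather than a choice. Initiations of one focal
separated by less than 5 minutes form a session; only the first choice
per session is analysed. Subadults are excluded throughout — as targets,
candidates and bystanders. Windows are half-open: the aggression
look-back is [t − 30 min, t), and the session rule splits at gaps of
exactly 5 minutes.

Quantitative covariates are z-standardized (n−1 denominator) over the
final table; a zero-variance column is an error naming the column. The
squared partner-rank term defaults to the square of the standardized
rank, which centres the quadratic; the square-then-standardize variant is
available as a switch for sensitivity analysis. The offset is
log(1/n_candidates). The relative-rank pool includes the focal (it is
present); a config flag restricts the pool to candidates only.

## The partner-choice model

With exactly one chosen candidate per session, a binomial logit with a
session intercept and the log(1/n) offset is likelihood-equivalent to a
conditional (session-stratified) logit, in which both the intercept and
the offset cancel exactly. That conditional logit is the primary backend:
Newton–Raphson on the exact log-likelihood with analytic gradient and
Hessian, gradient tolerance 1e-8, at most 500 iterations, backtracking
line search, standard errors from the observed information. At β = 0 the
log-likelihood equals Σ_s log(1/n_s) — the uniform-choice baseline —
which is asserted exactly, and per-session fitted probabilities sum to 1
by construction. Divergence (|β| above 15 with a vanishing gradient, or
above 40 mid-iteration) is reported as probable complete separation,
never returned as an estimate. Sessions with a single candidate are
uninformative under this backend and are dropped with a count.

Covariate columns with no within-session variation — the control
predictors: focal sex, group identity, focal-rank main effects — are
absorbed by the stratification; the backend detects and removes them,
recording the list in the result. Degrees of freedom for nested
comparisons are computed from estimable-parameter counts, so the
full–null test automatically spans only the terms the stratified design
can identify.

A mixed-effects backend (crossed random intercepts for focal, partner,
dyad and session; optional random slopes) is provided behind the same
interface via `lme4::glmer` (binomial, logit link, bobyqa), the standard
tool for this model class; its fixed-effect estimates agree with the
conditional logit on simulated data within sampling noise.

Model specifications mirror the two study designs: the all-communities
design interacts every test predictor with group identity, with focal
sex × partner sex and partner sex × group as controls; the
chimpanzee-only design interacts test predictors with focal sex, adds
the sex × sex × group three-way control, and enters prior aggression
without a sex interaction (too few female cases to support it).
Categorical coding is treatment coding with references "other"
(reproductive state), female, and the alphabetically first group.

Single-term deletion respects marginality: a term is droppable only if
its factor set is not a proper subset of a retained term's. VIFs come
from a fixed-effects-only linear design with main effects and no
interactions (perfect collinearity reported as infinite with a warning).
Stability checks refit the model leaving out one level of a chosen
grouping factor at a time; sessions that lose their chosen row drop out
entirely, per-level non-convergence is recorded rather than fatal, and
levels whose exclusion flips a coefficient sign are flagged. P-values are
reported unadjusted.

## The synthetic group

`simulate_group` is the study-condition generator. Defaults, chosen once:
5 adult males and 8 adult females (within the observed 12–24 adult range
of the motivating communities), 60 days of 8 presence scans, dominance
signals at 8/day with noise ε = 0.05 (a signal goes against the latent
order with probability ε), aggression 4/day, affinity-weighted proximity
bouts 25/day, one grooming decision per focal per day.

Party composition follows independent two-state Markov chains per
individual; `presence_persistence` is the probability of staying present
between scans, and the rejoining probability is set so the stationary
presence probability equals the profile's mean gregariousness (0.55
chimpanzee-like, 0.85 mangabey-like). This single-parameter process
reproduces weak versus strong fission–fusion; it is not a movement
model, and party membership is independent across individuals, which
real travel parties are not.

Latent affinity is sparse and bond-structured: a weak Beta(1, 4)
baseline with each individual nominating two partners lifted to
Beta(8, 3) bond strength. This mirrors the empirical shape of grooming
networks — most dyads weak, a few strong bonds — and is what makes the
maximum-bystander covariate informative: its within-session variation is
driven by whether a candidate's bond partner happens to be present.

Grooming decisions are drawn from a multinomial logit over ground-truth
covariates (party-relative latent rank, dyadic affinity, maximum
candidate–bystander affinity, reproductive state, 30-min prior
aggression) with true coefficients defaulting to (+1.0, +1.0, −0.8,
+1.0, +0.3, +1.0) — matching the two headline directions under study: a
preference for locally high-ranking partners and avoidance of partners
with a strong bystander relationship. Females cycle (35-day cycle, 10
tumescent days, random phase) and give birth at 0.002/day, entering the
young-infant state for 90 days. The mangabey-like profile suppresses
male-initiated grooming entirely, so downstream code is exercised
against structurally absent strata. Decision timestamps occupy fixed
per-focal slots in the first half of each scan, which keeps same-focal
decisions well clear of the 5-minute session boundary and makes the
simulator's emitted decision count exactly recoverable by the extractor
— a deliberate round-trip property, at the cost of slightly stylized
timing. A single seeded generator drives all sampling; identical config
and seed give byte-identical logs.

`simulate_choice_study` generates (session × candidate) tables directly
from the same latent structure, skipping the event-log layer. The
replicate-heavy calibrations run on it: with 200 null replicates of 300
sessions the drop-one LRT p-values are uniform (KS) and the type-I error
is nominal; with 100 replicates of 500 sessions the two headline
coefficients are recovered in sign and covered by 95% Wald intervals at
their nominal rates. These sizes were chosen to give stable Monte-Carlo
estimates at desk scale. What passing shows: the inference machinery is
correctly calibrated when the model is correctly specified. What it does
not show: robustness to the misspecifications real data carry —
observation error in presence sets, time-varying preferences, kinship
structure (not modelled at all), or dependence between party composition
and the choice process.

## Known limitations

- The Elo and DDSI parameter defaults are conventions; analyses relying
  on cardinal index values (rather than daily orders) should
  sensitivity-check them.
- The conditional-logit backend cannot estimate session-constant effects
  (by design); use the mixed backend when those are of scientific
  interest.
- The mixed backend requires an R installation with lme4 and currently
  reports a diagonal covariance (Wald SEs per coefficient only).
- The simulator has no spatial structure, no juveniles, no seasonality,
  and no kinship; its party process is stationary.
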