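# Methods

`flocknet` implements an analysis chain for RFID feeder data from a
closed, pedigree-monitored bird population: infer social associations
from arrival times, summarize each bird's network position, attach
pedigree-based fitness, and ask whether sociality is repeatable and
under selection. A seeded generator produces synthetic populations so
the whole chain is testable end to end without field data. This note
records the models, the choices that were genuinely open, and what the
synthetic experiments do and do not demonstrate.

## Arrival inference

The raw observable is a stream of (timestamp, tag, antenna) detections
at a single feeder. Per bird, detections are partitioned into *bouts*:
a detection opens a new bout when the gap from the previous detection
strictly exceeds the absence threshold `delta_i` (default 300 s — the
rule is "absent for more than 300 s", so a gap of exactly 300 s does
not split a bout). The bout's first detection is the *arrival*.

Three association definitions operate on the same stream:

* **arrival time** (the primary method): two birds are associated when
  their arrivals fall within `delta_t` of each other (default 150 s,
  inclusive — "within 150 s" is read as a closed interval). The rule
  is dyadic and deliberately non-transitive: A–B and B–C do not force
  A–C, unlike group-based definitions.
* **gambit of the group**: single-linkage clustering of arrivals in
  time; every within-group dyad is associated. At a busy feeder this
  chains separate flocks together and overestimates associations —
  the package reproduces that contrast as a test fixture.
* **time-window overlap**: presence intervals `[arrival, bout_end +
  delta_t]` that intersect. Under near-continuous visitation this
  yields chain-like networks (first bird linked to second, second to
  third, ...), also reproduced as a fixture.

Counting: a dyad accumulates one count per matched co-arrival across
the window, with greedy one-to-one matching in time order so one
arrival of A cannot be counted against several bouts of B; hence
`x_ab <= min(n_a, n_b)`. A `binary_per_window` option caps each dyad
at one count per window instead; per-co-arrival counting is the
default because the Simple Ratio Index needs accumulating numerators.
The greedy matcher is verified exactly against an independent
brute-force all-pairs matcher on 1000 random streams.

Windows: weekly networks use half-open 7-day blocks anchored at each
event's start; a bout belongs to the week of its arrival. Detections
outside every event window are dropped with a logged count.

## Networks and centrality

Dyadic weights are Simple Ratio Indices,
`SRI_ab = x_ab / (x_ab + y_a + y_b)` with `y_a = n_a − x_ab`, i.e.
joint arrivals over occasions either bird arrived; 0 means never
together, 1 always together. Because the sampling unit is an arrival
rather than a survey scan, there is no "both observed apart in the
same period" term in the denominator. Networks are undirected,
weighted, never thresholded; only birds that arrived in at least one
dyad (degree > 0) are vertices.

Per bird and window the package computes degree, strength,
eigenvector centrality and opposite-sex degree. Strength is the
scaled transform `S_i = d_i * (sum_j SRI_ij) / N(V)` ("net association
quality": the summed index weighted by connectedness relative to
network size). The printed form of this transform is typographically
ambiguous in its source; the scaled product above is the
implementation's reading, and the plain summed SRI is available via
`strength_definition="sum"`. Eigenvector centrality is the dominant
eigenvector of the full weighted adjacency normalized to a maximum of
1 (the igraph convention, which makes event-level values comparable
across networks); on a disconnected network the dominant component
carries the scores and the condition is logged. Opposite-sex degree is
the bird's degree in the bipartite sub-graph that retains only
male–female edges (same-sex edges are removed *before* that
sub-graph's degree filter); it is a count of opposite-sex associates,
not a summed weight.

## Fitness

A *recruit* is an offspring that survived and produced genetic
offspring itself, read off the pedigree (an individual is a recruit
iff it appears as a parent). Annual recruits of bird i in breeding
year t are its offspring born in t that became recruits. Exclusions
follow the field protocol: birds dead before the breeding season are
absent rows (not zeros), as are yearlings with zero recruits.
Lifetime recruits are censored at a configurable final pedigree year.

De-lifed fitness is the individual's contribution to realized
population growth:

    p_ti = (xi_t(i) − w_t) / (N_t − 1)

with `N_t` the April census, `w_t = N_{t+1}/N_t`, and `xi_t(i)` =
(offspring share) × (surviving offspring of i born in t) + 1 if i
itself survived to the next April. The offspring share defaults to
0.5 — each surviving offspring is split between its two genetic
parents — because that is the convention under which a closed, fully
censused population satisfies `sum_i p_ti = 0` exactly each year. The
package asserts this conservation identity to 1e-10 on simulated
pedigrees; it is the sharpest available detector of census or
parentage bookkeeping errors. A share of 1.0 (full credit to each
parent) is available behind a flag. "Survived to the following
breeding period" is operationalized as alive on April 1 of t+1.
Lifetime de-lifed fitness is the within-individual sum of p_ti. The
published convention of reporting p_ti only for birds with at least
one recruit is an output filter (`recruits_only`), never a
computation change.

## Mixed models and the sampler

Repeatability of a weekly centrality measure is estimated from a
Gaussian intercept-only mixed model with a bird-level random
intercept; `R = V_id / (V_id + V_res)` is formed per posterior draw
and summarized by its kernel-density mode and central 95% credible
interval. Selection models take one sociality measure at a time (the
four measures are strongly correlated, so they are never entered
jointly):

* annual: `response ~ c + c² + sex + age + age² + age:sex +
  (1|bird) + (1|cohort)`
* lifetime: `response ~ c + c² + sex + lifespan + lifespan:sex +
  (1|cohort)`

Recruit counts use a Poisson log link; de-lifed fitness is Gaussian.
Centrality covariates are mean-centered within year before fitting
(removing between-year level differences); age is left uncentered. A
fixed effect is "significant" when its central 95% credible interval
excludes zero.

The sampler is written in-package in the MCMCglmm tradition: location
effects (fixed + all random intercepts) are drawn jointly from their
Gaussian full conditional using the auxiliary-data perturbation trick,
with the largest random factor handled as a diagonal block through its
Schur complement (a draw costs O(n + q)); variance components get
inverse-gamma full conditionals from scalar inverse-Wishart priors
(V = 1, nu = 0.002 — weakly informative; configurable). Poisson
responses introduce a latent log-rate field `l` with
`y_i ~ Poisson(exp(l_i))` and `l = Xb + Zu + e`: the observation-level
residual e doubles as additive overdispersion, and `l` is updated by a
vectorized site-wise random-walk Metropolis step whose scale adapts
toward 44% acceptance during burn-in only (so the retained chain is a
valid fixed-kernel sample). Fixed effects carry a flat-ish Gaussian
prior (variance 1e8). Variance draws are clipped to [1e-12, 1e12] as
a numerical guard; a chain pinned there fails the diagnostics rather
than crashing. The default contract mirrors the published analysis —
343,000 iterations, burn-in 3000, thinning 200 (1700 retained) — and
every fit reports per-parameter lag-1 autocorrelation and effective
sample size (Geyer initial monotone sequence), with pass thresholds
|r1| < 0.1 and ESS >= 1000. Gaussian fits are validated against a
REML oracle (statsmodels MixedLM) on balanced designs; Poisson fits
against parameter-recovery experiments.

A note on identifiability: in a single-year annual fit the cohort
factor is a function of age, and with one observation per bird the
bird-level variance is confounded with the overdispersion residual.
The synthetic experiments therefore always simulate at least two
breeding years; real multi-event data has the same structure.

## Null models and dominance

The node-permutation null shuffles the identity column of the arrival
table across rows (within event by default, within week optionally).
This exactly conserves the multiset of arrival times, the multiset of
identities, *and each bird's arrival count*, while randomizing who
arrives with whom. Null centralities are summarized per bird by the
mode across permutations — exact mode for integer measures, the
recursive half-sample mode for continuous ones (the half-sample
estimator is robust and deterministic given samples; a binned mode
would add a bandwidth choice for no benefit). Selection refits on
these modal null centralities are the package's null pipeline.
Refitting on a *single* permuted network is also provided (and used in
the attenuation experiment), but with precise fits it can reach
significance through chance alignment of one shuffle with the latent
trait — the reason the modal design exists.

Elo dominance ratings use the behavioural-ecology convention (start
1000, k = 100): the winner gains `k(1 − p_win)` with
`p_win = 1/(1 + 10^((R_loser − R_winner)/400))`, so total rating is
conserved exactly. Dominance–centrality association is a Spearman
rank correlation with a two-sided permutation p-value; null-model
centralities are excluded from these correlations by construction.

## Synthetic data

The generator emulates the study system at its default settings: a
closed island population (~150 founders across three pre-study
cohorts), annual monogamous breeding with Poisson offspring numbers
and a constant adult annual survival of 0.6 (mean adult lifespan
around the three years reported for the system), a single feeder
recording 06:00–24:00, and two non-breeding events of 15 and 13
weeks. Flocks arrive as a Poisson process within operating hours (the
source describes no generative model; a Poisson process is the
simplest mechanism producing clustered arrivals), members join with
Gaussian jitter (SD 20 s) around the flock's arrival time, and each
arrival spawns a short detection bout, with re-arrivals separated by
more than the 300 s absence criterion plus an exponential revisit gap.

Latent sociality is a standard-normal propensity per bird; weekly
realizations mix the stable part with weekly noise to hit a target
intraclass correlation (default 0.3, matching the observed
repeatability range of the system). Two design choices matter:

* Sociality expresses itself through the probability of arriving
  *with* the flock versus solo (a logistic map around the population
  concentration, default 0.9). Attendance effort is flat by default.
  This is deliberate: a count-preserving node permutation conserves
  effort, so a generator in which sociality drove visit *rate* would
  make the null model structurally unable to break the
  sociality–fitness link. In the generator, central birds are central
  because of whom they arrive with — which is exactly the channel the
  permutation destroys.
* At a busy feeder most birds end up linked to most others at least
  once, so raw degree saturates and carries little signal; the
  SRI-weighted measures (strength) carry the flock structure. The
  coupled-experiment suite therefore uses strength as the measured
  sociality phenotype. This mirrors the real system, where event
  networks contained more than half of all tagged birds.

Fitness coupling draws recruits from
`Poisson(exp(b0 + b1 c + b2 c² + b_sex·sex + b_age·age + e))` (or the
Gaussian analogue for de-lifed fitness), with `c` any chosen
sociality covariate — the latent truth in the end-to-end experiments,
or an arbitrary observed measure. The optional `e ~
N(0, overdispersion_sd)` term (default 0) adds log-scale
overdispersion; the recovery experiments set it to 0.3 so the
generated counts lie in the model class being fitted (Poisson with an
observation-level latent residual) and resemble wild recruit data,
which is invariably overdispersed. This matters for the sampler too:
with exactly Poisson counts the latent residual variance collapses
toward zero and the latent field freezes (a known degeneracy of
latent-field samplers), producing overconfident intervals.

Two further experiment-design choices concern the null model. The
permutation conserves each bird's arrival count, so any component of
a centrality measure that is a function of sampling effort survives
permutation; a meaningful null experiment must keep effort orthogonal
to sociality. Beyond the flat attendance default, the controlled
null experiments also set `fixed_daily_arrivals=True`, replacing each
flock's Poisson number of daily arrival bouts with its expectation —
otherwise flock-level effort variation (shared by all flockmates)
correlates with flock-mean sociality at an effective sample size of
the number of flocks, a heavy-tailed chance channel that null refits
duly detect.

What the synthetic experiments show: the estimators recover known
repeatability (ICC 0.30: 95% CI coverage >= 90/100 replicates) and
selection gradients (linear 0.25 and stabilizing −0.15: sign,
significance and coverage >= 90/100), false-significance stays at the
nominal level under zero coupling, the de-lifing identity holds to
machine precision, and the null pipeline removes a genuine
sociality–fitness coupling. What they do not show: that the real
system satisfies the generator's assumptions (no spatial structure,
single antenna, no weather or seasonal covariates, no dominance
effects on arrival order, pedigree error-free). Published numeric
values from the real dataset (network sizes, Table-level posterior
summaries) are not reproduction targets here — they require the
deposited data.

## Problem sizes and numerical choices

The validation experiments run at desk scale by design: recovery
suites use a shortened sampler with the same shape as the published
contract (6000 iterations, burn-in 1000, thinning 5, >= 1000 retained
draws), 100-replicate recovery loops, and 50–100 permutations per
null refit. Posterior modes come from a Gaussian KDE on a 512-point
grid; degenerate (zero-variance) chains return their value directly.
Ties in the exact integer mode resolve to the smallest value via the
argmax convention. Empty weeks are retained as empty slices so
repeatability models see missing weeks as absent rows. Timestamps are
timezone-naive integer seconds (local feeder time).

## Known limitations

* The Poisson latent-field Metropolis step mixes more slowly than the
  Gaussian conjugate updates; at the shortened contract some
  parameters sit below the ESS >= 1000 bar and fits are flagged
  accordingly rather than hidden.
* The single-permutation null refit is kept for the attenuation
  experiment but should not be used for inference (see above).
* The generator's flock structure is static (no membership turnover
  within an event) and all flocks share one feeder; spatial processes
  are out of scope.
* Elo parameters follow convention rather than estimation; ratings
  are sequence-dependent and no bootstrap over orderings is provided.
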