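# Methods

This note records the models, the defaults and why they were chosen, the
numerical decisions, and what the synthetic-data tests do and do not
demonstrate.

## Event model and bout segmentation

A trial is a fixed-duration (default 14,400 s) dyadic encounter scored on
a snapshot grid (default 5 s). Events carry an actor, a behavior from a
closed vocabulary — the non-contact approach `proximity`, seven physical
behaviors (`touch, bump, head, mount, grapple, chase, flip`), and the
explicit `end` of an interaction — an onset and a duration. Ties in
onset (likely under snapshot scoring) are broken deterministically by
(onset, actor, behavior) so all downstream structure is reproducible.

A *bout* is the unit over which transitions are counted: a contiguous
run of events closed by an `end`. Since observers may not score an `end`
after every disengagement, a configurable inter-onset gap (default 30 s
= six snapshots) also closes a bout; a zero-duration `end` flagged
`synthetic_end` is then appended so every terminated bout ends in `end`,
and such events are excluded from frequency tallies and count panels.
Segmentation is idempotent on its own output. An approach that leads
nowhere is retained as a one-event proximity bout; these "proximity-only"
bouts are a reported quantity (share of initiated interactions) and must
therefore be countable.

Interaction time is the length of the union of all event spans in a
trial divided by trial duration; overlapping spans (the two females act
simultaneously) count once. Interval arithmetic is exact, not
rasterized; tests compare it against a 1-s-grid oracle.

## Transition analysis

Within each bout, runs of the same behavior are collapsed to one state
(default), making the diagonal structurally zero; each ordered adjacent
pair increments one cell of the count matrix. Sources are proximity plus
the physical behaviors; targets additionally include the absorbing
`end`. Per-trial matrices from round 1 only are summed by default to
avoid pseudoreplication (each female appears in all three rounds); other
rounds can be pooled by flag.

Cell-wise significance uses Haberman adjusted standardized residuals
with a two-sided normal critical value at α = 0.05, the standard choice
in lag-sequential analysis. Structural zeros are excluded from testing
but simply carried as zero cells in the marginals; quasi-independence
fitting is *not* implemented — a documented simplification that leaves
the test slightly conservative for collapsed-repeat matrices (the
Monte-Carlo calibration tests use tables without structural zeros, where
the flag rate at α = 0.05 sits in [0.03, 0.07]). A seeded permutation
alternative (row sums fixed, targets resampled from the pooled column
marginals, two-sided p on |O − E|) is available for small tables. No
multiple-testing correction is applied by default; Bonferroni across
tested cells is available behind a flag.

Transition probabilities are row-normalized counts — the maximum-
likelihood estimate of a first-order Markov chain. Rows never observed
as a source are flagged undefined (NaN), never silently uniform.

## Aggression classification

A behavior is aggressive when its statistically supported modal
consequence is that the interaction ends immediately: the (b → end)
cell must be significant with positive residual *and* `end` must be the
argmax of b's transition probabilities. Requiring the conjunction is the
conservative reading of "significant transitions to ending" plus "most
frequently resulted in ending". `mount` is always its own category
(mounting occurs in both courtship and same-sex contexts); `end` is
terminal; a behavior never observed as a source is nonaggressive with a
warning (absence of evidence).

`proximity` is deliberately excluded from aggression candidacy. In an
approach-then-leave sequence the *initiator* withdraws; nobody was made
to flee, so the operational definition of aggression (a behavior that
makes the partner leave) does not apply — even though proximity → end is
typically the most over-represented transition in a dataset where ~half
of approaches lead nowhere. Treating proximity as a candidate would
mechanically label approaching "aggressive" in precisely the datasets
that show the least interaction.

## Repeatability (ICC)

Per-behavior response: the count of initiations by each female in each
trial (durations are a possible alternative response, not implemented;
discrete acts are the natural unit for the behaviors modeled). The model
is a log-link Poisson GLMM with female and trial random intercepts and
an observation-level latent residual (the Poisson-lognormal
overdispersion device):

    y_ij ~ Poisson(exp(mu + a_f + b_t + e_ij)),
    a ~ N(0, V_female), b ~ N(0, V_trial), e ~ N(0, V_resid).

Priors: scaled-inverse-χ²(ν = 0.002, V = 1) on each variance (the
conventional "noninformative" default in this modeling tradition;
configurable) and N(0, 100) on μ.

Sampler: Metropolis-within-Gibbs, self-contained and compiled with
numba. The Poisson likelihood admits no conjugate update for the
latents, so e, a, b and μ are updated by random-walk Metropolis — the
latent blocks in parallel, which is valid because the likelihood
factorizes over observations and each observation touches exactly one
female and one trial effect. Step sizes adapt toward 0.44 acceptance in
windows of 50 iterations *during burn-in only* (so the retained chain is
a fixed-kernel Markov chain). Variance components have exact conjugate
scaled-inverse-χ² draws given the latents. The linear predictor is
clipped at 30 inside the exponential to prevent overflow; non-finite
variance draws abort with diagnostics. One root seed fans out to
per-behavior streams via SHA-256, so a pipeline run is reproducible from
a single integer.

Run lengths: the desk-scale default is 50,000 iterations, thinning 10,
burn-in 500; a long reference preset (500,000 / 100 / 5,000) retains the
same 4,950 draws, and the test suite checks the two agree on the
posterior-mean ICC to < 0.02 on a fixed dataset.

ICC is computed per retained draw on the latent (log) scale as
V_female / (V_female + V_resid) — trial variance excluded from the
denominator by default, matching the convention of reporting individual
repeatability against residual variance; flags add V_trial and/or the
observation-scale correction (which adds the Poisson sampling variance
term log(1/E[count] + 1) to the denominator). The 95% HPD interval is
the shortest contiguous window over the sorted draws.

Known estimator behavior, verified in the tests: (i) with very sparse
counts (≲ 0.5 events per female-trial) the latent-scale ICC is weakly
identified — posterior means drift and HPD intervals span nearly [0, 1],
exactly the pattern real sparse behaviors show; (ii) on null data the
posterior mean of the variance *ratio* is positively biased at modest
sample sizes (a handful of percent at 200 females × 3 trials, more at
47 females), so the honest evidence statement for "not repeatable" is
the lower HPD bound reaching ~0, not a small posterior mean; (iii) with
exactly constant counts both V_female and V_resid collapse to the prior
floor and the latent-scale ratio is indeterminate — the observation-scale
ICC is the quantity that is near zero there.

## Resource use

Patrolling for a female in a trial is |her on-fungus intervals minus her
partner's| by exact interval intersection; any positive alone time makes
her a patroller (a minimum-dwell threshold is configurable but defaults
to zero, since no dwell criterion is part of the measure's definition).
Body size (elytra length, the only size measure) is compared between
patrollers and non-patrollers with Welch's unequal-variance t-test
(Satterthwaite df); total initiated behaviors in each female's first
trial with the Mann-Whitney U test, since counts are not normal. The
reported W follows the convention W = #{(x, y): x > y} + ½·ties (the
value standard statistical environments print for the first sample);
the default p uses the normal approximation with tie and continuity
corrections, and an exact tie-aware enumeration over group assignments
is available for n₁ + n₂ ≤ 12. "First trial" is strictly round 1 for
the panel selector (error if absent), while the full-design analysis
uses each female's earliest round, because with an odd paint split one
female sits out each round.

## Synthetic data

The generator emulates the study design: 47 females (24 white / 23
black), three rounds of random white-×-black pairings (23 dyads per
round; one female sits out), 4-h trials on a 5-s grid. Each female
initiates her own Poisson number of bouts at rate (bout_rate/2) ·
exp(a_f + b_t + e_ft), so among-female variance in counts is controlled
by V_female_true and the planted latent ICC is known. A bout is
proximity-only with probability `proximity_only_prob`, otherwise a
realization of the configured chain from the start distribution until
`end` (the preset matrices encode the same proximity → end share in
their proximity row, so both routes give one consistent transition
structure). Dwell times are geometric on the snapshot grid, capped at
five snapshots so within-bout gaps never trigger the 30-s bout-splitting
threshold; bouts are laid out left-to-right with at least two empty
snapshots between them. Occupancy intervals are generated independently
of behavior (patrolling is its own scored measure, not inferred from
events).

Defaults are chosen to resemble the study's reported scale: bout_rate 10
and geometric dwells of ~10 s give ~3% of trial time interacting;
proximity_only_prob 0.48; the `null_female` behavior shares put bump at
~33% of physical behaviors, grapple at zero; patrol_prob 0.15 with
exponential mean 3600 s gives ~9 min mean patrolling per female-trial
and roughly half the females patrolling at least once over three
rounds. The `male_like` preset plants grapple/chase/flip with
P(b → end) = 0.6 (modal and strongly over-represented), higher
interactivity, and V_female = 0.8 vs V_resid = 0.2 (latent ICC 0.8).
The baseline log count μ = 1.5 used by the direct panel generator gives
mean counts around 5–10, enough Poisson information to identify the
observation-level residual variance.

What the simulator does *not* emulate — and therefore what passing
recovery tests do not show about real data: spatial movement and
partner-dependent strategy switching (behavior is first-order Markov
with a fixed chain, while real sequences may be state-dependent at
longer lags); actor alternation within bouts (all events in a simulated
bout are attributed to its initiator); observer error and missed scores;
any correlation between patrolling and behavioral interaction (they are
generated independently); and the real study's exact 71-trial pairing
scheme (the generator produces 3 × 23 = 69; the scheme behind 71 is not
described).

## Problem sizes in the test suite

Recovery checks run at desk scale, chosen to finish in minutes on one
CPU while leaving comfortable statistical margins: 500 bouts for
transition-matrix recovery (sup-norm tolerance 0.05), 1,000 tables of
sizes 3–9 for null calibration, 100 replicates × 300 bouts per preset
for classification recovery, and 20 seeded fits at 200 females × 3
trials (desk-scale MCMC settings) for ICC recovery. End-to-end
determinism is checked by byte-comparing two pipeline runs on a
12-female fixture.

## Known limitations

- Quasi-independence is not fitted for structurally-zero diagonals; the
  cell test is mildly conservative on collapsed-repeat matrices.
- The latent-scale ICC is unidentified for behaviors with almost no
  counts; reports should lean on the HPD interval, not the mean.
- The Mann-Whitney exact path is limited to n₁ + n₂ ≤ 12 by its
  enumeration cost.
- The simulator's bout layout truncates bouts that would overrun the
  trial end (< 1% of bouts at default rates).
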