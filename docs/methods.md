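# Methods

## Setting and notation

A player's game is an ordered sequence of binary shot outcomes
S ∈ {M, X}ⁿ (M = make, X = miss) with an associated probability vector
P ∈ (0,1)ⁿ, where pᵢ is a model's estimate of Pr[sᵢ = M] given the shot's
context (distance to the basket, defender distance, touch time,
dribbles, shot type).  Shots are modelled as **independent but not
identically distributed** Bernoulli trials — a heterogeneous Bernoulli
process.  The hot-hand hypothesis is serial dependence on top of that:
the make probability after k consecutive makes exceeding what shot
quality alone predicts.

A **follower** at streak length k is a shot whose k immediately
preceding shots *in the same game* were all makes; streaks never span
games, and overlapping streaks each count (sliding window — a run of m ≥
k makes yields a follower at every position preceded by ≥ k makes).
The observed conditional rate is

    Pr[M | M…M (k)]_data = (follower makes) / (followers),

pooled over all of a player's games, and is undefined (an error, never a
silent 0) when there are no followers.

## Why the naive statistic misleads: streak selection bias

Even for iid trials, the expected proportion of successes among
followers in a finite sequence is below the success rate.  For a
sequence of n trials with exactly M successes, both the
"pick-a-random-success, look at the next trial" probability and the mean
over all arrangements of the per-sequence k = 1 conditional statistic
(undefined arrangements excluded) equal

    (M − 1) / (n − 1)  <  M / n,

a sampling-without-replacement effect: the success conditioned on is
itself removed from the pool.  `nulls.perm_mean_closed_form_k1` exposes
the closed form; `nulls.exhaustive_conditional_mean` verifies it by
enumeration (the tests check every composition with n ≤ 10), and
`nulls.selection_bias_probability` computes the selection experiment
exactly, by enumeration, or by Monte Carlo.  For k > 1 streak overlap
adds a further restriction; the enumeration oracle covers that case too
and the test suite checks the bias is never positive.

## The three nulls

**Permutation null** (`permutation_conditional_distribution`): outcomes
are shuffled uniformly *within each game* (per-game make/miss
composition preserved — games are the unit of analysis) and the pooled
conditional statistic recomputed per replicate.  Valid when shots are
exchangeable; it removes the selection bias by construction.  Replicates
with zero followers are excluded from the empirical distribution and
their count reported.  The empirical p-value is the fraction of defined
replicates ≥ the observed statistic; ties count as extreme by default
(the strict `>` convention is available via `tail="gt"`).

**Heterogeneous-Bernoulli simulation null**
(`simulate_conditional_null`): when shots differ in difficulty,
permutation is invalid, so each *follower* shot is instead re-drawn as
an independent Bernoulli(pᵢ).  Only shots that actually follow streaks
in the data are simulated — conditioning is taken from the real
sequence, which avoids biases from streaky situations differing
systematically from non-streaky ones.  Each replicate's statistic is a
Poisson-binomial success fraction with mean mean(pᵢ).

**Runs test** (`wald_wolfowitz_test`): the historical baseline.  With n₁
makes and n₂ misses, E[R] = 2n₁n₂/n + 1 and
Var[R] = 2n₁n₂(2n₁n₂ − n)/(n²(n − 1)); the one-sided p for fewer runs
than expected (clustering) is reported by default, continuity correction
off (classical large-sample form, toggleable).

## Adjusted effect size and the per-player test

The raw effect is e = Pr[M|M…M]_data − Pr[M|M…M]_sim.  Any
miscalibration of the probability model contaminates e, so the model
error is estimated on a **matched null sample**: `sample_size =
n_followers` shots drawn uniformly without replacement from the player's
shots regardless of streak status, with

    ε = Pr[M]_data − Pr[M]_sim   (on that sample),

and the adjusted effect is ê = e − ε.  Matching the sample size makes
the two terms carry comparable sampling noise; ê is invariant (in
expectation) to adding a constant bias to every model probability, which
the tests verify with biases of ±0.05.

Significance uses paired simulation replicates.  Replicate r draws every
relevant shot **once** — a shot belonging to both the follower set and
the null sample contributes the same simulated outcome to both rates,
exactly as the observed rates share those realized outcomes — and forms

    ê_r = (obs − sim_r) − (null_obs − null_sim_r).

Under the no-streak null, (obs − null_obs) is one further draw from the
same distribution as (sim_r − null_sim_r), so the replicate standard
deviation estimates the null sampling scale of ê itself.  The reported
p-value is one-sided, P(T_{n_sim−1} > ê / sd(ê_r)); the empirical
quantile #{ê_r ≤ 0}/n_sim is recorded alongside (`p_empirical`).  Note
the scale is the *per-replicate* spread, not spread/√n_sim: the
replicates estimate the variability of a single realization of the data,
not of their own mean — dividing by √n_sim would reject a null data set
about half the time.  Type-I calibration is verified on a 200-player
null league (rejection count within the central 99% band of
Binomial(200, 0.05)), and the p-value distribution under the null passes
a Kolmogorov–Smirnov uniformity check.

Probabilities of exactly 0 or 1 are clipped to [1e−6, 1 − 1e−6] before
simulation.

### Attenuation of ê under a true effect (known limitation)

Because the null sample is drawn unconditional on streak status, a
*true* streak effect δ leaks into ε: followers make up a fraction f of
all shots (f ≈ previous-shot make rate ≈ 0.5 at k = 1 for a ~50%
shooter), so E[ε] ≈ δ·f and E[ê] ≈ δ(1 − f).  The raw effect e recovers
δ without attenuation; ê is a deliberately conservative estimate whose
bias is second-order for the small effects typical of real data but
roughly halves a large injected boost.  `player_test(...,
error_sample="non_followers")` draws the null sample from non-follower
shots instead, which keeps the effect out of ε and recovers δ (verified
in the tests); the default remains the unconditional sample, which is
the classical description of the procedure.  Both choices coincide under
the null, so calibration is unaffected.

## League scan and meta-test

`league_scan` runs the per-player test for every qualifying player at
each k.  Players with fewer than `follower_floor` followers (default 10,
configurable down to 1) are excluded from that k's tally and reported —
their tests are severely underpowered.  With M tests at level α, the
count of significant results under the global null is Binomial(M, α)
(tests across players are treated as independent), and
`binomial_meta_pvalue` computes the exact upper tail via the binomial
survival function — no normal approximation.  Reported effect summaries
are follower-weighted means of ê over significant players and over all
tested players; both the t-based and empirical significance counts are
tallied.

## Probability model and calibration

The framework only requires a calibrated pᵢ; any external model can
populate `make_probability`.  The built-in baseline
(`fit_baseline_model`) is an additive log-odds (logistic GLM) model:
intercept, linear terms for distance, defender distance, touch time and
dribbles, a category effect per shot type, and optionally a cubic
B-spline on distance (`distance_spline_df`, quantile knots).  Unseen
shot-type categories at predict time fall back to the reference category
effect with a logged warning; single-class training data is an error.
Fitted models serialize to a JSON parameter file.

`loso_predict` fills probabilities by leave-one-season-out cross-fitting
(≥ 2 season labels required; with two seasons this is 2-fold
cross-validation).  A leakage test confirms that perturbing a held-out
season's outcomes leaves that season's predictions unchanged.

`reliability_curve` bins predictions in [p, p + 0.05) (final bin closed
at 1.0; other widths allowed, with a warning when they do not divide 1),
reporting per-bin mean prediction, observed success fraction and count;
empty bins are flagged, never interpolated.  `accuracy` is the 0.5
threshold accuracy with ties counted as predicted success.

## Synthetic league

`generate_league` emulates a two-season tracking dataset.  Defaults: 153
players, 164 games each (two 82-game seasons), shots per game 1 +
Poisson(11) (mean 12 — roughly the volume that motivates a 1000-shot
inclusion filter).  Covariates: shot type categorical (jump shot 62%,
lay-up 22%, floater 6%, tip 3%, dunk 7%); distance a near-rim/jumper
mixture tied to shot type (|N(2, 1.5)| ft at the rim, N(17, 6) clipped
to [2, 30] ft otherwise); defender distance Gamma(2, 2) ft; touch time
Gamma(1.5, 1.8) s; dribbles Poisson(2).  True make probabilities follow
an additive log-odds model (intercept 0.2; −0.045/ft distance;
+0.065/ft defender distance; −0.02/s touch time; −0.01/dribble; shot-type
effects up to +2.2 for dunks), giving a league-wide make rate near 0.47
with per-shot probabilities spanning roughly 0.15–0.97.  These values
were chosen once as representative of professional basketball shot
profiles and are not tuned.

Outcomes are drawn sequentially within each game so the streak state at
every shot is causally correct.  With `player_fraction = 0` the process
is exactly heterogeneous-Bernoulli (no serial dependence).  A streak
effect adds δ to the probability (or to the log-odds, mode
`logit_boost`) of every shot whose streak state ≥ k\*, for the selected
fraction of players; boosted probabilities are clipped into (0,1) with
the clip count logged and returned (`truth.attrs["n_clipped"]`) — zero
under the defaults.  The default mode is the probability boost because
the effect sizes the tests report are probability differences.  The
generator emits both the shot log (optionally with the *baseline* truth
as the model probability — a perfectly calibrated model blind to the
streak effect) and a truth table with baseline and realized
probabilities and streak states, for recovery experiments.  Covariates
are drawn identically in both synthetic seasons (no drift).

What the generator does **not** emulate: defensive adjustment to hot
shooters, fatigue, or shot-selection endogeneity (hot players attempting
harder shots).  Passing tests on synthetic data therefore demonstrate
the statistical machinery — calibration under the stated null and
recovery of an injected effect — not the behavioural realism of the
null itself on real data.

## Problem sizes and numerical conventions

The test suite exercises the pipeline at desk scale: the type-I
experiment uses 200 null players with ~550 followers each at k = 1
(≈ 240k shots) and 500 simulation replicates per player; recovery uses
100 boosted players at the same size.  Enumeration oracles run at n ≤ 10
(k = 1) and n ≤ 8 (k = 2).  Monte-Carlo checks use 3-standard-error
bands.  All randomness flows from explicit seeds; per-player streams are
spawned deterministically from a root `numpy` SeedSequence, so any run
is exactly reproducible from its (config, seed) pair.  Reported numbers
print at 4 decimals; files carry full precision.

## Known limitations

- The ê attenuation under large true effects described above.
- The simulation null conditions on the observed follower set; it tests
  serial dependence given when streaks occurred, not a full generative
  model of streak occurrence.
- The binomial meta-test assumes independent per-player tests.
- The baseline probability model is a GLM, adequate for covariate
  structures like the synthetic generator's; users with richer data
  should supply their own probabilities through `make_probability`.
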