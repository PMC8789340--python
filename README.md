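# hothand

Streak ("hot hand") tests for **independent but non-identically
distributed** binary trials.

Whether success breeds success in sequential performance — basketball
shooting being the canonical battleground — is hard to test for two
reasons. First, the naive statistic, the observed success rate
immediately after a streak, is *biased downward* in finite sequences
even when trials are perfectly independent (streak selection bias): in a
20-trial sequence with exactly 10 makes, the trial after a randomly
chosen make is another make with probability 9/19 ≈ 0.47, not 0.5.
Second, real attempts are not identical — an open lay-up and a contested
three have very different success probabilities — so permuting outcomes
is not a valid null either.

`hothand` implements the full inferential chain for this setting:

- **Streak statistics and filtering** — follower shots after *k*
  consecutive makes (within-game only), conditional success rates,
  whole-game drops for incomplete covariates, minimum-shot player
  filters.
- **Chance baselines** — within-game permutation null, a
  heterogeneous-Bernoulli (Poisson-binomial) simulation null driven by
  per-shot model probabilities, the exact selection-bias calculator, and
  the classical Wald–Wolfowitz runs test for comparison.
- **Adjusted effect size** — the raw effect
  `e = Pr[M | M…M]_data − Pr[M | M…M]_sim` minus the model error
  `ε = Pr[M]_data − Pr[M]_sim` measured on a size-matched random sample
  of the player's shots, giving `ê = e − ε` with a one-sided
  significance test built from paired simulation replicates.
- **League meta-test** — the exact binomial upper tail
  `Σ_{p=r}^{M} C(M,p) α^p (1−α)^{M−p}` for the count of significant
  players among M tests, plus follower-weighted average effects.
- **Probability models and calibration** — a pluggable per-shot make
  probability interface, a baseline additive log-odds model,
  leave-one-season-out cross-fitting, reliability curves and accuracy.
- **Synthetic league generator** — players × games × ordered shots with
  realistic covariates, a known true probability model and an optional
  injected streak boost, for type-I and recovery experiments.

## Worked example

Library use, statsmodels style:

```python
import hothand as hh

model = hh.HotHandModel.simulate(
    hh.SynthConfig(n_players=6, games_per_player=60, shots_per_game_mean=12,
                   hot_hand=hh.HotHandEffect(k_star=1, delta=0.08,
                                             player_fraction=0.5)),
    seed=42, ks=(1, 2), min_shots=500,
)
results = model.fit(seed=7)
print(results.summary())
```

or the equivalent from the shell:

```bash
hothand simulate --n-players 6 --games-per-player 60 --shots-per-game-mean 12 \
    --player-fraction 0.5 --delta 0.08 --seed 42 --out-shots demo.csv
hothand league-scan --shots demo.csv --ks 1,2 --min-shots 500 --n-sim 500 --seed 7
```

which prints

```
Adjusted hot-hand analysis
players tested: 6   alpha: 0.05   n_sim: 500   seed: 7

 k  n_hh_players  adj_hh_effect_size  mean_sequence_length  overall_adj_effect_size  meta_p
 1             3              0.0649              355.1667                   0.0284 0.00223
 2             2              0.0997              180.1667                   0.0539  0.0328
```

Half of the six synthetic players carry a true +0.08 boost after a make.
At k = 1 the scan flags 3 players (`n_hh_players`), whose
follower-weighted mean adjusted effect is 0.065; the overall weighted
effect across all six is 0.028, and the binomial meta-test says 3
significant tests out of 6 at α = 0.05 would occur by chance with
probability 0.002. `mean_sequence_length` is the average number of
follower shots per player entering the test.

The selection-bias calculator reproduces the finite-sample bias that
derailed the early literature:

```bash
$ hothand bias-demo --n 20 --m 10 --method exact
P(next is make | randomly chosen make) = 0.4737 (exact); success rate M/n = 0.5000; selection bias = -0.0263
```

## Documentation

See `docs/methods.md` for the statistical model, the simulation-based
test construction, the synthetic-league design, numerical conventions
and known limitations (in particular the attenuation of `ê` when a true
streak effect leaks into the model-error sample).
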