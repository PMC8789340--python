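"""Chance baselines for streak statistics.

Three nulls for the conditional make rate after ``k`` consecutive makes:

* an iid permutation null — outcomes shuffled uniformly *within* each
  game, which preserves each game's make/miss composition and removes any
  serial dependence (appropriate when all shots are exchangeable);
* a heterogeneous-Bernoulli simulation null — each follower shot
  re-drawn as an independent Bernoulli with its own model probability
  (appropriate when shots differ in difficulty: independent but not
  identically distributed trials);
* the streak-selection-bias calculator — the finite-sample expectation
  of "the trial after a randomly chosen success", which is (M-1)/(n-1)
  for a sequence of n trials with M successes, *below* the success rate
  M/n.  This downward bias is why naive streak proportions look like
  "cold hands" even under independence.

Plus the classical Wald-Wolfowitz runs test as the historical baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

from .shotlog import (
    ConfigurationError,
    GameSequence,
    StreakContext,
    UndefinedStatisticError,
    conditional_streak_stat,
    follower_indices,
)


@dataclass
class NullDistribution:
    """Empirical null of the conditional streak statistic.

    ``replicate_values`` holds one pooled statistic per defined replicate;
    replicates whose permuted/simulated data had zero followers are
    excluded and counted in ``n_undefined``.  ``empirical_p`` is the
    fraction of defined replicates at least as extreme as ``observed``
    (ties count as extreme by default; ``tail='gt'`` gives the strict
    convention).
    """

    kind: str  # {"permutation", "simulation"}
    k: int
    replicate_values: np.ndarray
    n_replicates: int
    n_undefined: int
    mean: float
    observed: float | None
    empirical_p: float | None
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "k": self.k,
            "n_replicates": self.n_replicates,
            "n_undefined": self.n_undefined,
            "mean": self.mean,
            "observed": self.observed,
            "empirical_p": self.empirical_p,
            "seed": self.seed,
        }


def _empirical_p(values: np.ndarray, observed: float, tail: str) -> float:
    if tail == "ge":
        return float(np.mean(values >= observed))
    if tail == "gt":
        return float(np.mean(values > observed))
    raise ConfigurationError(f"tail must be 'ge' or 'gt', got {tail!r}")


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------

def permutation_conditional_distribution(
    sequences: Sequence[GameSequence],
    k: int,
    n_perm: int = 500,
    seed: int | None = None,
    tail: str = "ge",
) -> NullDistribution:
    """Permutation null of the pooled conditional streak statistic.

    Each replicate independently shuffles outcomes uniformly within every
    game (per-game composition preserved) and recomputes the statistic
    pooled over all games.
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be at least 1")
    observed_ctx = follower_indices(sequences, k)
    observed = conditional_streak_stat(observed_ctx)  # raises if no followers
    rng = np.random.default_rng(seed)
    outcomes = [s.outcomes for s in sequences]
    values = np.full(n_perm, np.nan)
    for r in range(n_perm):
        nf = nm = 0
        for o in outcomes:
            perm = rng.permutation(o)
            run = 0
            for i in range(o.size):
                if run >= k:
                    nf += 1
                    nm += perm[i]
                run = run + 1 if perm[i] == 1 else 0
        if nf:
            values[r] = nm / nf
    defined = values[~np.isnan(values)]
    if defined.size == 0:
        raise UndefinedStatisticError("every permutation replicate had zero followers")
    return NullDistribution(
        kind="permutation",
        k=k,
        replicate_values=defined,
        n_replicates=n_perm,
        n_undefined=int(n_perm - defined.size),
        mean=float(defined.mean()),
        observed=observed,
        empirical_p=_empirical_p(defined, observed, tail),
        seed=seed,
    )


def exhaustive_conditional_mean(n: int, M: int, k: int = 1) -> float:
    """Enumeration oracle: mean conditional statistic over all arrangements.

    Averages the per-sequence statistic Pr[make | k makes] over every
    arrangement of exactly ``M`` makes in ``n`` trials, excluding
    arrangements where it is undefined.  Brute force; intended for small
    ``n`` (the number of arrangements is C(n, M)).
    """
    if not (0 <= M <= n):
        raise ConfigurationError("require 0 <= M <= n")
    vals = []
    for pos in combinations(range(n), M):
        o = np.zeros(n, dtype=np.int8)
        o[list(pos)] = 1
        nf = nm = 0
        run = 0
        for i in range(n):
            if run >= k:
                nf += 1
                nm += o[i]
            run = run + 1 if o[i] else 0
        if nf:
            vals.append(nm / nf)
    if not vals:
        raise UndefinedStatisticError(
            f"statistic undefined for every arrangement (n={n}, M={M}, k={k})"
        )
    return float(np.mean(vals))


def perm_mean_closed_form_k1(n: int, M: int) -> float:
    """Closed-form mean of the k=1 conditional statistic under permutation.

    Equals the exhaustive-enumeration mean over all arrangements of ``M``
    makes in ``n`` trials (undefined arrangements excluded):
    ``(M - 1) / (n - 1)``.  The gap below the success rate ``M/n`` is the
    streak selection bias — a sampling-without-replacement effect: the
    make conditioned on consumes one of the ``M`` successes, leaving
    ``M - 1`` among the remaining ``n - 1`` trials.
    """
    if n < 2:
        raise ConfigurationError("need n >= 2")
    if not (1 <= M <= n):
        raise UndefinedStatisticError(
            "statistic undefined for all arrangements when M = 0"
        )
    return (M - 1) / (n - 1)


# ---------------------------------------------------------------------------
# Streak selection bias
# ---------------------------------------------------------------------------

def selection_bias_probability(
    n: int,
    M: int,
    method: str = "exact",
    n_mc: int = 100_000,
    seed: int | None = None,
) -> float:
    """P(next trial is a success | a uniformly chosen success, not last).

    For a uniformly random arrangement of exactly ``M`` successes among
    ``n`` trials, pick one of the successes uniformly; conditioned on a
    next trial existing, return the probability that it is a success.
    ``exact`` uses the closed form (M-1)/(n-1); ``enumerate`` brute-forces
    all arrangements; ``monte_carlo`` samples arrangements and selections.
    """
    if not (1 <= M <= n):
        raise UndefinedStatisticError("need at least one success (1 <= M <= n)")
    if method == "exact":
        if n < 2:
            raise ConfigurationError("need n >= 2 for a next trial to exist")
        return (M - 1) / (n - 1)
    if method == "enumerate":
        hits = trials = 0
        for pos in combinations(range(n), M):
            s = set(pos)
            for p in pos:
                if p == n - 1:
                    continue  # no next trial; excluded by conditioning
                trials += 1
                hits += (p + 1) in s
        if trials == 0:
            raise UndefinedStatisticError("no selected success has a next trial")
        return hits / trials
    if method == "monte_carlo":
        rng = np.random.default_rng(seed)
        base = np.zeros(n, dtype=np.int8)
        base[:M] = 1
        hits = trials = 0
        for _ in range(n_mc):
            arr = rng.permutation(base)
            makes = np.nonzero(arr)[0]
            pick = makes[rng.integers(makes.size)]
            if pick == n - 1:
                continue
            trials += 1
            hits += int(arr[pick + 1])
        if trials == 0:
            raise UndefinedStatisticError("no Monte-Carlo draw had a next trial")
        return hits / trials
    raise ConfigurationError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Heterogeneous-Bernoulli simulation null
# ---------------------------------------------------------------------------

def simulate_conditional_null(
    follower_probs: np.ndarray,
    n_sim: int = 500,
    seed: int | None = None,
    observed: float | None = None,
    tail: str = "ge",
    k: int = 1,
) -> NullDistribution:
    """Simulation null: re-draw each follower shot from its own probability.

    The follower shots are fixed to those observed in the data (streak
    conditioning is taken from the real sequence, not re-simulated), so
    each replicate is a Poisson-binomial draw over the follower
    probabilities; the replicate statistic is the simulated make fraction.
    """
    p = np.asarray(follower_probs, dtype=float)
    if p.size == 0:
        raise UndefinedStatisticError("follower_probs is empty")
    if not ((p > 0) & (p < 1)).all():
        raise ValueError("follower probabilities must lie strictly in (0, 1)")
    if n_sim < 1:
        raise ConfigurationError("n_sim must be at least 1")
    rng = np.random.default_rng(seed)
    draws = rng.random((n_sim, p.size)) < p
    values = draws.mean(axis=1)
    return NullDistribution(
        kind="simulation",
        k=k,
        replicate_values=values,
        n_replicates=n_sim,
        n_undefined=0,
        mean=float(values.mean()),
        observed=observed,
        empirical_p=None if observed is None else _empirical_p(values, observed, tail),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Wald-Wolfowitz runs test
# ---------------------------------------------------------------------------

def wald_wolfowitz_test(
    seq: GameSequence,
    alternative: str = "clustered",
    continuity_correction: bool = False,
) -> tuple[float, float]:
    """Runs test for randomness (normal approximation).

    With n1 successes and n2 failures (n = n1 + n2), the run count R has
    E[R] = 2 n1 n2 / n + 1 and
    Var[R] = 2 n1 n2 (2 n1 n2 - n) / (n^2 (n - 1)).
    ``alternative='clustered'`` reports the one-sided p for *fewer* runs
    than expected (the streaky direction); ``'two-sided'`` doubles the
    smaller tail.  Continuity correction off by default (classical
    large-sample form).
    """
    o = seq.outcomes
    n1 = int(o.sum())
    n2 = int(o.size - n1)
    n = n1 + n2
    if n1 == 0 or n2 == 0:
        raise UndefinedStatisticError("runs test undefined for single-valued sequences")
    if n < 3:
        raise UndefinedStatisticError("runs test needs at least 3 trials")
    from .shotlog import runs_count

    R = runs_count(seq)
    mu = 2 * n1 * n2 / n + 1
    var = 2 * n1 * n2 * (2 * n1 * n2 - n) / (n ** 2 * (n - 1))
    diff = R - mu
    if continuity_correction:
        diff = np.sign(diff) * max(abs(diff) - 0.5, 0.0)
    z = diff / np.sqrt(var)
    if alternative == "clustered":
        p = stats.norm.cdf(z)
    elif alternative == "two-sided":
        p = 2 * stats.norm.sf(abs(z))
    else:
        raise ConfigurationError("alternative must be 'clustered' or 'two-sided'")
    return float(z), float(p)
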