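"""Per-player streak inference: raw effect, model-error adjustment, test.

The raw hot-hand effect for player pi and streak length k is

    e_{pi,k} = Pr[make | k makes]_data - Pr[make | k makes]_sim,

the observed make rate on follower shots minus its expectation under the
heterogeneous-Bernoulli null driven by the model probabilities.  Any
miscalibration of the probability model leaks into e, so it is adjusted
by the *model error*

    epsilon_pi = Pr[make]_data - Pr[make]_sim

measured on a matched random sample of the player's shots drawn without
regard to streak status, with the sample size matched to the follower
count so both terms carry comparable sampling noise.  The adjusted effect
is e-hat = e - epsilon; positive values mean hotter than chance.

Significance is assessed from paired simulation replicates: replicate r
draws every relevant shot once (a shot belonging to both the follower set
and the error sample gets a single shared draw, mirroring the fact that
the two observed rates share those very outcomes) and forms

    e-hat_r = (obs - sim_r) - (null_obs - null_sim_r).

Under the no-streak null, obs - null_obs is one more draw from the same
distribution as sim_r - null_sim_r, so the replicate spread estimates the
null sampling scale of e-hat itself.  The reported p-value refers
t = e-hat / sd(e-hat_r) to a t distribution with n_sim - 1 degrees of
freedom (one-sided, H1: e-hat > 0); the empirical quantile
p = #{e-hat_r <= 0} / n_sim is always recorded alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .nulls import NullDistribution
from .shotlog import (
    ConfigurationError,
    ShotLog,
    UndefinedStatisticError,
    conditional_streak_stat,
    follower_indices,
)

#: probabilities at exactly 0/1 are clipped here before simulation
PROB_CLIP = 1e-6


@dataclass
class PlayerTestResult:
    """Everything the per-(player, k) test produced."""

    player_id: object
    k: int
    n_followers: int
    observed_rate: float
    sim_mean: float
    raw_effect: float
    null_sample_observed: float
    null_sample_sim_mean: float
    model_error: float
    adjusted_effect: float
    p_value: float
    p_empirical: float
    n_sim: int
    seed: int | None

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)

    def to_dict(self) -> dict:
        d = {
            "player_id": self.player_id,
            "k": self.k,
            "n_followers": self.n_followers,
            "observed_rate": self.observed_rate,
            "sim_mean": self.sim_mean,
            "raw_effect": self.raw_effect,
            "null_sample_observed": self.null_sample_observed,
            "null_sample_sim_mean": self.null_sample_sim_mean,
            "model_error": self.model_error,
            "adjusted_effect": self.adjusted_effect,
            "p_value": self.p_value,
            "p_empirical": self.p_empirical,
            "n_sim": self.n_sim,
            "seed": self.seed,
        }
        return d


def significance_stars(p: float) -> str:
    """Footnote convention: *p<0.05, **p<0.01, ***p<0.001 ('' otherwise)."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def raw_effect(observed_rate: float, null: NullDistribution) -> float:
    """e = observed conditional rate minus the simulation-null mean."""
    if null.kind != "simulation":
        raise ConfigurationError(
            "raw_effect is defined against the heterogeneous-Bernoulli "
            f"simulation null, got kind={null.kind!r}"
        )
    return observed_rate - null.mean


def adjusted_effect(e: float, epsilon: float) -> float:
    """e-hat = e - epsilon."""
    return e - epsilon


def estimate_model_error(
    log: ShotLog,
    player_id,
    sample_size: int,
    n_rep: int = 500,
    seed: int | None = None,
) -> tuple[float, NullDistribution]:
    """Model error epsilon from one matched random sample of shots.

    Draws ``sample_size`` of the player's shots uniformly without
    replacement, unconditional on streak status, and returns the sample's
    observed make fraction minus the mean simulated fraction over
    ``n_rep`` Bernoulli replicates of the same shots.
    """
    if sample_size < 1:
        raise ConfigurationError("sample_size must be at least 1")
    sub = log.player_log(player_id).df
    if "make_probability" not in sub.columns or sub["make_probability"].isna().any():
        raise UndefinedStatisticError(
            "every shot needs a make_probability to estimate the model error"
        )
    if sample_size > len(sub):
        raise ConfigurationError(
            f"sample_size={sample_size} exceeds the {len(sub)} shots available "
            f"for player {player_id!r}; cap it at the available count"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(sub), size=sample_size, replace=False)
    outcomes = sub["outcome"].to_numpy()[idx]
    probs = np.clip(sub["make_probability"].to_numpy()[idx], PROB_CLIP, 1 - PROB_CLIP)
    observed = float(outcomes.mean())
    draws = rng.random((n_rep, sample_size)) < probs
    values = draws.mean(axis=1)
    null = NullDistribution(
        kind="simulation",
        k=0,
        replicate_values=values,
        n_replicates=n_rep,
        n_undefined=0,
        mean=float(values.mean()),
        observed=observed,
        empirical_p=float(np.mean(values >= observed)),
        seed=seed,
    )
    return observed - null.mean, null


def player_test(
    log: ShotLog,
    player_id,
    k: int,
    n_sim: int = 500,
    seed: int | None = None,
    error_sample: str = "all",
) -> PlayerTestResult:
    """Full adjusted hot-hand test for one (player, k).

    ``error_sample`` selects which shots the model-error sample is drawn
    from: ``'all'`` (unconditional on streak status, the default) or
    ``'non_followers'`` (shots not preceded by k consecutive makes, which
    keeps a genuine streak effect out of the epsilon term; see the
    methods note on attenuation).
    """
    player = log.player_log(player_id)
    sequences = player.sequences(require_probs=True)
    ctx = follower_indices(sequences, k)
    if ctx.n_followers < 1:
        raise UndefinedStatisticError(
            f"player {player_id!r} has no follower shots at k={k}"
        )
    observed = conditional_streak_stat(ctx)

    df = player.df
    follower_keys = set(ctx.follower_positions)
    is_follower = np.fromiter(
        ((g, i) in follower_keys for g, i in zip(df["game_id"], df["order_index"])),
        dtype=bool,
        count=len(df),
    )
    if error_sample == "all":
        pool = np.arange(len(df))
    elif error_sample == "non_followers":
        pool = np.nonzero(~is_follower)[0]
    else:
        raise ConfigurationError("error_sample must be 'all' or 'non_followers'")
    sample_size = min(ctx.n_followers, pool.size)
    if sample_size < 1:
        raise UndefinedStatisticError("no shots available for the model-error sample")

    rng = np.random.default_rng(seed)
    sample_idx = rng.choice(pool, size=sample_size, replace=False)
    outcomes = df["outcome"].to_numpy()
    probs = np.clip(df["make_probability"].to_numpy(), PROB_CLIP, 1 - PROB_CLIP)

    follower_idx = np.nonzero(is_follower)[0]
    null_obs = float(outcomes[sample_idx].mean())

    # one shared draw per distinct shot and replicate: shots in both sets
    # contribute the same simulated outcome to both rates, matching the
    # covariance structure of the two observed rates
    union_idx = np.union1d(follower_idx, sample_idx)
    pos = {int(j): i for i, j in enumerate(union_idx)}
    f_cols = np.array([pos[int(j)] for j in follower_idx])
    s_cols = np.array([pos[int(j)] for j in sample_idx])
    draws = rng.random((n_sim, union_idx.size)) < probs[union_idx]
    sim_rates = draws[:, f_cols].mean(axis=1)
    null_sim_rates = draws[:, s_cols].mean(axis=1)

    sim_mean = float(sim_rates.mean())
    null_sim_mean = float(null_sim_rates.mean())
    e = observed - sim_mean
    eps = null_obs - null_sim_mean
    ehat = e - eps
    ehat_r = (observed - sim_rates) - (null_obs - null_sim_rates)
    sd = float(ehat_r.std(ddof=1))
    if sd == 0.0:
        p_t = 0.5 if ehat == 0 else (0.0 if ehat > 0 else 1.0)
    else:
        p_t = float(stats.t.sf(ehat / sd, df=n_sim - 1))
    p_emp = float(np.mean(ehat_r <= 0))

    return PlayerTestResult(
        player_id=player_id,
        k=k,
        n_followers=ctx.n_followers,
        observed_rate=observed,
        sim_mean=sim_mean,
        raw_effect=e,
        null_sample_observed=null_obs,
        null_sample_sim_mean=null_sim_mean,
        model_error=eps,
        adjusted_effect=ehat,
        p_value=p_t,
        p_empirical=p_emp,
        n_sim=n_sim,
        seed=seed,
    )
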