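"""Synthetic shot-log generator with known truth.

Emulates the structure of an optical-tracking shot dataset: players x
games x ordered shots, each shot carrying contextual covariates (distance
to the basket, closest-defender distance, touch time, dribble count,
shot type) and a true make probability given by an additive log-odds
model on those covariates.  Defaults mirror a two-season league: 153
players, 164 games (two 82-game seasons), a mean of 12 shots per game.

With ``player_fraction = 0`` the generated outcomes form a heterogeneous
Bernoulli process — independent but not identically distributed shots
with no serial dependence; this is the null every test should *not*
reject.  A streak effect can be injected: for "hot" players, any shot
preceded by at least ``k_star`` consecutive makes in the same game gets
its probability boosted by ``delta`` (additively on the probability
scale, or on the log-odds scale).  Outcomes are drawn sequentially
within each game so the streak state at every shot is causally correct,
and both the baseline and the realized (post-boost) truth are emitted
for recovery tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .shotlog import GameSequence, ShotLog

logger = logging.getLogger(__name__)

SHOT_TYPES = ("jump_shot", "layup", "floater", "tip", "dunk")
SHOT_TYPE_WEIGHTS = (0.62, 0.22, 0.06, 0.03, 0.07)

#: true log-odds coefficients of the generating model
DEFAULT_COEFFICIENTS = {
    "intercept": 0.2,
    "distance_to_basket": -0.045,
    "defender_distance": 0.065,
    "touch_time": -0.02,
    "dribbles": -0.01,
    "shot_type": {"jump_shot": 0.0, "layup": 0.4, "floater": -0.1, "tip": 0.1, "dunk": 2.2},
}


@dataclass
class HotHandEffect:
    """Injected streak effect: boost after ``k_star`` consecutive makes."""

    k_star: int = 1
    delta: float = 0.08
    mode: str = "probability_boost"  # or "logit_boost"
    player_fraction: float = 0.0


@dataclass
class SynthConfig:
    """Generator parameters; the defaults are the reference league."""

    n_players: int = 153
    games_per_player: int = 164  # two 82-game seasons
    shots_per_game_mean: float = 12.0  # 1 + Poisson(mean - 1), so min 1
    n_seasons: int = 2
    true_coefficients: dict = field(default_factory=lambda: dict(DEFAULT_COEFFICIENTS))
    hot_hand: HotHandEffect = field(default_factory=HotHandEffect)
    probability_column: str = "baseline"  # {"baseline", "none"}
    seed: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Draw shot covariates: a near-rim/jumper distance mixture, skewed
    defender distance and touch time, Poisson dribbles, categorical type."""
    shot_type = rng.choice(SHOT_TYPES, size=n, p=SHOT_TYPE_WEIGHTS)
    at_rim = np.isin(shot_type, ("layup", "tip", "dunk"))
    rim_d = np.abs(rng.normal(2.0, 1.5, size=n))
    jump_d = np.clip(rng.normal(17.0, 6.0, size=n), 2.0, 30.0)
    distance = np.where(at_rim, rim_d, jump_d)
    return pd.DataFrame(
        {
            "distance_to_basket": np.round(distance, 2),
            "defender_distance": np.round(rng.gamma(2.0, 2.0, size=n), 2),
            "touch_time": np.round(np.clip(rng.gamma(1.5, 1.8, size=n), 0.1, 24.0), 2),
            "dribbles": rng.poisson(2.0, size=n),
            "shot_type": shot_type,
        }
    )


def _baseline_probability(cov: pd.DataFrame, coef: dict) -> np.ndarray:
    eta = np.full(len(cov), float(coef["intercept"]))
    for c in ("distance_to_basket", "defender_distance", "touch_time", "dribbles"):
        eta += coef[c] * cov[c].to_numpy(dtype=float)
    type_effect = cov["shot_type"].map(coef["shot_type"]).to_numpy(dtype=float)
    return 1.0 / (1.0 + np.exp(-(eta + type_effect)))


def generate_league(
    config: SynthConfig | None = None, seed: int | None = None
) -> tuple[ShotLog, pd.DataFrame]:
    """Generate a league and its ground truth; fully seeded and reproducible.

    Returns the shot log (``make_probability`` filled with the *baseline*
    truth when ``probability_column='baseline'``, i.e. a perfectly
    calibrated model that does not know about the streak effect) and a
    truth table aligned row-for-row with ``baseline_prob``,
    ``realized_prob`` and ``streak_state`` (consecutive makes immediately
    before the shot).  ``truth.attrs['n_clipped']`` counts boosted
    probabilities that had to be clipped into (0, 1); it is 0 under the
    default parameters.
    """
    config = config or SynthConfig()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    hh = config.hot_hand
    if not (0.0 <= hh.player_fraction <= 1.0):
        raise ValueError("player_fraction must be in [0, 1]")
    n_hot = int(round(hh.player_fraction * config.n_players))
    hot_ids = set(rng.choice(config.n_players, size=n_hot, replace=False).tolist())
    games_per_season = max(config.games_per_player // config.n_seasons, 1)

    frames = []
    n_clipped = 0
    eps = 1e-6
    for pi in range(config.n_players):
        n_shots_per_game = 1 + rng.poisson(
            config.shots_per_game_mean - 1, size=config.games_per_player
        )
        n_total = int(n_shots_per_game.sum())
        cov = _covariates(rng, n_total)
        baseline = _baseline_probability(cov, config.true_coefficients)
        game_ids = np.repeat(np.arange(config.games_per_player), n_shots_per_game)
        order = np.concatenate([np.arange(m) for m in n_shots_per_game])

        is_hot = pi in hot_ids and hh.delta != 0.0
        realized = baseline.copy()
        streak_state = np.zeros(n_total, dtype=np.int64)
        u = rng.random(n_total)
        outcomes = np.empty(n_total, dtype=np.int8)
        run = 0
        for i in range(n_total):
            run = 0 if order[i] == 0 else run  # streaks reset at game start
            streak_state[i] = run
            if is_hot and run >= hh.k_star:
                if hh.mode == "probability_boost":
                    p = baseline[i] + hh.delta
                elif hh.mode == "logit_boost":
                    logit = np.log(baseline[i] / (1 - baseline[i])) + hh.delta
                    p = 1.0 / (1.0 + np.exp(-logit))
                else:
                    raise ValueError(f"unknown hot-hand mode {hh.mode!r}")
                if p <= 0.0 or p >= 1.0:
                    n_clipped += 1
                    p = min(max(p, eps), 1 - eps)
                realized[i] = p
            outcomes[i] = u[i] < realized[i]
            run = run + 1 if outcomes[i] else 0

        frame = pd.DataFrame(
            {
                "player_id": f"p{pi:03d}",
                "game_id": [f"g{g:04d}" for g in game_ids],
                "order_index": order,
                "outcome": outcomes,
                "season": [f"S{g // games_per_season + 1}" for g in game_ids],
            }
        )
        frame = pd.concat([frame, cov], axis=1)
        frame["baseline_prob"] = baseline
        frame["realized_prob"] = realized
        frame["streak_state"] = streak_state
        frame["is_hot_player"] = is_hot
        frames.append(frame)

    full = pd.concat(frames, ignore_index=True)
    truth = full[
        ["player_id", "game_id", "order_index", "baseline_prob", "realized_prob",
         "streak_state", "is_hot_player"]
    ].copy()
    truth.attrs["n_clipped"] = n_clipped
    if n_clipped:
        logger.warning("clipped %d boosted probabilities into (0, 1)", n_clipped)

    log_cols = ["player_id", "game_id", "order_index", "outcome", "season",
                "distance_to_basket", "defender_distance", "touch_time",
                "dribbles", "shot_type"]
    log_df = full[log_cols].copy()
    if config.probability_column == "baseline":
        log_df["make_probability"] = np.clip(full["baseline_prob"], eps, 1 - eps)
    elif config.probability_column != "none":
        raise ValueError("probability_column must be 'baseline' or 'none'")
    return ShotLog(log_df), truth


def generate_fixed_composition_sequences(
    n: int, M: int, n_sequences: int, seed: int | None = None
) -> list[GameSequence]:
    """Uniformly random arrangements of exactly ``M`` makes among ``n`` trials."""
    if not (0 <= M <= n):
        raise ValueError("require 0 <= M <= n")
    rng = np.random.default_rng(seed)
    base = np.zeros(n, dtype=np.int8)
    base[:M] = 1
    return [
        GameSequence(outcomes=rng.permutation(base), game_id=i)
        for i in range(n_sequences)
    ]
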