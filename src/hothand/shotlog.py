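"""Shot-log container, streak statistics and filtering rules.

The universal input is a *shot log*: one row per attempt with a player
identifier, a game identifier, the order of the attempt within the game,
the binary outcome (1 = make, 0 = miss), contextual covariates and an
optional per-shot make probability produced by a probability model.

Streaks are defined strictly within a game: a *follower* shot for streak
length ``k`` is a shot whose ``k`` immediately preceding shots in the same
game were all makes.  Streaks never span game boundaries, and overlapping
streaks each count (a run of m >= k makes yields a follower at every
position preceded by at least k makes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Covariate columns of the standard shot-log CSV schema.
COVARIATE_FIELDS = (
    "distance_to_basket",
    "defender_distance",
    "touch_time",
    "dribbles",
    "shot_type",
)

#: Columns every shot log must carry.
REQUIRED_COLUMNS = ("player_id", "game_id", "order_index", "outcome")


class ConfigurationError(ValueError):
    """Invalid user configuration (unknown field, bad threshold...)."""


class UndefinedStatisticError(ValueError):
    """The requested statistic has an empty denominator (zero followers)."""


@dataclass(frozen=True)
class GameSequence:
    """Ordered outcomes of one game, with optional per-shot probabilities.

    Parameters
    ----------
    outcomes : array of {0, 1}
        1 = make (success), 0 = miss (failure), in shot order.
    probs : array of float in (0, 1), optional
        Model make probability per shot.  Either absent as a whole or
        present for every shot.
    game_id : hashable
        Opaque identifier; carried through to follower positions.
    """

    outcomes: np.ndarray
    probs: np.ndarray | None = None
    game_id: object = None

    def __post_init__(self):
        outcomes = np.asarray(self.outcomes, dtype=np.int8)
        if outcomes.ndim != 1 or outcomes.size < 1:
            raise ValueError("outcomes must be a non-empty 1-D vector")
        if not np.isin(outcomes, (0, 1)).all():
            raise ValueError("outcomes must be binary (0 = miss, 1 = make)")
        object.__setattr__(self, "outcomes", outcomes)
        if self.probs is not None:
            probs = np.asarray(self.probs, dtype=float)
            if probs.shape != outcomes.shape:
                raise ValueError("probs must align with outcomes")
            if not ((probs > 0) & (probs < 1)).all():
                raise ValueError("probabilities must lie strictly in (0, 1)")
            object.__setattr__(self, "probs", probs)

    @property
    def n(self) -> int:
        return self.outcomes.size


@dataclass
class StreakContext:
    """Follower shots for a streak length ``k``, pooled across games.

    ``follower_positions`` are ``(game_id, order_index)`` pairs (0-based
    order index) of shots preceded, within their game, by ``k``
    consecutive makes.
    """

    k: int
    follower_positions: list = field(default_factory=list)
    follower_outcomes: np.ndarray = field(default_factory=lambda: np.empty(0, np.int8))
    follower_probs: np.ndarray | None = None

    @property
    def n_followers(self) -> int:
        return int(self.follower_outcomes.size)

    @property
    def n_follower_makes(self) -> int:
        return int(self.follower_outcomes.sum())


class ShotLog:
    """A validated shot-log table.

    Thin wrapper around a :class:`pandas.DataFrame` with the standard
    schema.  ``order_index`` is 0-based internally (reports print 1-based
    positions).  Missing covariates are empty CSV fields (NaN in memory),
    never magic numbers.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ConfigurationError(f"shot log is missing columns: {missing}")
        df = df.copy()
        df["outcome"] = df["outcome"].astype(int)
        if not df["outcome"].isin((0, 1)).all():
            raise ValueError("outcome column must be binary 0/1")
        df["order_index"] = df["order_index"].astype(int)
        if (df["order_index"] < 0).any():
            raise ValueError("order_index must be non-negative")
        dup = df.duplicated(subset=["player_id", "game_id", "order_index"])
        if dup.any():
            raise ValueError("order_index must be unique within (player, game)")
        if "make_probability" in df.columns:
            p = df["make_probability"]
            bad = p.notna() & ~((p > 0) & (p < 1))
            if bad.any():
                raise ValueError("make_probability values must lie strictly in (0, 1)")
        df = df.sort_values(["player_id", "game_id", "order_index"], kind="stable")
        self._df = df.reset_index(drop=True)

    # -- container basics -------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    @property
    def has_probabilities(self) -> bool:
        return (
            "make_probability" in self._df.columns
            and self._df["make_probability"].notna().all()
        )

    def players(self) -> list:
        return list(self._df["player_id"].unique())

    def player_log(self, player_id) -> "ShotLog":
        sub = self._df[self._df["player_id"] == player_id]
        if sub.empty:
            raise KeyError(f"unknown player_id: {player_id!r}")
        return ShotLog(sub)

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_csv(cls, path) -> "ShotLog":
        df = pd.read_csv(path)
        if "make_probability" in df.columns and df["make_probability"].isna().all():
            df = df.drop(columns=["make_probability"])
        return cls(df)

    def to_csv(self, path) -> None:
        self._df.to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ShotLog":
        return cls(df)

    # -- sequences ---------------------------------------------------------
    def sequences(self, player_id=None, require_probs: bool = False) -> list[GameSequence]:
        """Per-game outcome (and probability) vectors, in game order."""
        df = self._df if player_id is None else self.player_log(player_id)._df
        if require_probs and (
            "make_probability" not in df.columns
            or df["make_probability"].isna().any()
        ):
            raise UndefinedStatisticError(
                "make_probability must be present on every shot for this operation"
            )
        has_p = "make_probability" in df.columns and df["make_probability"].notna().all()
        out = []
        for (_, gid), g in df.groupby(["player_id", "game_id"], sort=True):
            out.append(
                GameSequence(
                    outcomes=g["outcome"].to_numpy(),
                    probs=g["make_probability"].to_numpy() if has_p else None,
                    game_id=gid,
                )
            )
        return out


# ---------------------------------------------------------------------------
# Filtering rules
# ---------------------------------------------------------------------------

def drop_incomplete_games(log: ShotLog, required_fields: Iterable[str]) -> ShotLog:
    """Drop every (player, game) group containing a shot with a missing field.

    A single shot with a missing required covariate breaks the within-game
    sequence, so the whole game is removed rather than the shot alone.
    Idempotent; ``required_fields=[]`` is the identity.
    """
    required_fields = list(required_fields)
    allowed = set(COVARIATE_FIELDS) | {"make_probability"}
    unknown = [f for f in required_fields if f not in allowed]
    if unknown:
        raise ConfigurationError(f"unknown covariate field(s): {unknown}")
    if not required_fields:
        return log
    df = log.df
    present = [f for f in required_fields if f in df.columns]
    missing_cols = [f for f in required_fields if f not in df.columns]
    if missing_cols:
        # a column absent from the table counts as missing on every shot
        return ShotLog(df.iloc[0:0])
    bad = df[present].isna().any(axis=1)
    bad_games = df.loc[bad, ["player_id", "game_id"]].drop_duplicates()
    keep = df.merge(bad_games, on=["player_id", "game_id"], how="left", indicator=True)
    return ShotLog(df[(keep["_merge"] == "left_only").to_numpy()])


def filter_players_min_shots(log: ShotLog, min_shots: int = 1000) -> ShotLog:
    """Keep players whose total retained shot count is at least ``min_shots``."""
    if min_shots < 1:
        raise ConfigurationError("min_shots must be a positive count")
    counts = log.df.groupby("player_id")["outcome"].size()
    keep = counts[counts >= min_shots].index
    return ShotLog(log.df[log.df["player_id"].isin(keep)])


# ---------------------------------------------------------------------------
# Streak statistics
# ---------------------------------------------------------------------------

def follower_indices(sequences: Sequence[GameSequence], k: int) -> StreakContext:
    """Find all follower shots for streak length ``k`` across games.

    A position ``i`` (0-based) is a follower when ``i >= k`` and outcomes
    ``i-k .. i-1`` are all makes.  Sliding-window convention: overlapping
    streaks each contribute a follower.  A ``k`` at or beyond the longest
    game yields an empty context, not an error.
    """
    if k < 1:
        raise ConfigurationError("k must be a positive integer")
    positions: list = []
    outs: list[np.ndarray] = []
    probs: list[np.ndarray] = []
    all_have_probs = all(s.probs is not None for s in sequences)
    for seq in sequences:
        o = seq.outcomes
        if o.size <= k:
            continue
        # run[i] = number of consecutive makes immediately before shot i
        run = np.zeros(o.size, dtype=np.int64)
        for i in range(1, o.size):
            run[i] = run[i - 1] + 1 if o[i - 1] == 1 else 0
        idx = np.nonzero(run >= k)[0]
        if idx.size == 0:
            continue
        positions.extend((seq.game_id, int(i)) for i in idx)
        outs.append(o[idx])
        if all_have_probs:
            probs.append(seq.probs[idx])
    follower_outcomes = (
        np.concatenate(outs) if outs else np.empty(0, np.int8)
    )
    return StreakContext(
        k=k,
        follower_positions=positions,
        follower_outcomes=follower_outcomes,
        follower_probs=np.concatenate(probs) if (probs and all_have_probs) else None,
    )


def conditional_streak_stat(ctx: StreakContext) -> float:
    """Observed make rate on follower shots, Pr[make | k consecutive makes]."""
    if ctx.n_followers < 1:
        raise UndefinedStatisticError(
            f"no follower shots at k={ctx.k}: conditional statistic undefined"
        )
    return ctx.n_follower_makes / ctx.n_followers


def runs_count(seq: GameSequence) -> int:
    """Number of maximal blocks of identical outcomes in the sequence."""
    o = seq.outcomes
    return int(1 + np.count_nonzero(o[1:] != o[:-1]))
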