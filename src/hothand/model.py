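"""Model/Results facade over the streak-testing pipeline.

:class:`HotHandModel` holds a shot log plus the analysis configuration;
:meth:`HotHandModel.fit` runs the filtering rules, the per-player
adjusted tests and the league meta-test, returning a
:class:`HotHandResults` with the estimates, their simulation-based
uncertainties and a ``summary()`` table.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from . import __version__ as _version
from .league import LeagueScanResult, league_scan, league_summary_frame
from .shotlog import (
    ShotLog,
    drop_incomplete_games,
    filter_players_min_shots,
)
from .synth import SynthConfig, generate_league


class HotHandModel:
    """Adjusted streak (hot-hand) analysis of a shot log.

    Parameters
    ----------
    data : ShotLog or pandas.DataFrame
        Shot log in the standard schema; every shot must carry a
        ``make_probability`` (use :func:`hothand.probmodel.loso_predict`
        to fill it from covariates).
    ks : iterable of int
        Streak lengths to test.
    min_shots : int
        Minimum raw shot count for a player to qualify (applied before
        the whole-game completeness drop, matching the filtering
        narrative of two-season tracking data).
    required_fields : list of str, optional
        Covariates that must be present on every shot of a retained
        game; games with any missing value are dropped whole.
    drop_incomplete_first : bool
        Apply the whole-game drop before the min-shot filter instead.
    follower_floor : int
        Minimum follower count for a player to enter a given k's tally.
    error_sample : {"all", "non_followers"}
        Pool for the model-error sample (see :func:`hothand.effects.player_test`).
    """

    def __init__(
        self,
        data,
        ks=(1, 2, 3, 4),
        min_shots: int = 1000,
        required_fields=None,
        drop_incomplete_first: bool = False,
        follower_floor: int = 10,
        n_sim: int = 500,
        alpha: float = 0.05,
        error_sample: str = "all",
    ):
        self.log = data if isinstance(data, ShotLog) else ShotLog(data)
        self.ks = tuple(ks)
        self.min_shots = min_shots
        self.required_fields = list(required_fields or [])
        self.drop_incomplete_first = drop_incomplete_first
        self.follower_floor = follower_floor
        self.n_sim = n_sim
        self.alpha = alpha
        self.error_sample = error_sample

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_csv(cls, path, **kwargs) -> "HotHandModel":
        return cls(ShotLog.from_csv(path), **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "HotHandModel":
        return cls(ShotLog(df), **kwargs)

    @classmethod
    def simulate(cls, config: SynthConfig | None = None, seed=None, **kwargs):
        """Generate a synthetic league and wrap it as a model."""
        log, truth = generate_league(config, seed=seed)
        model = cls(log, **kwargs)
        model.truth = truth
        return model

    # -- filtering ---------------------------------------------------------
    def filtered_log(self) -> ShotLog:
        log = self.log
        if self.drop_incomplete_first:
            log = drop_incomplete_games(log, self.required_fields)
            log = filter_players_min_shots(log, self.min_shots)
        else:
            log = filter_players_min_shots(log, self.min_shots)
            log = drop_incomplete_games(log, self.required_fields)
        return log

    # -- estimation --------------------------------------------------------
    def fit(self, seed: int | None = None) -> "HotHandResults":
        log = self.filtered_log()
        scans = league_scan(
            log,
            ks=self.ks,
            alpha=self.alpha,
            n_sim=self.n_sim,
            seed=seed,
            follower_floor=self.follower_floor,
            error_sample=self.error_sample,
        )
        return HotHandResults(self, scans, seed)


class HotHandResults:
    """Fitted league-wide streak analysis."""

    def __init__(self, model: HotHandModel, scans: list[LeagueScanResult], seed):
        self.model = model
        self.scans = {s.k: s for s in scans}
        self.seed = seed

    @property
    def player_results(self) -> pd.DataFrame:
        """One row per (player, k) with all test fields."""
        return pd.concat(
            [s.to_frame() for s in self.scans.values()], ignore_index=True
        )

    @property
    def league_summary(self) -> pd.DataFrame:
        return league_summary_frame(list(self.scans.values()))

    def summary(self) -> str:
        """League summary table: per k, the number of players with
        significant streakiness, the follower-weighted adjusted effect
        among them, the mean follower count, the overall weighted
        adjusted effect, and the binomial meta-test p-value."""
        df = self.league_summary
        lines = [
            "Adjusted hot-hand analysis",
            f"players tested: {next(iter(self.scans.values())).n_players_tested}"
            f"   alpha: {self.model.alpha}   n_sim: {self.model.n_sim}"
            f"   seed: {self.seed}",
            "",
            df.to_string(
                index=False,
                float_format=lambda v: f"{v:0.4f}",
                formatters={"meta_p": lambda v: f"{v:0.3g}"},
            ),
        ]
        return "\n".join(lines)

    # -- output ------------------------------------------------------------
    def to_csv(self, players_path, summary_path=None) -> None:
        self.player_results.to_csv(players_path, index=False)
        if summary_path is not None:
            self.league_summary.to_csv(summary_path, index=False)

    def to_json(self, path=None) -> str:
        payload = {
            "package_version": _version,
            "seed": self.seed,
            "alpha": self.model.alpha,
            "n_sim": self.model.n_sim,
            "ks": list(self.model.ks),
            "league": self.league_summary.to_dict(orient="records"),
            "players": self.player_results.to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=1, default=str)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    # -- plotting ----------------------------------------------------------
    def plot_adjusted_effects(self, k=None, ax=None):
        """Histogram of per-player adjusted effects at one k."""
        import matplotlib.pyplot as plt

        k = k if k is not None else next(iter(self.scans))
        scan = self.scans[k]
        if ax is None:
            _, ax = plt.subplots()
        vals = [r.adjusted_effect for r in scan.per_player]
        ax.hist(vals, bins=30)
        ax.axvline(0.0, color="k", lw=1)
        ax.set_xlabel(f"adjusted effect (k={k})")
        ax.set_ylabel("players")
        return ax
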