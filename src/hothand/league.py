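"""League-wide scan and the binomial meta-test.

Testing every player separately at level alpha produces false positives
in proportion to the number of tests.  With M independent per-player
tests, the count of significant results under the global null is
Binomial(M, alpha), so the probability of seeing at least r significant
players by chance is the exact upper-tail sum

    sum_{p=r}^{M} C(M, p) alpha^p (1 - alpha)^(M-p).

A small value says the significant players cannot (all) be chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .effects import PlayerTestResult, player_test
from .shotlog import ConfigurationError, ShotLog, UndefinedStatisticError


def binomial_meta_pvalue(M: int, r: int, alpha: float = 0.05) -> float:
    """Exact P(X >= r) for X ~ Binomial(M, alpha), via the survival function."""
    if not (0 <= r <= M):
        raise ConfigurationError("require 0 <= r <= M")
    if not (0 < alpha < 1):
        raise ConfigurationError("require 0 < alpha < 1")
    if r == 0:
        return 1.0
    return float(stats.binom.sf(r - 1, M, alpha))


@dataclass
class LeagueScanResult:
    """Scan of one streak length k across all qualifying players."""

    k: int
    alpha: float
    n_players_tested: int
    n_significant: int
    n_significant_empirical: int
    meta_p: float
    meta_p_empirical: float
    weighted_hh_effect: float  # over significant players, weights = n_followers
    weighted_overall_effect: float  # over all tested players
    mean_sequence_length: float  # mean follower count per tested player
    n_skipped: int
    skipped_players: list = field(default_factory=list)
    per_player: list[PlayerTestResult] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() | {"stars": r.stars} for r in self.per_player])

    def summary_row(self) -> dict:
        return {
            "k": self.k,
            "n_hh_players": self.n_significant,
            "adj_hh_effect_size": self.weighted_hh_effect,
            "mean_sequence_length": self.mean_sequence_length,
            "overall_adj_effect_size": self.weighted_overall_effect,
            "meta_p": self.meta_p,
        }


def _weighted_mean(values: np.ndarray, weights: np.ndarray) -> float:
    if values.size == 0 or weights.sum() == 0:
        return float("nan")
    return float(np.average(values, weights=weights))


def league_scan(
    log: ShotLog,
    ks=(1, 2, 3, 4),
    alpha: float = 0.05,
    n_sim: int = 500,
    seed: int | None = None,
    follower_floor: int = 10,
    error_sample: str = "all",
) -> list[LeagueScanResult]:
    """Run the adjusted per-player test for every player at each k.

    Players whose follower count at a given k falls below
    ``follower_floor`` are excluded from that k's tally (severely
    underpowered tests) and reported in ``skipped_players``; the floor is
    configurable down to 1.  Significance is tallied at level ``alpha``
    for both the t-based and the empirical p-value.
    """
    players = log.players()
    if not players:
        raise ConfigurationError("shot log contains no players")
    if follower_floor < 1:
        raise ConfigurationError("follower_floor must be >= 1")
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(players) * len(ks))]
    out = []
    for ki, k in enumerate(ks):
        results: list[PlayerTestResult] = []
        skipped: list = []
        for pi, pid in enumerate(players):
            s = child_seeds[ki * len(players) + pi]
            try:
                res = player_test(
                    log, pid, k, n_sim=n_sim, seed=s, error_sample=error_sample
                )
            except UndefinedStatisticError:
                skipped.append(pid)
                continue
            if res.n_followers < follower_floor:
                skipped.append(pid)
                continue
            results.append(res)
        if not results:
            raise UndefinedStatisticError(f"no player qualifies at k={k}")
        pvals = np.array([r.p_value for r in results])
        pvals_emp = np.array([r.p_empirical for r in results])
        ehats = np.array([r.adjusted_effect for r in results])
        weights = np.array([r.n_followers for r in results], dtype=float)
        sig = pvals < alpha
        sig_emp = pvals_emp < alpha
        M = len(results)
        r_sig = int(sig.sum())
        out.append(
            LeagueScanResult(
                k=k,
                alpha=alpha,
                n_players_tested=M,
                n_significant=r_sig,
                n_significant_empirical=int(sig_emp.sum()),
                meta_p=binomial_meta_pvalue(M, r_sig, alpha),
                meta_p_empirical=binomial_meta_pvalue(M, int(sig_emp.sum()), alpha),
                weighted_hh_effect=_weighted_mean(ehats[sig], weights[sig]),
                weighted_overall_effect=_weighted_mean(ehats, weights),
                mean_sequence_length=float(weights.mean()),
                n_skipped=len(skipped),
                skipped_players=skipped,
                per_player=results,
            )
        )
    return out


def league_summary_frame(scans: list[LeagueScanResult]) -> pd.DataFrame:
    """One row per k, mirroring the league summary table layout."""
    return pd.DataFrame([s.summary_row() for s in scans])
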