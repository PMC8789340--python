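import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import hothand as hh

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("ci")


def make_log(rows):
    return hh.ShotLog(pd.DataFrame(rows))


@pytest.fixture
def toy_two_game_log():
    """Player with two games; one shot of game B misses defender_distance."""
    rows = []
    for i, out in enumerate([1, 1, 0, 1, 1]):
        rows.append(
            dict(player_id="p1", game_id="A", order_index=i, outcome=out,
                 distance_to_basket=10.0, defender_distance=4.0,
                 touch_time=2.0, dribbles=1, shot_type="jump_shot")
        )
    for i, out in enumerate([1, 0]):
        rows.append(
            dict(player_id="p1", game_id="B", order_index=i, outcome=out,
                 distance_to_basket=12.0,
                 defender_distance=np.nan if i == 1 else 3.0,
                 touch_time=1.5, dribbles=0, shot_type="jump_shot")
        )
    return make_log(rows)


@pytest.fixture(scope="session")
def null_league():
    """Small heterogeneous-Bernoulli league with correct model probabilities."""
    cfg = hh.SynthConfig(
        n_players=12, games_per_player=40, shots_per_game_mean=10,
        hot_hand=hh.HotHandEffect(player_fraction=0.0), seed=314,
    )
    log, truth = hh.generate_league(cfg, seed=314)
    return log, truth


@pytest.fixture(scope="session")
def hot_league():
    """League where every player gets a +0.10 boost after a single make."""
    cfg = hh.SynthConfig(
        n_players=30, games_per_player=60, shots_per_game_mean=12,
        hot_hand=hh.HotHandEffect(k_star=1, delta=0.10, mode="probability_boost",
                                  player_fraction=1.0),
        seed=2718,
    )
    log, truth = hh.generate_league(cfg, seed=2718)
    return log, truth
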