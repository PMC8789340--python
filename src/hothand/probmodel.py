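"""Per-shot success-probability models and calibration diagnostics.

The streak tests only need a *calibrated* per-shot make probability;
where that probability comes from is pluggable (any value in the
``make_probability`` column is accepted).  The built-in baseline is an
additive log-odds model: linear terms for the numeric covariates, a
category effect per shot type, and an optional B-spline on shot distance.

Out-of-sample probabilities come from leave-one-season-out (LOSO)
cross-fitting: each shot is predicted by a model that never saw its own
season, so no information leaks from an outcome into its own predicted
probability.

Calibration is assessed with a reliability curve: shots are binned by
predicted probability (default bin width 0.05, bins [p, p + 0.05), last
bin closed at 1.0) and the mean prediction in a bin is compared with the
observed make fraction; a well-calibrated model has the two equal in
every occupied bin.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.interpolate import BSpline

from .shotlog import ConfigurationError, ShotLog

logger = logging.getLogger(__name__)

DEFAULT_NUMERIC = ("distance_to_basket", "defender_distance", "touch_time", "dribbles")


@dataclass
class ModelConfig:
    """Covariate configuration of the baseline additive log-odds model."""

    numeric_covariates: tuple = DEFAULT_NUMERIC
    use_shot_type: bool = True
    distance_spline_df: int | None = None  # None = plain linear distance term

    def to_dict(self) -> dict:
        return {
            "numeric_covariates": list(self.numeric_covariates),
            "use_shot_type": self.use_shot_type,
            "distance_spline_df": self.distance_spline_df,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(
            numeric_covariates=tuple(d["numeric_covariates"]),
            use_shot_type=d["use_shot_type"],
            distance_spline_df=d["distance_spline_df"],
        )


class ShotProbabilityModel:
    """Fitted additive log-odds make-probability model.

    Obtain instances through :func:`fit_baseline_model`; serialize with
    :meth:`to_json` / :meth:`from_json` (plain-text parameter file).
    """

    def __init__(self, config, columns, params, shot_type_levels, spline_knots):
        self.config = config
        self.columns = list(columns)
        self.params = np.asarray(params, dtype=float)
        self.shot_type_levels = list(shot_type_levels)
        self.spline_knots = None if spline_knots is None else np.asarray(spline_knots)

    # -- design matrix -----------------------------------------------------
    def _design(self, df: pd.DataFrame, training: bool) -> np.ndarray:
        cols = [np.ones(len(df))]
        for c in self.config.numeric_covariates:
            if c not in df.columns or df[c].isna().any():
                raise ConfigurationError(f"covariate {c!r} missing or incomplete")
            x = df[c].to_numpy(dtype=float)
            if c == "distance_to_basket" and self.spline_knots is not None:
                lo, hi = self.spline_knots[0], self.spline_knots[-1]
                cols.append(BSpline.design_matrix(
                    np.clip(x, lo, hi), self.spline_knots, 3
                ).toarray()[:, 1:])  # drop one basis column, intercept present
            else:
                cols.append(x[:, None])
        if self.config.use_shot_type:
            if "shot_type" not in df.columns or df["shot_type"].isna().any():
                raise ConfigurationError("covariate 'shot_type' missing or incomplete")
            st = df["shot_type"].astype(str)
            if not training:
                unseen = sorted(set(st) - set(self.shot_type_levels))
                if unseen:
                    logger.warning(
                        "unseen shot_type level(s) %s: falling back to the "
                        "baseline category effect", unseen,
                    )
            # reference level = first; unseen levels get the all-zero row
            for level in self.shot_type_levels[1:]:
                cols.append((st == level).to_numpy(float)[:, None])
        return np.column_stack(cols)

    def predict(self, data) -> np.ndarray:
        """Make probabilities in (0, 1) for each row of a shot log / frame."""
        df = data.df if isinstance(data, ShotLog) else data
        X = self._design(df, training=False)
        eta = X @ self.params
        return 1.0 / (1.0 + np.exp(-eta))

    # -- serialization -----------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "config": self.config.to_dict(),
            "columns": self.columns,
            "params": self.params.tolist(),
            "shot_type_levels": self.shot_type_levels,
            "spline_knots": None if self.spline_knots is None else self.spline_knots.tolist(),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ShotProbabilityModel":
        try:
            payload = json.loads(source)
        except (json.JSONDecodeError, TypeError):
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            config=ModelConfig.from_dict(payload["config"]),
            columns=payload["columns"],
            params=payload["params"],
            shot_type_levels=payload["shot_type_levels"],
            spline_knots=payload["spline_knots"],
        )


def fit_baseline_model(log: ShotLog, config: ModelConfig | None = None) -> ShotProbabilityModel:
    """Fit the additive log-odds model by maximum likelihood (logistic GLM).

    An empty covariate configuration yields the intercept-only model
    (constant predicted probability = training make rate).
    """
    config = config or ModelConfig()
    df = log.df
    y = df["outcome"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ConfigurationError(
            "training outcomes are single-class; a log-odds model cannot be fitted"
        )
    spline_knots = None
    if config.distance_spline_df:
        x = df["distance_to_basket"].to_numpy(dtype=float)
        df_s = int(config.distance_spline_df)
        inner = np.quantile(x, np.linspace(0, 1, df_s + 1)[1:-1])
        lo, hi = float(x.min()), float(x.max())
        spline_knots = np.r_[[lo] * 4, inner, [hi] * 4]
    levels = (
        sorted(df["shot_type"].astype(str).unique()) if config.use_shot_type else []
    )
    model = ShotProbabilityModel(config, [], np.zeros(1), levels, spline_knots)
    X = model._design(df, training=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    model.params = np.asarray(fit.params)
    model.columns = [f"x{i}" for i in range(X.shape[1])]
    return model


def loso_predict(
    log: ShotLog,
    config: ModelConfig | None = None,
    season_column: str = "season",
) -> ShotLog:
    """Fill ``make_probability`` by leave-one-season-out cross-fitting.

    Each season's shots are predicted by a model trained on all the other
    seasons, so predictions are strictly out of sample.  Requires at
    least two distinct season labels (with a single season there is
    nothing to hold out; use ordinary k-fold cross-fitting instead).
    """
    df = log.df
    if season_column not in df.columns:
        raise ConfigurationError(f"shot log has no {season_column!r} column")
    seasons = df[season_column].unique()
    if len(seasons) < 2:
        raise ConfigurationError(
            "leave-one-season-out needs at least 2 seasons; with a single "
            "season use a k-fold split instead"
        )
    out = df.copy()
    out["make_probability"] = np.nan
    for s in seasons:
        held = df[season_column] == s
        model = fit_baseline_model(ShotLog(df[~held]), config)
        p = model.predict(df[held])
        out.loc[held, "make_probability"] = np.clip(p, 1e-6, 1 - 1e-6)
    return ShotLog(out)


@dataclass
class ReliabilityCurve:
    """Binned predicted-vs-observed probabilities."""

    bin_edges: np.ndarray
    predicted_mean: np.ndarray  # NaN for empty bins
    observed_rate: np.ndarray  # NaN for empty bins
    bin_counts: np.ndarray
    occupied: np.ndarray = field(init=False)

    def __post_init__(self):
        self.occupied = self.bin_counts > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "predicted_mean": self.predicted_mean,
                "observed_rate": self.observed_rate,
                "count": self.bin_counts,
            }
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot([0, 1], [0, 1], "k--", lw=1, label="perfect calibration")
        m = self.occupied
        ax.plot(self.predicted_mean[m], self.observed_rate[m], "o-", label="model")
        ax.set_xlabel("predicted make probability")
        ax.set_ylabel("observed make fraction")
        ax.legend()
        return ax


def reliability_curve(probs, outcomes, bin_width: float = 0.05) -> ReliabilityCurve:
    """Bin predictions by value and compare with observed success rates."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if p.shape != y.shape:
        raise ConfigurationError("probs and outcomes must have equal length")
    if p.size == 0 or ((p < 0) | (p > 1)).any():
        raise ConfigurationError("probs must be non-empty and within [0, 1]")
    n_bins = int(np.ceil(round(1.0 / bin_width, 9)))
    if abs(n_bins * bin_width - 1.0) > 1e-9:
        warnings.warn(
            f"bin_width={bin_width} does not divide 1 evenly; last bin truncated",
            stacklevel=2,
        )
    edges = np.minimum(np.arange(n_bins + 1) * bin_width, 1.0)
    idx = np.minimum((p // bin_width).astype(int), n_bins - 1)  # closes last bin at 1
    counts = np.bincount(idx, minlength=n_bins)
    pred = np.full(n_bins, np.nan)
    obs = np.full(n_bins, np.nan)
    occ = counts > 0
    pred[occ] = np.bincount(idx, weights=p, minlength=n_bins)[occ] / counts[occ]
    obs[occ] = np.bincount(idx, weights=y, minlength=n_bins)[occ] / counts[occ]
    return ReliabilityCurve(edges, pred, obs, counts)


def accuracy(probs, outcomes, threshold: float = 0.5) -> float:
    """Classification accuracy of thresholded probabilities (ties -> success)."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(outcomes)
    return float(np.mean((p >= threshold).astype(int) == y))
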