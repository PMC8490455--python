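"""Empirical quantile mapping (QM) for daily series.

QM matches the distribution of a model variable to observations quantile by
quantile over a calibration period, separately per calibration window
(default: calendar months). Correction is applied to the WBGT *input
variables* before the index is computed, not to WBGT itself. Values outside
the calibrated range receive the boundary correction (constant delta), a
standard convention recorded in the model metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, InsufficientDataError


@dataclass
class QMModel:
    """Fitted quantile pairs per window. ``window="monthly"`` keys 1–12, ``"annual"`` keys 0."""

    model_q: dict[int, np.ndarray]
    obs_q: dict[int, np.ndarray]
    n_quantiles: int
    window: str
    calibration_period: tuple[str, str]
    extrapolation: str = field(default="constant-delta")

    def to_dict(self) -> dict:
        return {
            "model_q": {str(k): v.tolist() for k, v in self.model_q.items()},
            "obs_q": {str(k): v.tolist() for k, v in self.obs_q.items()},
            "n_quantiles": self.n_quantiles,
            "window": self.window,
            "calibration_period": list(self.calibration_period),
            "extrapolation": self.extrapolation,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QMModel":
        return cls(
            model_q={int(k): np.asarray(v) for k, v in d["model_q"].items()},
            obs_q={int(k): np.asarray(v) for k, v in d["obs_q"].items()},
            n_quantiles=d["n_quantiles"],
            window=d["window"],
            calibration_period=tuple(d["calibration_period"]),
            extrapolation=d.get("extrapolation", "constant-delta"),
        )


def _window_keys(index: pd.DatetimeIndex, window: str) -> np.ndarray:
    if window == "monthly":
        return index.month.to_numpy()
    if window == "annual":
        return np.zeros(len(index), dtype=int)
    raise ConfigError(f"unknown QM window {window!r}")


def fit_qm(
    obs: pd.Series,
    model: pd.Series,
    n_quantiles: int = 99,
    window: str = "monthly",
) -> QMModel:
    """Fit the empirical quantile map from *model* to *obs* on their common span.

    Percentiles 1 … ``n_quantiles`` (evenly spaced, linear estimator) of both
    series are paired per window. Applying the fitted map to the calibration
    model series reproduces the observed quantiles at the fitted points.
    """
    if n_quantiles < 1:
        raise ConfigError("n_quantiles must be >= 1")
    obs_idx, model_idx = pd.DatetimeIndex(obs.index), pd.DatetimeIndex(model.index)
    t0, t1 = max(obs_idx.min(), model_idx.min()), min(obs_idx.max(), model_idx.max())
    if pd.isna(t0) or pd.isna(t1) or t0 > t1:
        raise InsufficientDataError("observation and model series do not overlap")
    obs_c, model_c = obs.loc[t0:t1], model.loc[t0:t1]

    probs = np.linspace(1, n_quantiles, n_quantiles) * 100.0 / (n_quantiles + 1)
    keys_o = _window_keys(pd.DatetimeIndex(obs_c.index), window)
    keys_m = _window_keys(pd.DatetimeIndex(model_c.index), window)
    model_q, obs_q = {}, {}
    for k in np.unique(keys_m):
        o = obs_c.to_numpy()[keys_o == k]
        m = model_c.to_numpy()[keys_m == k]
        if len(o) == 0 or len(m) == 0:
            raise InsufficientDataError(f"no calibration data in window {k}")
        model_q[int(k)] = np.percentile(m, probs)
        obs_q[int(k)] = np.percentile(o, probs)
    return QMModel(
        model_q=model_q,
        obs_q=obs_q,
        n_quantiles=n_quantiles,
        window=window,
        calibration_period=(str(t0.date()), str(t1.date())),
    )


def apply_qm(qm: QMModel, series: pd.Series) -> pd.Series:
    """Bias-correct a daily series with a fitted quantile map.

    Piecewise-linear interpolation between fitted quantile pairs; beyond the
    calibrated range the boundary correction is applied as a constant offset.
    Order-preserving by construction.
    """
    idx = pd.DatetimeIndex(series.index)
    keys = _window_keys(idx, qm.window)
    out = np.empty(len(series))
    x_all = series.to_numpy(dtype=float)
    for k in np.unique(keys):
        if int(k) not in qm.model_q:
            raise ConfigError(f"window {k} was not fitted")
        mq, oq = qm.model_q[int(k)], qm.obs_q[int(k)]
        sel = keys == k
        x = x_all[sel]
        y = np.interp(x, mq, oq)
        lo, hi = x < mq[0], x > mq[-1]
        y[lo] = x[lo] + (oq[0] - mq[0])
        y[hi] = x[hi] + (oq[-1] - mq[-1])
        out[sel] = y
    return pd.Series(out, index=series.index, name=series.name)
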