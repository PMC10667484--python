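"""Post-arrival suppression terms shared by the generator and the models.

All terms act additively on log10 Ne, are zero before human arrival
(``t >= t_arr`` on the years-BP axis) and are monotone non-increasing in
time since arrival for non-negative rates and drops.  Elapsed time since
arrival is scaled by 10,000 years so rate parameters are order one.
"""

from __future__ import annotations

import numpy as np

__all__ = ["TSCALE_YR", "logistic_drop", "exponential_drop", "linear_drop",
           "presence_ramp", "human_term"]

TSCALE_YR = 10_000.0


def _elapsed(t_yr: np.ndarray, t_arr: float) -> np.ndarray:
    return np.maximum(t_arr - np.asarray(t_yr, dtype=float), 0.0) / TSCALE_YR


def logistic_drop(t_yr, t_arr: float, k: float, delta: float) -> np.ndarray:
    """-delta / (1 + exp(-k * elapsed)) after arrival, 0 before."""
    t_yr = np.asarray(t_yr, dtype=float)
    e = _elapsed(t_yr, t_arr)
    out = -delta / (1.0 + np.exp(-k * e))
    return np.where(t_yr >= t_arr, 0.0, out)


def exponential_drop(t_yr, t_arr: float, k: float, delta: float) -> np.ndarray:
    """-delta * (1 - exp(-k * elapsed)); continuous at arrival."""
    t_yr = np.asarray(t_yr, dtype=float)
    e = _elapsed(t_yr, t_arr)
    out = -delta * (1.0 - np.exp(-k * e))
    return np.where(t_yr >= t_arr, 0.0, out)


def linear_drop(t_yr, t_arr: float, b: float, delta: float) -> np.ndarray:
    """-min(delta, b * elapsed); linear decline saturating at -delta."""
    t_yr = np.asarray(t_yr, dtype=float)
    e = _elapsed(t_yr, t_arr)
    out = -np.minimum(delta, b * e)
    return np.where(t_yr >= t_arr, 0.0, out)


def presence_ramp(t_yr, earliest_yr: float, latest_yr: float) -> np.ndarray:
    """Probability-of-human-presence covariate: 0 before the earliest arrival
    bound, 1 after the latest, linear in between (years-BP axis)."""
    t_yr = np.asarray(t_yr, dtype=float)
    if earliest_yr <= latest_yr:
        raise ValueError("need earliest_yr > latest_yr on the BP axis")
    return np.clip((earliest_yr - t_yr) / (earliest_yr - latest_yr), 0.0, 1.0)


def human_term(trend: str, t_yr, t_arr: float, rate: float, delta: float) -> np.ndarray:
    if trend == "logistic":
        return logistic_drop(t_yr, t_arr, rate, delta)
    if trend == "exponential":
        return exponential_drop(t_yr, t_arr, rate, delta)
    if trend == "linear":
        return linear_drop(t_yr, t_arr, rate, delta)
    raise ValueError(f"unknown human trend {trend!r}")
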