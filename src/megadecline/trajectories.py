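"""Core containers and time-axis operations for demographic trajectories.

Everything downstream of PSMC parsing works with three step-function
containers: :class:`NeTrajectory` (effective population size vs years before
present), :class:`ClimateSeries` (temperature and precipitation on the same
axis) and :class:`SpeciesTraits` (per-species metadata driving scaling and
regressions).  The time axis is years BEFORE present — larger values are
older — and every step function is right-open: value ``k`` applies on
``[boundaries[k], boundaries[k+1])``.

Slope conventions used across the package: rates of population-size change
are expressed as d log10 Ne per decade of log10 time moving TOWARD the
present, so a species declining toward today has a negative slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "NeTrajectory",
    "SpeciesTraits",
    "ClimateSeries",
    "window_mean",
    "average_trend",
    "predict_mutation_rate",
    "read_traits",
    "write_traits",
    "read_climate",
    "write_climate",
    "read_trajectories",
    "write_trajectories",
]


def _check_step(boundaries: np.ndarray, values: np.ndarray, name: str) -> None:
    if boundaries.ndim != 1 or values.ndim != 1:
        raise ValueError(f"{name}: boundaries and values must be 1-D")
    if len(boundaries) != len(values) + 1:
        raise ValueError(
            f"{name}: need len(boundaries) == len(values) + 1, got "
            f"{len(boundaries)} and {len(values)}"
        )
    if np.any(np.diff(boundaries) <= 0):
        raise ValueError(f"{name}: boundaries must be strictly increasing")
    if boundaries[0] < 0:
        raise ValueError(f"{name}: boundaries must be non-negative (years BP)")


@dataclass(frozen=True)
class NeTrajectory:
    """Step function of effective population size over years before present.

    Parameters
    ----------
    species_id : str
        Identifier, conventionally ``Genus_species``.
    boundaries : array of float, length m+1
        Window edges in years BP, strictly increasing, ``boundaries[0] >= 0``.
    ne : array of float, length m
        Diploid effective population size on each window; all positive.
    """

    species_id: str
    boundaries: np.ndarray
    ne: np.ndarray

    def __post_init__(self):
        b = np.asarray(self.boundaries, dtype=float)
        n = np.asarray(self.ne, dtype=float)
        _check_step(b, n, "NeTrajectory")
        if len(n) < 2:
            raise ValueError("NeTrajectory: need at least 2 intervals")
        if np.any(n <= 0):
            raise ValueError("NeTrajectory: all ne must be positive")
        object.__setattr__(self, "boundaries", b)
        object.__setattr__(self, "ne", n)

    @property
    def midpoints(self) -> np.ndarray:
        """Window midpoints in years BP."""
        return 0.5 * (self.boundaries[:-1] + self.boundaries[1:])

    @property
    def support(self) -> tuple[float, float]:
        return float(self.boundaries[0]), float(self.boundaries[-1])

    def value_at(self, t: np.ndarray | float) -> np.ndarray:
        """Step-function evaluation at years BP ``t`` (right-open windows)."""
        t = np.asarray(t, dtype=float)
        lo, hi = self.support
        if np.any(t < lo) or np.any(t >= hi):
            raise ValueError(f"time outside trajectory support [{lo}, {hi})")
        idx = np.searchsorted(self.boundaries, t, side="right") - 1
        return self.ne[idx]

    def scaled(self, factor: float) -> "NeTrajectory":
        return NeTrajectory(self.species_id, self.boundaries, self.ne * factor)


@dataclass(frozen=True)
class ClimateSeries:
    """Mean annual temperature and precipitation as step functions of years BP."""

    boundaries: np.ndarray
    temp: np.ndarray
    precip: np.ndarray

    def __post_init__(self):
        b = np.asarray(self.boundaries, dtype=float)
        t = np.asarray(self.temp, dtype=float)
        p = np.asarray(self.precip, dtype=float)
        _check_step(b, t, "ClimateSeries(temp)")
        if len(p) != len(t):
            raise ValueError("ClimateSeries: temp and precip lengths differ")
        object.__setattr__(self, "boundaries", b)
        object.__setattr__(self, "temp", t)
        object.__setattr__(self, "precip", p)

    @property
    def support(self) -> tuple[float, float]:
        return float(self.boundaries[0]), float(self.boundaries[-1])


_STATUS_VALUES = {"extant_included", "extant_missing", "extinct"}


@dataclass(frozen=True)
class SpeciesTraits:
    """Per-species metadata: mass, generation time, mutation rate, realm, census."""

    species_id: str
    mass_kg: float
    gen_time_yr: float
    mu: float
    realm: str
    biome: str = ""
    iucn_census: float | None = None
    met_rate_kj_day: float | None = None
    status: str = "extant_included"

    def __post_init__(self):
        for attr in ("mass_kg", "gen_time_yr", "mu"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"SpeciesTraits.{attr} must be positive")
        if self.met_rate_kj_day is not None and self.met_rate_kj_day <= 0:
            raise ValueError("SpeciesTraits.met_rate_kj_day must be positive")
        if self.status not in _STATUS_VALUES:
            raise ValueError(f"unknown status {self.status!r}")

    @property
    def genus(self) -> str:
        tok = self.species_id.split("_")
        if len(tok) < 2 or not tok[0]:
            raise ValueError(
                f"species_id {self.species_id!r} does not encode Genus_species"
            )
        return tok[0]


def window_mean(series: NeTrajectory | ClimateSeries, window: tuple[float, float],
                which: str = "ne") -> float:
    """Time-weighted mean of a step function over ``[start, end)`` years BP.

    For a :class:`ClimateSeries`, ``which`` selects ``"temp"`` or ``"precip"``.
    """
    start, end = float(window[0]), float(window[1])
    if start >= end:
        raise ValueError("window start must be < end")
    boundaries = series.boundaries
    if isinstance(series, NeTrajectory):
        values = series.ne
    else:
        values = getattr(series, which)
    lo, hi = boundaries[0], boundaries[-1]
    if start < lo or end > hi:
        raise ValueError(
            f"window [{start}, {end}) outside series support [{lo}, {hi}]"
        )
    left = np.clip(boundaries[:-1], start, end)
    right = np.clip(boundaries[1:], start, end)
    w = right - left
    return float(np.sum(w * values) / (end - start))


def predict_mutation_rate(calibration: pd.DataFrame, query_gen_time: float) -> float:
    """Predict a per-generation mutation rate from generation time.

    Ordinary least squares of log10(mu) on log10(generation time) over a
    calibration table of extant mammals; the prediction is back-transformed.

    Parameters
    ----------
    calibration : DataFrame with columns ``gen_time_yr`` and ``mu``
    query_gen_time : generation time in years for the species to predict
    """
    if len(calibration) < 3:
        raise ValueError("need at least 3 calibration rows")
    if query_gen_time <= 0:
        raise ValueError("query generation time must be positive")
    g = np.asarray(calibration["gen_time_yr"], dtype=float)
    mu = np.asarray(calibration["mu"], dtype=float)
    if np.any(g <= 0) or np.any(mu <= 0):
        raise ValueError("calibration values must be positive")
    X = sm.add_constant(np.log10(g))
    fit = sm.OLS(np.log10(mu), X).fit()
    pred = fit.params[0] + fit.params[1] * np.log10(query_gen_time)
    return float(10.0 ** pred)


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return w


def average_trend(trajs: Sequence[NeTrajectory], grid: np.ndarray,
                  span: float = 0.3) -> pd.DataFrame:
    """Cross-species mean population trend with a 95% band, by loess.

    Each trajectory is evaluated (as a step function) at every grid time;
    the pooled (log10 t, log10 Ne) points are smoothed with a local linear
    regression using tricube weights over a ``span`` fraction of points.
    The band is mean +/- 1.96 standard errors of the local fit.

    Returns a DataFrame with columns ``t_yr``, ``mean_log10_ne``, ``lo``, ``hi``.
    """
    if len(trajs) < 2:
        raise ValueError("need at least 2 trajectories")
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty grid")
    xs, ys = [], []
    for tr in trajs:
        xs.append(np.log10(grid))
        ys.append(np.log10(tr.value_at(grid)))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    k = max(4, int(np.ceil(span * len(x))))
    out = np.empty((len(grid), 3))
    for j, g in enumerate(np.log10(grid)):
        d = np.abs(x - g)
        h = np.partition(d, k - 1)[k - 1]
        if h == 0:
            h = max(d.max(), 1e-12)
        w = _tricube(d / h)
        mask = w > 0
        if not mask.any():
            mask = d <= h
            w = np.where(mask, 1.0, 0.0)
        W = w[mask]
        X = np.column_stack([np.ones(mask.sum()), x[mask] - g])
        WX = X * W[:, None]
        XtWX = X.T @ WX
        # pseudo-inverse guards the degenerate case of all-equal abscissae
        XtWX_inv = np.linalg.pinv(XtWX)
        beta = XtWX_inv @ (WX.T @ y[mask])
        resid = y[mask] - X @ beta
        dof = max(mask.sum() - 2, 1)
        s2 = float(resid @ (W * resid)) / float(W.sum()) * mask.sum() / dof
        # variance of the local intercept (fitted value at the grid point)
        cov = XtWX_inv @ (X.T @ (W[:, None] ** 2 * X)) @ XtWX_inv
        se = np.sqrt(max(s2 * cov[0, 0], 0.0))
        out[j] = beta[0], beta[0] - 1.96 * se, beta[0] + 1.96 * se
    return pd.DataFrame(
        {"t_yr": grid, "mean_log10_ne": out[:, 0], "lo": out[:, 1], "hi": out[:, 2]}
    )


# ---------------------------------------------------------------------------
# tabular I/O

_TRAIT_COLS = [
    "species_id", "mass_kg", "gen_time_yr", "mu", "realm", "biome",
    "iucn_census", "met_rate_kj_day", "status",
]


def read_traits(path) -> list[SpeciesTraits]:
    """Read the species metadata TSV (header per the package conventions)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        out.append(
            SpeciesTraits(
                species_id=str(row["species_id"]),
                mass_kg=float(row["mass_kg"]),
                gen_time_yr=float(row["gen_time_yr"]),
                mu=float(row["mu"]),
                realm=str(row["realm"]),
                biome=str(row.get("biome", "")),
                iucn_census=None if pd.isna(row.get("iucn_census")) else float(row["iucn_census"]),
                met_rate_kj_day=None if pd.isna(row.get("met_rate_kj_day")) else float(row["met_rate_kj_day"]),
                status=str(row.get("status", "extant_included")),
            )
        )
    return out


def write_traits(traits: Iterable[SpeciesTraits], path) -> None:
    rows = []
    for t in traits:
        rows.append({
            "species_id": t.species_id, "mass_kg": t.mass_kg,
            "gen_time_yr": t.gen_time_yr, "mu": t.mu, "realm": t.realm,
            "biome": t.biome, "iucn_census": t.iucn_census,
            "met_rate_kj_day": t.met_rate_kj_day, "status": t.status,
        })
    pd.DataFrame(rows, columns=_TRAIT_COLS).to_csv(path, sep="\t", index=False)


def read_climate(path) -> ClimateSeries:
    """Read the climate CSV (start_yr, end_yr, temp, precip)."""
    df = pd.read_csv(path)
    df = df.sort_values("start_yr").reset_index(drop=True)
    b = np.append(df["start_yr"].to_numpy(float), float(df["end_yr"].iloc[-1]))
    return ClimateSeries(b, df["temp"].to_numpy(float), df["precip"].to_numpy(float))


def write_climate(series: ClimateSeries, path) -> None:
    pd.DataFrame({
        "start_yr": series.boundaries[:-1], "end_yr": series.boundaries[1:],
        "temp": series.temp, "precip": series.precip,
    }).to_csv(path, index=False)


def read_trajectories(path) -> list[NeTrajectory]:
    """Read the tidy trajectory CSV (species_id, start_yr, end_yr, ne)."""
    df = pd.read_csv(path)
    out = []
    for sid, grp in df.groupby("species_id", sort=True):
        grp = grp.sort_values("start_yr")
        b = np.append(grp["start_yr"].to_numpy(float), float(grp["end_yr"].iloc[-1]))
        out.append(NeTrajectory(str(sid), b, grp["ne"].to_numpy(float)))
    return out


def write_trajectories(trajs: Iterable[NeTrajectory], path) -> None:
    frames = []
    for tr in trajs:
        frames.append(pd.DataFrame({
            "species_id": tr.species_id,
            "start_yr": tr.boundaries[:-1],
            "end_yr": tr.boundaries[1:],
            "ne": tr.ne,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
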