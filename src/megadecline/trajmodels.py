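"""Climate-only, human-only and combined models of Ne trajectories.

The model family explains per-species log10 Ne over the last 742 kyr with a
Gaussian likelihood whose mean combines (i) standardised mean annual
temperature and precipitation of each PSMC window, optionally quadratic and
optionally lagged by one (older) window, and (ii) a monotone suppression
term applied after a latent *H. sapiens* arrival time drawn from the
species' realm arrival window.  Enumeration yields exactly 32 models:
12 climate-only ({linT, quadT} x {noP, linP, quadP} x {+/- lag}), 4
human-only (logistic / exponential / linear trend, or a probability-of-
presence ramp covariate) and 16 combined (4 configured climate specs x 4
human trends).

Fitting routes: models that are linear in their coefficients (all
climate-only models and any model whose only human component is the pH
ramp) use the exact conjugate normal-inverse-gamma posterior; models with a
nonlinear suppression term are sampled with ensemble MCMC (default) or a
Laplace approximation (``method="laplace"``, used for large simulation
studies).  Every fit retains the pointwise log-likelihood matrix for
PSIS-LOO model comparison.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats as sps

from . import trends
from .bayes import (ConjugateLinearModel, MCMCConfig, convergence, hpdi,
                    laplace_sir, psis_loo, sample_emcee)
from .simulate import ArrivalWindow
from .trajectories import ClimateSeries, NeTrajectory, window_mean

__all__ = [
    "ModelSpec", "enumerate_models", "build_design",
    "TrajectoryModel", "TrajectoryFit", "fit_model", "loo_score",
    "rank_models", "fit_predict_holdout", "compare_windows",
    "human_megafauna_correlation", "DEFAULT_FIT_RANGE", "HOLDOUT_INTERVALS",
]

DEFAULT_FIT_RANGE = (742_000.0, 0.0)
#: four 25-kyr contrast intervals (years BP, right-open), most recent first
HOLDOUT_INTERVALS = ((0.0, 25_000.0), (25_000.0, 50_000.0),
                     (50_000.0, 75_000.0), (75_000.0, 100_000.0))

_HUMAN_TRENDS = ("logistic", "exponential", "linear", "presence_prob")
_HUMAN_CODE = {"logistic": "logH", "exponential": "expH",
               "linear": "linH", "presence_prob": "pH"}


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one trajectory model."""

    family: str                  # climate | human | combined
    temp_effect: str = "none"    # none | linear | quadratic
    precip_effect: str = "none"  # none | linear | quadratic
    lag: bool = False
    human_trend: str = "none"    # none | logistic | exponential | linear | presence_prob

    def __post_init__(self):
        if self.family not in ("climate", "human", "combined"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "climate" and self.human_trend != "none":
            raise ValueError("climate family cannot carry a human trend")
        if self.family == "human" and (self.temp_effect != "none"
                                       or self.precip_effect != "none" or self.lag):
            raise ValueError("human family cannot carry climate terms")
        if self.family == "combined" and (self.temp_effect == "none"
                                          or self.human_trend == "none"):
            raise ValueError("combined family needs both components")

    @property
    def label(self) -> str:
        parts = []
        if self.temp_effect != "none":
            parts.append({"linear": "linT", "quadratic": "quadT"}[self.temp_effect])
        if self.precip_effect != "none":
            parts.append({"linear": "linP", "quadratic": "quadP"}[self.precip_effect])
        if self.lag:
            parts.append("L")
        climate = "_".join(parts)
        if self.family == "climate":
            return climate
        human = _HUMAN_CODE[self.human_trend]
        if self.family == "human":
            return human
        return f"{climate}+{human}"

    @property
    def nonlinear(self) -> bool:
        return self.human_trend in ("logistic", "exponential", "linear")

    @property
    def climate_spec(self) -> "ModelSpec | None":
        if self.temp_effect == "none":
            return None
        return ModelSpec("climate", self.temp_effect, self.precip_effect, self.lag)


def _default_best_climate() -> list[ModelSpec]:
    # the four climate specs combined with human trends; the linear-in-both
    # model (the best-predicting climate form) plus its lag and quadratic kin
    return [
        ModelSpec("climate", "linear", "linear", False),
        ModelSpec("climate", "linear", "linear", True),
        ModelSpec("climate", "quadratic", "quadratic", False),
        ModelSpec("climate", "quadratic", "quadratic", True),
    ]


def enumerate_models(best_climate: list[ModelSpec] | None = None) -> list[ModelSpec]:
    """The full 32-model family: 12 climate + 4 human + 16 combined."""
    climate = [
        ModelSpec("climate", t, p, lag)
        for t, p, lag in itertools.product(("linear", "quadratic"),
                                           ("none", "linear", "quadratic"),
                                           (False, True))
    ]
    human = [ModelSpec("human", human_trend=h) for h in _HUMAN_TRENDS]
    if best_climate is None:
        best_climate = _default_best_climate()
    if len(best_climate) != 4:
        raise ValueError("need exactly 4 best-fitting climate specs")
    combined = [
        ModelSpec("combined", c.temp_effect, c.precip_effect, c.lag, h)
        for c, h in itertools.product(best_climate, _HUMAN_TRENDS)
    ]
    specs = climate + human + combined
    labels = [s.label for s in specs]
    assert len(set(labels)) == len(labels)
    return specs


def build_design(traj: NeTrajectory, spec: ModelSpec, climate: ClimateSeries | None,
                 arrival: ArrivalWindow | None,
                 fit_range: tuple[float, float] = DEFAULT_FIT_RANGE) -> pd.DataFrame:
    """One row per PSMC window with midpoint inside ``fit_range``.

    Response ``y`` is log10 window Ne; climate covariates are window means
    standardised over the fit-range rows; ``lag`` columns repeat the
    adjacent OLDER window's means (the oldest usable window reuses its own
    value and is flagged in ``lag_imputed``).  Human trends are consumed by
    the likelihood from the ``t_mid`` column, except the pH ramp which is a
    plain covariate.  Attributes ``spec`` and ``arrival`` travel in
    ``df.attrs``.
    """
    max_yr, min_yr = fit_range
    mids = traj.midpoints
    keep = (mids <= max_yr) & (mids >= min_yr)
    idx = np.where(keep)[0]
    if len(idx) == 0:
        raise ValueError("no trajectory windows inside fit_range")
    df = pd.DataFrame({
        "t_mid": mids[idx],
        "start_yr": traj.boundaries[idx],
        "end_yr": traj.boundaries[idx + 1],
        "y": np.log10(traj.ne[idx]),
    })
    needs_climate = spec.temp_effect != "none" or spec.precip_effect != "none"
    if needs_climate:
        if climate is None:
            raise ValueError(f"spec {spec.label} needs a climate series")
        lo, hi = climate.support
        tw = np.empty(len(idx)); pw = np.empty(len(idx))
        tl = np.empty(len(idx)); pl = np.empty(len(idx))
        lag_imp = np.zeros(len(idx), bool)
        for r, k in enumerate(idx):
            w = (max(traj.boundaries[k], lo), min(traj.boundaries[k + 1], hi))
            if w[0] >= w[1]:
                raise ValueError("trajectory window outside climate support")
            tw[r] = window_mean(climate, w, "temp")
            pw[r] = window_mean(climate, w, "precip")
            if k + 2 < len(traj.boundaries) and traj.boundaries[k + 1] < hi:
                wl = (max(traj.boundaries[k + 1], lo),
                      min(traj.boundaries[k + 2], hi))
                tl[r] = window_mean(climate, wl, "temp")
                pl[r] = window_mean(climate, wl, "precip")
            else:
                tl[r], pl[r] = tw[r], pw[r]
                lag_imp[r] = True

        def zs(v):
            s = v.std()
            # variance at rounding level counts as constant
            if s <= 1e-9 * max(1.0, abs(v.mean())):
                return np.zeros_like(v)
            return (v - v.mean()) / s

        if spec.temp_effect != "none":
            df["T"] = zs(tw)
            if spec.temp_effect == "quadratic":
                df["T2"] = df["T"] ** 2
        if spec.precip_effect != "none":
            df["P"] = zs(pw)
            if spec.precip_effect == "quadratic":
                df["P2"] = df["P"] ** 2
        if spec.lag:
            df["T_lag"] = zs(tl)
            df["P_lag"] = zs(pl)
            df["lag_imputed"] = lag_imp
            if lag_imp.any():
                warnings.warn("lag imputed with own-window values for the "
                              "oldest usable window(s)")
    if spec.human_trend == "presence_prob":
        if arrival is None:
            raise ValueError("pH spec needs an arrival window")
        df["pH"] = trends.presence_ramp(df["t_mid"].to_numpy(),
                                        arrival.earliest_yr, arrival.latest_yr)
    df.attrs["spec"] = spec
    df.attrs["arrival"] = arrival
    return df


_COVARIATE_COLS = ("T", "T2", "P", "P2", "T_lag", "P_lag", "pH")


def _linear_matrix(df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    cols = [c for c in _COVARIATE_COLS if c in df.columns]
    X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(float) for c in cols])
    return X, ["intercept"] + cols


@dataclass
class TrajectoryFit:
    """Posterior fit of one ModelSpec to one species' trajectory."""

    species_id: str
    spec: ModelSpec
    design: pd.DataFrame
    coef_names: list[str]
    coef_draws: np.ndarray            # (draws, p) linear coefficients
    human_draws: dict | None          # t_arr, rate, delta draws for nonlinear trends
    sigma_draws: np.ndarray
    loglik: np.ndarray                # (draws, n_windows)
    pred_log10_ne: np.ndarray         # posterior-median mean per window
    mse: float
    method: str
    converged: bool = True
    _loo: tuple | None = field(default=None, repr=False)

    @property
    def loo_elpd(self) -> float:
        return self.loo()[0]

    @property
    def loo_se(self) -> float:
        return self.loo()[1]

    def loo(self):
        if self._loo is None:
            self._loo = psis_loo(self.loglik)
        return self._loo

    def drop_draws(self) -> np.ndarray | None:
        """Posterior draws of the realised present-day human suppression
        (log10 units, negative = decline); None for non-human models."""
        if self.human_draws is not None:
            t0 = np.zeros(1)
            return np.array([
                trends.human_term(self.spec.human_trend, t0, ta, r, d)[0]
                for ta, r, d in zip(self.human_draws["t_arr"],
                                    self.human_draws["rate"],
                                    self.human_draws["delta"])])
        if "pH" in self.coef_names:
            j = self.coef_names.index("pH")
            return self.coef_draws[:, j]
        return None

    def summary(self) -> str:
        elpd, se, _, flagged = self.loo()
        lines = [f"TrajectoryFit[{self.species_id} ~ {self.spec.label}]",
                 "=" * 40,
                 f"windows          {len(self.design)}",
                 f"method           {self.method}",
                 f"PSIS-LOO elpd    {elpd:.2f} (SE {se:.2f})"
                 + ("  ** unreliable (pareto k) **" if flagged else ""),
                 f"in-sample MSE    {self.mse:.4f}"]
        for j, nm in enumerate(self.coef_names):
            lo, hi = hpdi(self.coef_draws[:, j], 0.95)
            lines.append(f"  {nm:<10} {np.median(self.coef_draws[:, j]):+.3f}"
                         f" [{lo:+.3f}, {hi:+.3f}]")
        if self.human_draws is not None:
            for nm in ("t_arr", "rate", "delta"):
                v = self.human_draws[nm]
                lo, hi = hpdi(v, 0.95)
                lines.append(f"  {nm:<10} {np.median(v):+.4g} [{lo:+.4g}, {hi:+.4g}]")
        if not self.converged:
            lines.append("  ** flagged: convergence diagnostics failed **")
        return "\n".join(lines)


class TrajectoryModel:
    """Model object binding a trajectory, a ModelSpec and its covariates."""

    def __init__(self, traj: NeTrajectory, spec: ModelSpec,
                 climate: ClimateSeries | None = None,
                 arrival: ArrivalWindow | None = None,
                 fit_range: tuple[float, float] = DEFAULT_FIT_RANGE):
        self.traj = traj
        self.spec = spec
        self.arrival = arrival
        self.design = build_design(traj, spec, climate, arrival, fit_range)
        if len(self.design) < 6:
            raise ValueError("need at least 6 windows to fit")
        if spec.nonlinear and arrival is None:
            raise ValueError(f"spec {spec.label} needs an arrival window")

    # -- nonlinear route -----------------------------------------------------
    def _nl_setup(self):
        X, names = _linear_matrix(self.design)
        y = self.design["y"].to_numpy(float)
        t = self.design["t_mid"].to_numpy(float)
        a = self.arrival
        p = X.shape[1]
        n = len(y)
        ybar = float(y.mean())
        trend = self.spec.human_trend
        halfnorm_c = 0.5 * np.log(2.0 / np.pi)

        def unpack(theta):
            # theta: (m, ndim) -> constrained parameter arrays of length m
            beta = theta[:, :p]
            u = special.expit(theta[:, p])
            t_arr = a.latest_yr + (a.earliest_yr - a.latest_yr) * u
            rate = np.exp(theta[:, p + 1])
            delta = np.exp(theta[:, p + 2])
            sigma = np.exp(theta[:, p + 3])
            return beta, u, t_arr, rate, delta, sigma

        def log_post(theta):
            theta = np.atleast_2d(np.asarray(theta, float))
            beta, u, t_arr, rate, delta, sigma = unpack(theta)
            mu = beta @ X.T + trends.human_term(trend, t, t_arr[:, None],
                                                rate[:, None], delta[:, None])
            r = y[None, :] - mu
            ll = -0.5 * (n * np.log(2 * np.pi) + 2 * n * np.log(sigma)
                         + (r * r).sum(axis=1) / sigma ** 2)
            lp = -0.5 * ((beta[:, 0] - ybar) / 10.0) ** 2
            if p > 1:
                lp = lp - 0.5 * (beta[:, 1:] ** 2).sum(axis=1)
            lp = lp + np.log(u) + np.log1p(-u)   # uniform t_arr, logit Jacobian
            for val, logval in ((rate, theta[:, p + 1]), (delta, theta[:, p + 2]),
                                (sigma, theta[:, p + 3])):
                lp = lp + halfnorm_c - 0.5 * val ** 2 + logval
            out = ll + lp
            return np.where(np.isfinite(out), out, -np.inf)

        x0 = np.zeros(p + 4)
        x0[0] = ybar
        x0[p + 1] = 0.0
        x0[p + 2] = np.log(max(abs(y.max() - y.min()), 0.1))
        x0[p + 3] = np.log(max(y.std() * 0.5, 0.05))
        return X, names, y, t, unpack, log_post, x0

    def fit(self, config: MCMCConfig | None = None, method: str = "auto",
            seed: int = 0) -> TrajectoryFit:
        if config is None:
            config = MCMCConfig()
        if method == "auto":
            method = "emcee" if self.spec.nonlinear else "conjugate"
        y = self.design["y"].to_numpy(float)
        if not self.spec.nonlinear:
            X, names = _linear_matrix(self.design)
            m = ConjugateLinearModel(X, y, v0=100.0)
            beta, s2 = m.sample(config.posterior_samples, seed=seed)
            sigma = np.sqrt(s2)
            loglik = m.pointwise_loglik(beta, s2)
            mu_draws = beta @ X.T
            human = None
            converged = True
            used = "conjugate"
        else:
            X, names, y, t, unpack, log_post, x0 = self._nl_setup()
            ndim = len(x0)
            if method == "laplace":
                flat = laplace_sir(log_post, ndim, x0,
                                   config.posterior_samples, seed=seed)
                converged = True
            else:
                draws = sample_emcee(log_post, ndim, x0, config, seed=seed,
                                     vectorize=True)
                diag = convergence(draws)
                converged = diag["converged"]
                if not converged:
                    warnings.warn(f"{self.spec.label}: R-hat >= 1.01, fit flagged")
                flat_all = draws.reshape(-1, ndim)
                rng = np.random.default_rng(seed + 7)
                take = rng.choice(len(flat_all),
                                  size=min(config.posterior_samples, len(flat_all)),
                                  replace=False)
                flat = flat_all[take]
            p = X.shape[1]
            beta, _, t_arr, rate, delta, sigma = unpack(flat)
            mu_draws = beta @ X.T + trends.human_term(
                self.spec.human_trend, t, t_arr[:, None], rate[:, None],
                delta[:, None])
            r_ = y[None, :] - mu_draws
            loglik = -0.5 * (np.log(2 * np.pi * sigma[:, None] ** 2)
                             + r_ ** 2 / sigma[:, None] ** 2)
            human = {"t_arr": t_arr, "rate": rate, "delta": delta}
            used = method
        pred = np.median(mu_draws, axis=0)
        mse = float(np.mean((y - pred) ** 2))
        return TrajectoryFit(
            species_id=self.traj.species_id, spec=self.spec, design=self.design,
            coef_names=names, coef_draws=beta, human_draws=human,
            sigma_draws=sigma, loglik=loglik, pred_log10_ne=pred, mse=mse,
            method=used, converged=converged,
        )


def fit_model(design: pd.DataFrame, spec: ModelSpec | None = None,
              mcmc: MCMCConfig | None = None, method: str = "auto",
              seed: int = 0, traj: NeTrajectory | None = None,
              climate: ClimateSeries | None = None,
              arrival: ArrivalWindow | None = None) -> TrajectoryFit:
    """Functional wrapper; prefer :class:`TrajectoryModel` directly."""
    if traj is None:
        raise ValueError("fit_model needs the trajectory (traj=...)")
    spec = spec or design.attrs.get("spec")
    arrival = arrival or design.attrs.get("arrival")
    model = TrajectoryModel.__new__(TrajectoryModel)
    model.traj, model.spec, model.arrival, model.design = traj, spec, arrival, design
    if len(design) < 6:
        raise ValueError("need at least 6 windows to fit")
    return TrajectoryModel.fit(model, config=mcmc, method=method, seed=seed)


def loo_score(fit: TrajectoryFit) -> tuple[float, float]:
    """PSIS-LOO elpd and SE; warns when Pareto-k diagnostics are unreliable."""
    elpd, se, k, flagged = fit.loo()
    if flagged:
        warnings.warn(f"{fit.spec.label}/{fit.species_id}: >10% of Pareto k "
                      "above 0.7; LOO score unreliable")
    return elpd, se


def rank_models(fits: dict[str, dict[str, TrajectoryFit]]) -> pd.DataFrame:
    """Rank specs by total PSIS-LOO elpd summed across species.

    ``fits`` maps spec label -> {species_id -> fit}.  Every spec must cover
    the same species set.  Returns a DataFrame sorted best-first with
    columns label, family, elpd_total, se_total, rank, and the share of
    species whose posterior present-day suppression HPDI excludes zero.
    """
    all_species = sorted({s for d in fits.values() for s in d})
    gaps = [(lab, s) for lab, d in fits.items() for s in all_species if s not in d]
    if gaps:
        raise ValueError(f"missing species x spec fits: {gaps}")
    rows = []
    for lab, d in fits.items():
        elpds, ses = zip(*(loo_score(d[s]) for s in all_species))
        n_neg = 0
        n_h = 0
        for s in all_species:
            dd = d[s].drop_draws()
            if dd is not None:
                n_h += 1
                lo, hi = hpdi(dd, 0.95)
                if hi < 0:
                    n_neg += 1
        rows.append({
            "label": lab, "family": d[all_species[0]].spec.family,
            "elpd_total": float(np.sum(elpds)),
            "se_total": float(np.sqrt(np.sum(np.square(ses)))),
            "share_negative_trend": (n_neg / n_h) if n_h else np.nan,
        })
    out = pd.DataFrame(rows).sort_values("elpd_total", ascending=False)
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def fit_predict_holdout(traj: NeTrajectory, spec: ModelSpec,
                        climate: ClimateSeries, arrival: ArrivalWindow | None = None,
                        split_yr: float = 100_000.0,
                        config: MCMCConfig | None = None, method: str = "auto",
                        seed: int = 0) -> dict:
    """Fit on windows older than ``split_yr``, predict the newer windows.

    The climate covariates of the held-out windows are standardised with the
    fit-side statistics.  Returns the per-window predictions, squared
    errors, and the MSE aggregated into the four 25-kyr intervals.
    """
    if config is None:
        config = MCMCConfig()
    full = build_design(traj, spec, climate, arrival, fit_range=DEFAULT_FIT_RANGE)
    fit_mask = full["t_mid"] > split_yr
    if fit_mask.all() or not fit_mask.any():
        raise ValueError("need windows on both sides of the split")
    # re-standardise climate columns using fit-side statistics
    for c in _COVARIATE_COLS:
        if c in full.columns and c not in ("pH",) and not c.endswith("2"):
            raw = full[c].to_numpy(float)
            m, s = raw[fit_mask].mean(), raw[fit_mask].std()
            full[c] = (raw - m) / (s if s > 0 else 1.0)
    for c in ("T2", "P2"):
        if c in full.columns:
            full[c] = full[c[0]] ** 2
    fit_df = full[fit_mask].reset_index(drop=True)
    fit_df.attrs.update(full.attrs)
    hold_df = full[~fit_mask].reset_index(drop=True)
    f = fit_model(fit_df, spec, mcmc=config, method=method, seed=seed,
                  traj=traj, arrival=arrival)
    Xh = np.column_stack([np.ones(len(hold_df))]
                         + [hold_df[c].to_numpy(float) for c in f.coef_names[1:]])
    mu = f.coef_draws @ Xh.T
    if f.human_draws is not None:
        th = hold_df["t_mid"].to_numpy(float)
        mu = mu + np.stack([
            trends.human_term(spec.human_trend, th, ta, r, d)
            for ta, r, d in zip(f.human_draws["t_arr"], f.human_draws["rate"],
                                f.human_draws["delta"])])
    pred = np.median(mu, axis=0)
    obs = hold_df["y"].to_numpy(float)
    sq = (obs - pred) ** 2
    interval_mse = {}
    for lo, hi in HOLDOUT_INTERVALS:
        m = (hold_df["t_mid"] >= lo) & (hold_df["t_mid"] < hi)
        interval_mse[f"{int(lo/1000)}-{int(hi/1000)}kya"] = \
            float(sq[m.to_numpy()].mean()) if m.any() else np.nan
    return {"fit": f, "t_mid": hold_df["t_mid"].to_numpy(float),
            "observed": obs, "predicted": pred, "sq_error": sq,
            "interval_mse": interval_mse}


@dataclass(frozen=True)
class WindowContrast:
    interval: str
    t_stat: float
    df: int
    p_value: float
    cohens_d: float
    ci_low: float
    ci_high: float
    mean_diff: float


def compare_windows(observed: pd.DataFrame, predicted: pd.DataFrame,
                    df_convention: str = "n") -> list[WindowContrast]:
    """Paired contrasts of species-mean observed vs predicted log10 Ne.

    Both inputs are species x interval tables with identical indexes and
    columns.  Cohen's d is the mean paired difference over the SD of the
    differences; ``df_convention="n"`` reports n (the convention used for
    the published contrasts), ``"n-1"`` the usual t-test degrees of freedom.
    """
    if not observed.index.equals(predicted.index) or \
            not observed.columns.equals(predicted.columns):
        raise ValueError("observed and predicted must share index and columns")
    if len(observed) < 3:
        raise ValueError("need at least 3 species")
    out = []
    n = len(observed)
    rep_df = n if df_convention == "n" else n - 1
    for col in observed.columns:
        diff = observed[col].to_numpy(float) - predicted[col].to_numpy(float)
        t, p = sps.ttest_rel(observed[col], predicted[col])
        sd = diff.std(ddof=1)
        d = diff.mean() / sd if sd > 0 else 0.0
        se = sd / np.sqrt(n)
        ci = sps.t.interval(0.95, n - 1, loc=diff.mean(), scale=se) if sd > 0 \
            else (diff.mean(), diff.mean())
        out.append(WindowContrast(str(col), float(t), int(rep_df), float(p),
                                  float(d), float(ci[0]), float(ci[1]),
                                  float(diff.mean())))
    return out


def human_megafauna_correlation(human_traj: NeTrajectory, mean_trend,
                                time_range: tuple[float, float],
                                n_grid: int = 50) -> dict:
    """Correlation of human Ne with the mean megafauna trend on a log-time grid.

    ``mean_trend`` is either an :class:`NeTrajectory` or the DataFrame
    returned by :func:`megadecline.trajectories.average_trend`.  Returns
    Pearson and Spearman coefficients with p-values.
    """
    from_yr, to_yr = max(time_range), min(time_range)
    lo = max(to_yr, human_traj.support[0], 1.0)
    hi = min(from_yr, human_traj.support[1] * (1 - 1e-12))
    if isinstance(mean_trend, NeTrajectory):
        lo = max(lo, mean_trend.support[0])
        hi = min(hi, mean_trend.support[1] * (1 - 1e-12))
        # the grid cannot be finer than the coarser series' windows
        resolvable = min(
            int(np.sum((human_traj.midpoints >= lo)
                       & (human_traj.midpoints <= hi))),
            int(np.sum((mean_trend.midpoints >= lo)
                       & (mean_trend.midpoints <= hi))))
        if resolvable < 5:
            raise ValueError("fewer than 5 resolvable grid points in range")
        grid = np.geomspace(max(lo, 1.0), hi, n_grid)
        mega = np.log10(mean_trend.value_at(grid))
    else:
        t = mean_trend["t_yr"].to_numpy(float)
        keep = (t >= lo) & (t <= hi)
        grid = t[keep]
        mega = mean_trend["mean_log10_ne"].to_numpy(float)[keep]
    if len(grid) < 5:
        raise ValueError("fewer than 5 grid points in the overlap range")
    hum = np.log10(human_traj.value_at(grid))
    pr, pp = sps.pearsonr(hum, mega)
    sr, sp = sps.spearmanr(hum, mega)
    return {"pearson": float(pr), "pearson_p": float(pp),
            "spearman": float(sr), "spearman_p": float(sp), "n": len(grid)}
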