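"""Shared posterior machinery: samplers, HPDI, diagnostics and LOO scoring.

Three complementary fitting routes are provided and used across the
modelling modules:

* :func:`sample_emcee` — affine-invariant ensemble MCMC (emcee) over an
  arbitrary log-posterior, reshaped into pseudo-chains for split-R-hat and
  effective-sample-size diagnostics via arviz.
* :func:`laplace_sample` — mode-finding plus Gaussian (Laplace)
  approximation in an unconstrained parameterisation; orders of magnitude
  faster, used for large simulation studies.
* :class:`ConjugateLinearModel` — exact normal-inverse-gamma posterior for
  Gaussian linear regression, including the closed-form leave-one-out
  predictive density (Student-t), which serves as the independent oracle for
  PSIS-LOO checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

import arviz as az

__all__ = [
    "hpdi",
    "sample_emcee",
    "laplace_sample",
    "ConjugateLinearModel",
    "psis_loo",
    "MCMCConfig",
]

RHAT_LIMIT = 1.01


@dataclass(frozen=True)
class MCMCConfig:
    """MCMC settings; defaults are 4 chains, 2000 warm-up + 2000 draws."""

    chains: int = 4
    warmup: int = 2000
    draws: int = 2000
    walkers: int = 32
    posterior_samples: int = 1000  # thinned draws used for reported summaries
    seed: int = 0

    def reduced(self, warmup: int, draws: int) -> "MCMCConfig":
        return MCMCConfig(self.chains, warmup, draws, self.walkers,
                          min(self.posterior_samples, draws), self.seed)


def hpdi(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Narrowest contiguous interval containing ``prob`` of sorted draws."""
    if not (0.0 < prob < 1.0):
        raise ValueError("prob must be in (0, 1)")
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 draws")
    k = int(np.ceil(prob * n))
    k = min(max(k, 1), n)
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def sample_emcee(log_prob, ndim: int, x0: np.ndarray, config: MCMCConfig,
                 seed: int | None = None, vectorize: bool = False):
    """Run an emcee ensemble and return draws shaped (chains, draws, ndim).

    The ensemble is initialised in a small ball around ``x0``, burnt in for
    ``config.warmup`` steps, run for ``config.draws`` steps, and the walkers
    are partitioned into ``config.chains`` groups that play the role of
    independent chains in split-R-hat / ESS diagnostics.  With
    ``vectorize=True`` the log-probability is called on (nwalkers, ndim)
    arrays.
    """
    import emcee

    rng = np.random.default_rng(config.seed if seed is None else seed)
    nwalkers = max(config.walkers, 2 * ndim + 2)
    nwalkers -= nwalkers % config.chains
    p0 = x0[None, :] + 1e-3 * rng.standard_normal((nwalkers, ndim))
    sampler = emcee.EnsembleSampler(nwalkers, ndim, log_prob,
                                    vectorize=vectorize)
    state = sampler.run_mcmc(p0, config.warmup, skip_initial_state_check=True)
    sampler.reset()
    sampler.run_mcmc(state, config.draws, skip_initial_state_check=True)
    chain = sampler.get_chain()  # (draws, walkers, ndim)
    per = nwalkers // config.chains
    draws = np.stack(
        [chain[:, i * per:(i + 1) * per, :].reshape(-1, ndim)
         for i in range(config.chains)]
    )  # (chains, draws*per, ndim)
    return draws


def convergence(draws: np.ndarray) -> dict:
    """Split-R-hat and bulk ESS per parameter for (chains, draws, ndim)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = np.array([float(az.rhat(draws[..., j])) for j in range(draws.shape[-1])])
        ess = np.array([float(az.ess(draws[..., j])) for j in range(draws.shape[-1])])
    return {"rhat": rhat, "ess": ess, "converged": bool(np.all(rhat < RHAT_LIMIT))}


def laplace_sample(neg_log_post, ndim: int, x0: np.ndarray, n_draws: int,
                   seed: int = 0, n_restarts: int = 2) -> np.ndarray:
    """Gaussian posterior approximation at the mode (unconstrained space).

    Minimises ``neg_log_post``, forms the Hessian by central differences and
    draws ``n_draws`` samples from N(mode, H^{-1}).  Returns (n_draws, ndim).
    """
    rng = np.random.default_rng(seed)
    best = None
    for r in range(n_restarts):
        start = x0 if r == 0 else x0 + 0.5 * rng.standard_normal(ndim)
        res = optimize.minimize(neg_log_post, start, method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
    mode = best.x
    h = 1e-4 * np.maximum(np.abs(mode), 1.0)
    H = np.empty((ndim, ndim))
    for i in range(ndim):
        for j in range(i, ndim):
            ei = np.zeros(ndim); ei[i] = h[i]
            ej = np.zeros(ndim); ej[j] = h[j]
            f_pp = neg_log_post(mode + ei + ej)
            f_pm = neg_log_post(mode + ei - ej)
            f_mp = neg_log_post(mode - ei + ej)
            f_mm = neg_log_post(mode - ei - ej)
            H[i, j] = H[j, i] = (f_pp - f_pm - f_mp + f_mm) / (4 * h[i] * h[j])
    # regularise to SPD
    w, V = np.linalg.eigh(0.5 * (H + H.T))
    w = np.clip(w, 1e-8, None)
    cov = (V / w) @ V.T
    L = np.linalg.cholesky(0.5 * (cov + cov.T) + 1e-12 * np.eye(ndim))
    z = rng.standard_normal((n_draws, ndim))
    return mode[None, :] + z @ L.T


def laplace_sir(log_post_vec, ndim: int, x0: np.ndarray, n_draws: int,
                seed: int = 0, n_proposal: int = 4000,
                proposal_scale: float = 1.3, proposal_df: float = 7.0,
                n_restarts: int = 3) -> np.ndarray:
    """Laplace proposal + sampling importance resampling.

    ``log_post_vec`` must accept an (m, ndim) array and return (m,) log
    posteriors.  A multivariate-t proposal centred at the posterior mode
    (covariance = inflated inverse Hessian) is corrected by importance
    weights and resampled, which repairs the non-Gaussian geometry that a
    plain Laplace approximation misses (e.g. weakly identified arrival
    times).  Returns (n_draws, ndim).
    """
    rng = np.random.default_rng(seed)

    def neg(theta):
        return -float(log_post_vec(theta[None, :])[0])

    # mode finding with jittered restarts: bounded nonlinear terms (arrival
    # saturation) leave flat plateaus where a single start can strand
    bounds = [(-15.0, 15.0)] * ndim
    best = None
    for r in range(n_restarts):
        start = x0 if r == 0 else np.clip(
            x0 + 0.8 * np.random.default_rng(seed + 100 + r).standard_normal(ndim),
            -14.0, 14.0)
        res = optimize.minimize(neg, start, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    mode = best.x
    h = 1e-4 * np.maximum(np.abs(mode), 1.0)
    H = np.empty((ndim, ndim))
    for i in range(ndim):
        for j in range(i, ndim):
            ei = np.zeros(ndim); ei[i] = h[i]
            ej = np.zeros(ndim); ej[j] = h[j]
            H[i, j] = H[j, i] = (neg(mode + ei + ej) - neg(mode + ei - ej)
                                 - neg(mode - ei + ej) + neg(mode - ei - ej)
                                 ) / (4 * h[i] * h[j])
    w, V = np.linalg.eigh(0.5 * (H + H.T))
    # transformed parameters are unit-order: cap proposal sd at 5 per
    # direction so a flat (unidentified) direction cannot blow up the
    # proposal and starve the importance weights
    w = np.clip(w, 1.0 / 25.0, None)
    cov = (V / w) @ V.T * proposal_scale ** 2
    L = np.linalg.cholesky(0.5 * (cov + cov.T) + 1e-12 * np.eye(ndim))
    z = rng.standard_normal((n_proposal, ndim))
    g = rng.chisquare(proposal_df, size=n_proposal) / proposal_df
    prop = mode[None, :] + (z / np.sqrt(g)[:, None]) @ L.T
    lp = log_post_vec(prop)
    # multivariate-t log density (constants cancel in the weights)
    d2 = np.einsum("ij,ij->i", z, z) / g
    logq = -0.5 * (proposal_df + ndim) * np.log1p(d2 / proposal_df)
    lw = lp - logq
    lw -= lw.max()
    wts = np.exp(lw)
    wts /= wts.sum()
    idx = rng.choice(n_proposal, size=n_draws, replace=True, p=wts)
    return prop[idx]


class ConjugateLinearModel:
    """Bayesian Gaussian linear regression with an exact NIG posterior.

    y | b, s2 ~ N(X b, s2 I);  b | s2 ~ N(0, s2 * v0 I);  s2 ~ InvGamma(a0, b0).
    Weakly-informative defaults suit standardised predictors.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, v0: float = 100.0,
                 a0: float = 0.01, b0: float = 0.01):
        X = np.atleast_2d(np.asarray(X, float))
        y = np.asarray(y, float)
        self.X, self.y = X, y
        self.v0, self.a0, self.b0 = v0, a0, b0
        n, p = X.shape
        V0inv = np.eye(p) / v0
        self.Vn = np.linalg.inv(V0inv + X.T @ X)
        self.bn = self.Vn @ (X.T @ y)
        self.an = a0 + n / 2.0
        self.bn_ig = b0 + 0.5 * (y @ y - self.bn @ (V0inv + X.T @ X) @ self.bn)
        self.n, self.p = n, p

    def sample(self, n_draws: int, seed: int = 0):
        """Return (beta_draws (n_draws, p), sigma2_draws (n_draws,))."""
        rng = np.random.default_rng(seed)
        s2 = self.bn_ig / rng.gamma(self.an, 1.0, size=n_draws)
        L = np.linalg.cholesky(0.5 * (self.Vn + self.Vn.T) + 1e-14 * np.eye(self.p))
        z = rng.standard_normal((n_draws, self.p))
        beta = self.bn[None, :] + np.sqrt(s2)[:, None] * (z @ L.T)
        return beta, s2

    def pointwise_loglik(self, beta: np.ndarray, s2: np.ndarray) -> np.ndarray:
        """(n_draws, n_obs) Gaussian log density of each observation."""
        mu = beta @ self.X.T
        r = self.y[None, :] - mu
        return -0.5 * (np.log(2 * np.pi * s2[:, None]) + r ** 2 / s2[:, None])

    def log_predictive(self, x_new: np.ndarray, y_new: float) -> float:
        """Closed-form posterior predictive log density (Student-t)."""
        x_new = np.asarray(x_new, float)
        mu = float(x_new @ self.bn)
        scale2 = (self.bn_ig / self.an) * (1.0 + float(x_new @ self.Vn @ x_new))
        df = 2.0 * self.an
        return float(stats.t.logpdf(y_new, df, loc=mu, scale=np.sqrt(scale2)))

    def exact_loo(self) -> float:
        """Exact leave-one-out elpd: sum_i log p(y_i | y_{-i}) by refitting."""
        total = 0.0
        for i in range(self.n):
            mask = np.arange(self.n) != i
            sub = ConjugateLinearModel(self.X[mask], self.y[mask],
                                       self.v0, self.a0, self.b0)
            total += sub.log_predictive(self.X[i], self.y[i])
        return total


def psis_loo(loglik: np.ndarray):
    """PSIS-LOO elpd from a pointwise log-likelihood array.

    Accepts (draws, n_obs) or (chains, draws, n_obs); returns
    ``(elpd, se, pareto_k, flagged)`` where ``flagged`` is True when more
    than 10% of observations have Pareto k > 0.7.
    """
    ll = np.asarray(loglik, float)
    if ll.ndim == 2:
        ll = ll[None, ...]
    idata = az.from_dict(
        posterior={"_dummy": np.zeros(ll.shape[:2])},
        log_likelihood={"y": ll},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = az.loo(idata, pointwise=True)
    k = np.asarray(res.pareto_k)
    flagged = bool(np.mean(k > 0.7) > 0.10)
    return float(res.elpd_loo), float(res.se), k, flagged
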