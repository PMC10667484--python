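"""Species-level decline statistics.

Covers decline severity (1 - min/max Ne, reported as percent reduction),
the Bayesian hierarchical model of per-species slopes with a body-mass
effect, its phylogenetic variant, the severity regression, the one-per-genus
subset used to damp shared ancestry, and the pooled Ne-vs-time rank
correlation.

The hierarchical model is

    y_ij = a_i + s_i * x_ij + e_ij,      e_ij ~ N(0, sigma^2)
    a_i ~ N(mu_a, tau_a^2)
    s_i ~ N(alpha + beta * z_i, tau_s^2)

with y = log10 Ne, x = centred log10 time oriented toward the present (so a
declining species has s_i < 0) and z = standardised log10 body mass.  The
species-level intercepts and slopes are Gaussian, so they are integrated out
analytically (low-rank Woodbury identities on per-species sufficient
statistics) and only the six hyperparameters are sampled with MCMC; slope
posteriors are then drawn exactly from their conditional Gaussians.  The
phylogenetic variant correlates slope residuals through a Brownian-motion
covariance with an estimated lambda weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .bayes import (ConjugateLinearModel, MCMCConfig, convergence, hpdi,
                    sample_emcee)
from .trajectories import NeTrajectory, SpeciesTraits

__all__ = [
    "SeverityRecord", "decline_severity", "hpdi",
    "HierarchicalSlopeModel", "SlopeResults", "fit_slope_model",
    "SeverityModel", "fit_severity_model",
    "genus_subset", "fit_phylo_slope_model", "spearman_ne_time",
    "phylo_vcv",
]


# ---------------------------------------------------------------------------
# severity

@dataclass(frozen=True)
class SeverityRecord:
    species_id: str
    ne_min: float
    ne_max: float
    severity: float      # 1 - ne_min/ne_max, in [0, 1)
    t_min_yr: float      # midpoint (years BP) of the argmin window
    t_max_yr: float


def decline_severity(traj: NeTrajectory) -> SeverityRecord:
    """Fraction reduction from a trajectory's maximum to its minimum Ne.

    Scans all intervals regardless of temporal order; ties break toward the
    most recent (smallest years-BP) window.
    """
    mids = traj.midpoints
    ne = traj.ne
    # argmin/argmax with most-recent tie-break: scan from the recent end
    i_min = int(np.argmin(ne))
    i_max = int(np.argmax(ne))
    return SeverityRecord(
        species_id=traj.species_id,
        ne_min=float(ne[i_min]), ne_max=float(ne[i_max]),
        severity=float(1.0 - ne[i_min] / ne[i_max]),
        t_min_yr=float(mids[i_min]), t_max_yr=float(mids[i_max]),
    )


# ---------------------------------------------------------------------------
# hierarchical slope model

def _suffstats(trajs: list[NeTrajectory], traits: list[SpeciesTraits]):
    by_id = {t.species_id: t for t in traits}
    rows = []
    for tr in trajs:
        if tr.species_id not in by_id:
            continue
        mid = tr.midpoints
        keep = mid > 0
        rows.append((tr.species_id, -np.log10(mid[keep]), np.log10(tr.ne[keep])))
    if len(rows) < 3:
        raise ValueError("need at least 3 species with trajectories and masses")
    xbar = np.mean(np.concatenate([r[1] for r in rows]))
    ids = [r[0] for r in rows]
    logm = np.log10([by_id[i].mass_kg for i in ids])
    if np.ptp(logm) == 0:
        raise ValueError("body mass is constant across species; "
                         "the mass effect is unidentifiable")
    z = (logm - logm.mean()) / logm.std()
    S = len(rows)
    st = {k: np.empty(S) for k in ("n", "Sx", "Sxx", "Sy", "Syy", "Sxy")}
    for i, (_, x, y) in enumerate(rows):
        xc = x - xbar
        st["n"][i] = len(xc)
        st["Sx"][i] = xc.sum();  st["Sxx"][i] = (xc * xc).sum()
        st["Sy"][i] = y.sum();   st["Syy"][i] = (y * y).sum()
        st["Sxy"][i] = (xc * y).sum()
    st["z"] = z
    st["ids"] = ids
    st["ybar"] = float(np.mean(np.concatenate([r[2] for r in rows])))
    st["xbar"] = float(xbar)
    return st


def _unpack(theta):
    mu_a, alpha, beta = theta[..., 0], theta[..., 1], theta[..., 2]
    sig = np.exp(theta[..., 3]); tau_a = np.exp(theta[..., 4])
    tau_s = np.exp(theta[..., 5])
    return mu_a, alpha, beta, sig, tau_a, tau_s


_HALFNORM_C = 0.5 * np.log(2.0 / np.pi)


def _log_prior(theta, ybar):
    # N(ybar, 10) on mu_a; N(0,1) on alpha, beta; half-N(0,1) on the scales
    # with log-parameterisation Jacobians.  Inlined for sampler throughput.
    mu_a, alpha, beta, sig, tau_a, tau_s = _unpack(theta)
    lp = -0.5 * ((mu_a - ybar) / 10.0) ** 2
    lp = lp - 0.5 * (alpha ** 2 + beta ** 2)
    for s, logs in ((sig, theta[..., 3]), (tau_a, theta[..., 4]),
                    (tau_s, theta[..., 5])):
        lp = lp + _HALFNORM_C - 0.5 * s ** 2 + logs
    return lp


def _marginal_loglik(theta, st) -> float:
    """Marginal log-likelihood with species effects integrated out (Woodbury)."""
    mu_a, alpha, beta, sig, tau_a, tau_s = _unpack(np.asarray(theta))
    s2 = sig ** 2
    sbar = alpha + beta * st["z"]
    n, Sx, Sxx = st["n"], st["Sx"], st["Sxx"]
    Sy, Syy, Sxy = st["Sy"], st["Syy"], st["Sxy"]
    # residual sufficient statistics r = y - mu_a - sbar * x
    rr = (Syy - 2 * mu_a * Sy - 2 * sbar * Sxy + mu_a ** 2 * n
          + 2 * mu_a * sbar * Sx + sbar ** 2 * Sxx)
    Ur1 = Sy - mu_a * n - sbar * Sx
    Ur2 = Sxy - mu_a * Sx - sbar * Sxx
    # K = D^{-1} + U'U / s2 for each species (2x2)
    a11 = 1.0 / tau_a ** 2 + n / s2
    a12 = Sx / s2
    a22 = 1.0 / tau_s ** 2 + Sxx / s2
    det_k = a11 * a22 - a12 ** 2
    if np.any(det_k <= 0) or not np.isfinite(det_k).all():
        return -np.inf
    # det(Sigma) = s2^n * det(D) * det(K)
    logdet = (n * np.log(s2) + 2 * np.log(tau_a) + 2 * np.log(tau_s)
              + np.log(det_k))
    # quadratic form via the Woodbury identity
    kinv_ur1 = (a22 * Ur1 - a12 * Ur2) / det_k
    kinv_ur2 = (a11 * Ur2 - a12 * Ur1) / det_k
    quad = rr / s2 - (Ur1 * kinv_ur1 + Ur2 * kinv_ur2) / s2 ** 2
    ll = -0.5 * np.sum(n * np.log(2 * np.pi) + logdet + quad)
    return float(ll) if np.isfinite(ll) else -np.inf


def _conditional_slope_draws(hyper_draws, st, rng) -> np.ndarray:
    """Exact draws of per-species slopes given hyperparameter draws."""
    out = np.empty((len(hyper_draws), len(st["z"])))
    for d, theta in enumerate(hyper_draws):
        mu_a, alpha, beta, sig, tau_a, tau_s = _unpack(theta)
        s2 = sig ** 2
        sbar = alpha + beta * st["z"]
        a11 = 1.0 / tau_a ** 2 + st["n"] / s2
        a12 = st["Sx"] / s2
        a22 = 1.0 / tau_s ** 2 + st["Sxx"] / s2
        det_k = a11 * a22 - a12 ** 2
        b1 = mu_a / tau_a ** 2 + st["Sy"] / s2
        b2 = sbar / tau_s ** 2 + st["Sxy"] / s2
        mean_s = (a11 * b2 - a12 * b1) / det_k
        var_s = a11 / det_k
        out[d] = mean_s + np.sqrt(np.clip(var_s, 0, None)) * rng.standard_normal(len(sbar))
    return out


@dataclass
class SlopeResults:
    """Posterior of the hierarchical slope model.

    ``slope_draws`` has shape (draws, species); ``beta_draws`` are mass-effect
    draws on the standardised log10-mass scale.
    """

    species_ids: list[str]
    slope_draws: np.ndarray
    beta_draws: np.ndarray
    alpha_draws: np.ndarray
    hyper_draws: np.ndarray      # (chains, draws, 6)
    rhat: np.ndarray
    ess: np.ndarray
    converged: bool

    @property
    def beta_hpdi(self) -> tuple[float, float]:
        return hpdi(self.beta_draws, 0.95)

    def species_table(self) -> pd.DataFrame:
        med = np.median(self.slope_draws, axis=0)
        lo, hi = zip(*(hpdi(self.slope_draws[:, j], 0.95)
                       for j in range(self.slope_draws.shape[1])))
        return pd.DataFrame({"species_id": self.species_ids, "slope_median": med,
                             "hpdi_lo": lo, "hpdi_hi": hi})

    def summary(self) -> str:
        b_lo, b_hi = self.beta_hpdi
        tab = self.species_table()
        frac_neg = float(np.mean(tab["hpdi_hi"] < 0))
        return "\n".join([
            "Hierarchical slope model (mass effect on decline rate)",
            "=" * 54,
            f"species                      {len(self.species_ids)}",
            f"mass effect beta (median)    {np.median(self.beta_draws):+.4f}",
            f"beta 95% HPDI                [{b_lo:+.4f}, {b_hi:+.4f}]",
            f"species with HPDI < 0        {frac_neg:.0%}",
            f"max R-hat                    {self.rhat.max():.4f}"
            + ("" if self.converged else "  ** NOT CONVERGED **"),
        ])


class HierarchicalSlopeModel:
    """Partially pooled per-species decline slopes with a body-mass effect."""

    def __init__(self, trajs: list[NeTrajectory], traits: list[SpeciesTraits],
                 phylo_corr: np.ndarray | None = None):
        self.st = _suffstats(trajs, traits)
        self.phylo_corr = phylo_corr

    def _log_post(self, theta):
        lp = float(_log_prior(np.asarray(theta), self.st["ybar"]))
        if not np.isfinite(lp):
            return -np.inf
        if self.phylo_corr is None:
            return lp + _marginal_loglik(theta, self.st)
        return lp + _phylo_loglik(theta, self.st, self.phylo_corr)

    def _start(self, ndim):
        st = self.st
        slopes = (st["Sxy"] - st["Sx"] * st["Sy"] / st["n"]) / \
            np.maximum(st["Sxx"] - st["Sx"] ** 2 / st["n"], 1e-9)
        x0 = np.zeros(ndim)
        x0[0] = st["ybar"]
        x0[1] = float(np.mean(slopes))
        x0[2] = 0.0
        x0[3] = np.log(0.15); x0[4] = np.log(0.5); x0[5] = np.log(0.2)
        if ndim == 7:
            x0[6] = 0.0
        return x0

    def fit(self, config: MCMCConfig | None = None, seed: int = 0) -> SlopeResults:
        if config is None:
            config = MCMCConfig()
        ndim = 6 if self.phylo_corr is None else 7
        draws = sample_emcee(self._log_post, ndim, self._start(ndim), config,
                             seed=seed)
        diag = convergence(draws)
        if not diag["converged"]:
            warnings.warn("hierarchical slope model: R-hat >= 1.01; "
                          "results flagged as not converged")
        flat = draws.reshape(-1, ndim)
        rng = np.random.default_rng(seed + 1)
        take = rng.choice(len(flat), size=min(config.posterior_samples, len(flat)),
                          replace=False)
        hypers = flat[take]
        slope_draws = _conditional_slope_draws(hypers, self.st, rng)
        return SlopeResults(
            species_ids=list(self.st["ids"]),
            slope_draws=slope_draws,
            beta_draws=hypers[:, 2],
            alpha_draws=hypers[:, 1],
            hyper_draws=draws,
            rhat=diag["rhat"], ess=diag["ess"], converged=diag["converged"],
        )


def _phylo_loglik(theta, st, C) -> float:
    """Joint marginal likelihood with slope residuals correlated by lambda*C."""
    theta = np.asarray(theta)
    mu_a, alpha, beta, sig, tau_a, tau_s = _unpack(theta[:6])
    lam = 1.0 / (1.0 + np.exp(-theta[6]))
    s2 = sig ** 2
    S = len(st["z"])
    sbar = alpha + beta * st["z"]
    R = lam * C + (1 - lam) * np.eye(S)
    try:
        R_inv = np.linalg.inv(R)
        sgn, logdet_r = np.linalg.slogdet(R)
        if sgn <= 0:
            return -np.inf
    except np.linalg.LinAlgError:
        return -np.inf
    # W = [A, Xs]; D = blockdiag(tau_a^2 I, tau_s^2 R)
    # K = D^{-1} + W'W/s2 with W'W assembled from per-species sufficient stats
    K = np.zeros((2 * S, 2 * S))
    K[:S, :S] = np.diag(1.0 / tau_a ** 2 + st["n"] / s2)
    K[:S, S:] = np.diag(st["Sx"] / s2)
    K[S:, :S] = np.diag(st["Sx"] / s2)
    K[S:, S:] = R_inv / tau_s ** 2 + np.diag(st["Sxx"] / s2)
    Wr = np.concatenate([st["Sy"] - mu_a * st["n"] - sbar * st["Sx"],
                         st["Sxy"] - mu_a * st["Sx"] - sbar * st["Sxx"]])
    rr = np.sum(st["Syy"] - 2 * mu_a * st["Sy"] - 2 * sbar * st["Sxy"]
                + mu_a ** 2 * st["n"] + 2 * mu_a * sbar * st["Sx"]
                + sbar ** 2 * st["Sxx"])
    try:
        L = np.linalg.cholesky(K)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet_k = 2.0 * np.sum(np.log(np.diag(L)))
    sol = np.linalg.solve(L, Wr)
    quad = rr / s2 - (sol @ sol) / s2 ** 2
    N = st["n"].sum()
    logdet_sigma = (N * np.log(s2) + 2 * S * np.log(tau_a)
                    + 2 * S * np.log(tau_s) + logdet_r + logdet_k
                    # det(D) contributes tau_a^{2S} * tau_s^{2S} det(R):
                    )
    ll = -0.5 * (N * np.log(2 * np.pi) + logdet_sigma + quad)
    # uniform prior on lambda via logistic transform Jacobian
    ll += np.log(lam) + np.log1p(-lam)
    return float(ll) if np.isfinite(ll) else -np.inf


def fit_slope_model(trajs, traits, mcmc: MCMCConfig | None = None,
                    seed: int = 0) -> SlopeResults:
    """Functional wrapper around :class:`HierarchicalSlopeModel`."""
    return HierarchicalSlopeModel(trajs, traits).fit(config=mcmc, seed=seed)


def phylo_vcv(tree, species_ids: list[str]) -> np.ndarray:
    """Brownian-motion correlation matrix (shared branch length / max depth).

    ``tree`` is a dendropy Tree (or a path / newick string) whose tip labels
    contain the species ids (spaces and underscores interchangeable).
    """
    import dendropy

    if not isinstance(tree, dendropy.Tree):
        tree = dendropy.Tree.get(data=str(tree), schema="newick")
    tree = tree.clone(depth=1)
    norm = {}
    for leaf in tree.leaf_node_iter():
        label = (leaf.taxon.label if leaf.taxon else str(leaf)).replace(" ", "_")
        norm[label] = leaf
    missing = [s for s in species_ids if s not in norm]
    if missing:
        raise KeyError(f"species absent from tree: {missing}")
    pdm = tree.phylogenetic_distance_matrix()
    depths = {}
    for label, leaf in norm.items():
        d = 0.0
        nd = leaf
        while nd.parent_node is not None:
            d += nd.edge.length or 0.0
            nd = nd.parent_node
        depths[label] = d
    S = len(species_ids)
    maxdepth = max(depths[s] for s in species_ids)
    if maxdepth <= 0:
        raise ValueError("tree has zero total depth (no branch lengths)")
    C = np.zeros((S, S))
    for i, si in enumerate(species_ids):
        for j, sj in enumerate(species_ids):
            if i == j:
                C[i, j] = depths[si] / maxdepth
            else:
                dist = pdm.patristic_distance(norm[si].taxon, norm[sj].taxon)
                shared = 0.5 * (depths[si] + depths[sj] - dist)
                C[i, j] = max(shared, 0.0) / maxdepth
    # correlation form with unit diagonal keeps tau_s interpretable
    d = np.sqrt(np.clip(np.diag(C), 1e-12, None))
    return C / np.outer(d, d)


def fit_phylo_slope_model(trajs, traits, tree, mcmc: MCMCConfig | None = None,
                          seed: int = 0, lam_fixed: float | None = None
                          ) -> SlopeResults:
    """Hierarchical slope model with phylogenetically correlated residuals.

    Species missing from the tree are excluded with a warning.  With
    ``lam_fixed=0`` the model reduces exactly to the independent-residual
    fit (used as a nested-model identity check).
    """
    st_probe = _suffstats(trajs, traits)
    try:
        C = phylo_vcv(tree, st_probe["ids"])
        trajs_use, traits_use = trajs, traits
    except KeyError as err:
        import re
        missing = set(re.findall(r"'([^']+)'", str(err)))
        warnings.warn(f"excluding species absent from tree: {sorted(missing)}")
        trajs_use = [t for t in trajs if t.species_id not in missing]
        traits_use = [t for t in traits if t.species_id not in missing]
        st_probe = _suffstats(trajs_use, traits_use)
        C = phylo_vcv(tree, st_probe["ids"])
    if lam_fixed is not None:
        if lam_fixed == 0.0:
            return HierarchicalSlopeModel(trajs_use, traits_use).fit(
                config=mcmc, seed=seed)
        C = lam_fixed * C + (1 - lam_fixed) * np.eye(len(C))
    model = HierarchicalSlopeModel(trajs_use, traits_use, phylo_corr=C)
    res = model.fit(config=mcmc, seed=seed)
    return res


# ---------------------------------------------------------------------------
# severity regression

@dataclass
class SeverityModelResults:
    coef_names: list[str]
    coef_draws: np.ndarray     # (draws, p)
    importance: pd.DataFrame   # ranked |standardised effect|
    r_squared: float

    def coef_hpdi(self, name: str, prob: float = 0.95) -> tuple[float, float]:
        j = self.coef_names.index(name)
        return hpdi(self.coef_draws[:, j], prob)

    def summary(self) -> str:
        lines = ["Severity regression (logit severity ~ standardised predictors)",
                 "=" * 62]
        for j, nm in enumerate(self.coef_names):
            lo, hi = hpdi(self.coef_draws[:, j], 0.95)
            lines.append(f"{nm:<12} {np.median(self.coef_draws[:, j]):+.4f}"
                         f"  95% HPDI [{lo:+.4f}, {hi:+.4f}]")
        lines.append(f"R^2 {self.r_squared:.3f}")
        lines.append("importance ranking: "
                     + " > ".join(self.importance["predictor"]))
        return "\n".join(lines)


class SeverityModel:
    """Bayesian regression of logit decline severity on mass and timing.

    Predictors: standardised log10 mass and the (standardised) years BP of
    the minimum- and maximum-Ne windows.  Severities exactly 0 or 1 are
    winsorised to (eps, 1-eps) with eps = 1e-6 before the logit.
    """

    EPS = 1e-6

    def __init__(self, severities: list[SeverityRecord], traits: list[SpeciesTraits]):
        if len(severities) < 3:
            raise ValueError("need at least 3 species")
        by_id = {t.species_id: t for t in traits}
        sev, logm, tmin, tmax = [], [], [], []
        for rec in severities:
            if rec.species_id not in by_id:
                continue
            s = min(max(rec.severity, self.EPS), 1 - self.EPS)
            if s != rec.severity:
                warnings.warn(f"{rec.species_id}: severity winsorised to ({self.EPS},"
                              f" {1 - self.EPS})")
            sev.append(s)
            logm.append(np.log10(by_id[rec.species_id].mass_kg))
            tmin.append(rec.t_min_yr)
            tmax.append(rec.t_max_yr)
        self.y = np.log(np.array(sev) / (1 - np.array(sev)))

        def zs(v):
            v = np.asarray(v, float)
            s = v.std()
            return (v - v.mean()) / (s if s > 0 else 1.0)

        self.X = np.column_stack([np.ones(len(sev)), zs(logm), zs(tmin), zs(tmax)])
        self.names = ["intercept", "log10_mass", "t_min_yr", "t_max_yr"]

    def fit(self, n_draws: int = 2000, seed: int = 0) -> SeverityModelResults:
        m = ConjugateLinearModel(self.X, self.y, v0=100.0)
        beta, s2 = m.sample(n_draws, seed=seed)
        eff = np.abs(beta[:, 1:]).mean(axis=0)
        order = np.argsort(-eff)
        imp = pd.DataFrame({"predictor": [self.names[1 + i] for i in order],
                            "abs_std_effect": eff[order]})
        yhat = self.X @ m.bn
        ss_res = float(np.sum((self.y - yhat) ** 2))
        ss_tot = float(np.sum((self.y - self.y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return SeverityModelResults(self.names, beta, imp, r2)


def fit_severity_model(severities, traits, n_draws: int = 2000,
                       seed: int = 0) -> SeverityModelResults:
    return SeverityModel(severities, traits).fit(n_draws=n_draws, seed=seed)


# ---------------------------------------------------------------------------
# subsetting and correlations

def genus_subset(traits: list[SpeciesTraits],
                 trajs: list[NeTrajectory] | None = None) -> list[SpeciesTraits]:
    """One representative species per genus.

    The representative is the species with the largest trajectory window
    count (when trajectories are supplied), ties broken alphabetically;
    without trajectories the choice is alphabetical.
    """
    counts = {}
    if trajs is not None:
        counts = {tr.species_id: len(tr.ne) for tr in trajs}
    best: dict[str, SpeciesTraits] = {}
    for t in traits:
        g = t.genus  # raises with the offending id if unparseable
        cur = best.get(g)
        if cur is None:
            best[g] = t
            continue
        key_new = (-counts.get(t.species_id, 0), t.species_id)
        key_cur = (-counts.get(cur.species_id, 0), cur.species_id)
        if key_new < key_cur:
            best[g] = t
    return [best[g] for g in sorted(best)]


def spearman_ne_time(trajs: list[NeTrajectory]) -> tuple[float, float]:
    """Spearman correlation of pooled (time BP, Ne) window points.

    A positive rho means larger populations deeper in the past, i.e. a
    decreasing trend toward the present.
    """
    t = np.concatenate([tr.midpoints for tr in trajs])
    ne = np.concatenate([tr.ne for tr in trajs])
    if len(t) < 3:
        raise ValueError("need at least 3 pooled points")
    rho, p = sps.spearmanr(t, ne)
    return float(rho), float(p)
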