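"""Two-segment (breakpoint) regression of log10 Ne on log10 time.

The decline marker used throughout the package is the time at which a
continuous two-segment linear fit of log10 Ne against log10 years-BP changes
slope.  Slopes are reported per decade of log10 time moving toward the
present, so a negative post-breakpoint slope means an accelerating decline
in recent time.

Estimation profiles the residual sum of squares over breakpoint candidates
(midpoints between sorted unique abscissae) with an ordinary least-squares
fit at each candidate, followed by a bounded continuous refinement inside
the best candidate's bracket.  This is deterministic and globally optimal on
the candidate set; confidence intervals come from a case-resampling
bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .trajectories import NeTrajectory, SpeciesTraits

__all__ = [
    "PiecewiseRegression",
    "PiecewiseResults",
    "fit_piecewise",
    "breakpoint_ci",
    "grouped_fits",
    "segment_change",
]


def _design(u: np.ndarray, c: float) -> np.ndarray:
    # continuous two-segment basis with kink at c (u = -log10 t, ascending
    # toward the present): intercept = fitted value at the breakpoint
    return np.column_stack([
        np.ones_like(u),
        np.minimum(u, c) - c,       # pre-breakpoint slope (older side)
        np.maximum(u - c, 0.0),     # post-breakpoint slope (recent side)
    ])


def _rss_at(u: np.ndarray, y: np.ndarray, c: float) -> float:
    X = _design(u, c)
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


@dataclass
class PiecewiseResults:
    """Fitted two-segment regression; returned by :meth:`PiecewiseRegression.fit`."""

    breakpoint_log10t: float
    breakpoint_yr: float
    slope_pre: float
    slope_post: float
    intercept: float            # fitted log10 Ne at the breakpoint
    slope_pre_se: float
    slope_post_se: float
    slope_pre_p: float
    slope_post_p: float
    rss: float
    n_points: int
    no_breakpoint_support: bool
    breakpoint_ci_yr: tuple[float, float] | None = None
    _u: np.ndarray | None = field(default=None, repr=False)
    _y: np.ndarray | None = field(default=None, repr=False)

    def predict_log10_ne(self, t_yr) -> np.ndarray:
        """Fitted log10 Ne at years BP ``t_yr`` (within the fitted support)."""
        t_yr = np.atleast_1d(np.asarray(t_yr, dtype=float))
        if np.any(t_yr <= 0):
            raise ValueError("t_yr must be positive")
        u = -np.log10(t_yr)
        if self._u is not None:
            lo, hi = self._u.min(), self._u.max()
            if np.any(u < lo - 1e-9) or np.any(u > hi + 1e-9):
                raise ValueError("evaluation outside fitted support")
        c = -self.breakpoint_log10t
        du = u - c
        return self.intercept + np.where(du <= 0, self.slope_pre * du,
                                         self.slope_post * du)

    def summary(self) -> str:
        lines = [
            "Two-segment log-log regression of Ne on time",
            "=" * 46,
            f"n points            {self.n_points}",
            f"breakpoint          {self.breakpoint_yr:,.0f} yr BP"
            + (f"   95% CI [{self.breakpoint_ci_yr[0]:,.0f}, {self.breakpoint_ci_yr[1]:,.0f}]"
               if self.breakpoint_ci_yr else ""),
            f"slope (pre, older)  {self.slope_pre:+.4f}  SE {self.slope_pre_se:.4f}"
            f"  p={self.slope_pre_p:.3g}",
            f"slope (post)        {self.slope_post:+.4f}  SE {self.slope_post_se:.4f}"
            f"  p={self.slope_post_p:.3g}",
            f"RSS                 {self.rss:.6g}",
        ]
        if self.no_breakpoint_support:
            lines.append("note: no breakpoint support (single line fits as well)")
        return "\n".join(lines)


class PiecewiseRegression:
    """Model object for the two-segment fit of pooled (log10 t, log10 Ne) points.

    Parameters
    ----------
    log10_t, log10_ne : arrays
        Pooled window points; time in log10 years BP.
    search : (min_yr, max_yr), optional
        Restrict breakpoint candidates to this calendar range.
    """

    def __init__(self, log10_t, log10_ne, search: tuple[float, float] | None = None):
        x = np.asarray(log10_t, dtype=float)
        y = np.asarray(log10_ne, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("log10_t and log10_ne must be equal-length 1-D arrays")
        if len(x) < 6:
            raise ValueError("need at least 6 points for a two-segment fit")
        if np.ptp(x) == 0:
            raise ValueError("degenerate input: all time values identical")
        self.u = -x          # ascending toward the present
        self.y = y
        self.search = search

    def _candidates(self) -> np.ndarray:
        uu = np.unique(self.u)
        mids = 0.5 * (uu[:-1] + uu[1:])
        if self.search is not None:
            min_yr, max_yr = self.search
            lo_u, hi_u = -np.log10(max_yr), -np.log10(min_yr)
            mids = mids[(mids >= lo_u) & (mids <= hi_u)]
        # keep the kink strictly inside the data range
        mids = mids[(mids > self.u.min()) & (mids < self.u.max())]
        if len(mids) == 0:
            raise ValueError("search range excludes all breakpoint candidates")
        return mids

    def fit(self) -> PiecewiseResults:
        u, y = self.u, self.y
        cands = self._candidates()
        rss = np.array([_rss_at(u, y, c) for c in cands])
        i = int(np.argmin(rss))
        # continuous refinement within the bracketing interval
        lo = cands[i - 1] if i > 0 else u.min()
        hi = cands[i + 1] if i < len(cands) - 1 else u.max()
        res = optimize.minimize_scalar(
            lambda c: _rss_at(u, y, c), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10},
        )
        c_hat = float(res.x) if res.fun <= rss[i] else float(cands[i])
        X = _design(u, c_hat)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        rss_hat = float(r @ r)
        n, p = len(y), 3
        dof = max(n - p - 1, 1)  # breakpoint counts as a parameter
        s2 = rss_hat / dof
        XtX_inv = np.linalg.pinv(X.T @ X)
        se = np.sqrt(np.clip(s2 * np.diag(XtX_inv), 0.0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstats = np.where(se > 0, beta / se, np.inf)
        pvals = 2.0 * stats.t.sf(np.abs(tstats), dof)
        # single-line comparison for breakpoint support
        X1 = np.column_stack([np.ones_like(u), u])
        b1, *_ = np.linalg.lstsq(X1, y, rcond=None)
        rss1 = float(np.sum((y - X1 @ b1) ** 2))
        no_support = (rss1 - rss_hat) <= 1e-10 * max(rss1, 1e-30) or \
            abs(beta[1] - beta[2]) < 1e-8
        return PiecewiseResults(
            breakpoint_log10t=-c_hat,
            breakpoint_yr=10.0 ** (-c_hat),
            slope_pre=float(beta[1]),
            slope_post=float(beta[2]),
            intercept=float(beta[0]),
            slope_pre_se=float(se[1]), slope_post_se=float(se[2]),
            slope_pre_p=float(pvals[1]), slope_post_p=float(pvals[2]),
            rss=rss_hat, n_points=n, no_breakpoint_support=bool(no_support),
            _u=u.copy(), _y=y.copy(),
        )


def fit_piecewise(points, search: tuple[float, float] | None = None) -> PiecewiseResults:
    """Functional wrapper: ``points`` is a sequence of (log10_t, log10_ne)."""
    pts = np.asarray(points, dtype=float)
    return PiecewiseRegression(pts[:, 0], pts[:, 1], search=search).fit()


def breakpoint_ci(points, fit: PiecewiseResults | None = None, n_boot: int = 1000,
                  seed: int = 0, prob: float = 0.95,
                  search: tuple[float, float] | None = None) -> tuple[float, float]:
    """Percentile bootstrap interval (years BP) for the breakpoint.

    Case-resamples the pooled points; draws with fewer than 6 distinct usable
    points are rejected and redrawn.
    """
    if n_boot < 200:
        raise ValueError("need n_boot >= 200 for a stable percentile interval")
    pts = np.asarray(points, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(pts)
    bps = np.empty(n_boot)
    for b in range(n_boot):
        for _attempt in range(100):
            idx = rng.integers(0, n, size=n)
            sub = pts[idx]
            if len(np.unique(sub[:, 0])) >= 3 and len(sub) >= 6:
                try:
                    bps[b] = fit_piecewise(sub, search=search).breakpoint_yr
                    break
                except ValueError:
                    continue
        else:
            raise RuntimeError("could not draw a valid bootstrap sample")
    alpha = 1.0 - prob
    lo, hi = np.quantile(bps, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def pooled_points(trajs, log10: bool = True) -> np.ndarray:
    """Stack all window midpoints of the given trajectories as (log10 t, log10 Ne)."""
    xs, ys = [], []
    for tr in trajs:
        mid = tr.midpoints
        keep = mid > 0
        xs.append(np.log10(mid[keep]))
        ys.append(np.log10(tr.ne[keep]))
    return np.column_stack([np.concatenate(xs), np.concatenate(ys)])


def grouped_fits(trajs: list[NeTrajectory], traits: list[SpeciesTraits],
                 grouping: str = "realm",
                 search: tuple[float, float] | None = None,
                 n_boot: int = 0, seed: int = 0) -> dict[str, PiecewiseResults]:
    """Per-realm (or single global) pooled two-segment fits.

    Every species contributes its window midpoints as raw points (no
    per-species weighting).  Groups with fewer than 2 species are skipped
    with a warning.  When ``n_boot`` > 0, a bootstrap breakpoint CI is
    attached to each fit.
    """
    import warnings as _w

    by_id = {t.species_id: t for t in traits}
    groups: dict[str, list[NeTrajectory]] = {}
    for tr in trajs:
        if grouping == "global":
            key = "global"
        else:
            if tr.species_id not in by_id:
                continue
            key = getattr(by_id[tr.species_id], grouping)
        groups.setdefault(key, []).append(tr)
    out: dict[str, PiecewiseResults] = {}
    for key, members in sorted(groups.items()):
        if len(members) < 2:
            _w.warn(f"group {key!r} has <2 species; skipped")
            continue
        pts = pooled_points(members)
        res = fit_piecewise(pts, search=search)
        if n_boot:
            res.breakpoint_ci_yr = breakpoint_ci(pts, res, n_boot=n_boot,
                                                 seed=seed, search=search)
        out[key] = res
    return out


def segment_change(fit: PiecewiseResults, from_yr: float, to_yr: float) -> float:
    """Percent change in fitted Ne between two times (positive = decrease).

    ``100 * (1 - 10**(fit(to) - fit(from)))`` with ``from_yr > to_yr`` on the
    years-BP axis, evaluated on the fitted two-segment function.
    """
    if not (from_yr > to_yr >= 0):
        raise ValueError("need from_yr > to_yr >= 0 on the BP axis")
    f_from = fit.predict_log10_ne(from_yr)[0]
    if to_yr <= 0:
        # evaluate at the most recent fitted support point (no extrapolation)
        to_yr = 10.0 ** (-fit._u.max()) if fit._u is not None else 1.0
    f_to = fit.predict_log10_ne(to_yr)[0]
    return float(100.0 * (1.0 - 10.0 ** (f_to - f_from)))
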