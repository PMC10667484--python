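"""Ecosystem-scale accounting of the megafauna decline.

Effective sizes underestimate the number of individuals, so census sizes
(Nc) are reconstructed from each species' Holocene mean Ne and its current
IUCN census (ne_to_nc = Holocene Ne / IUCN Nc); past windows are then
scaled by that per-species ratio.  Totals convert to biomass assuming body
mass is 15% carbon (Gt C) and to energy turnover from per-individual daily
metabolic rates (pJ/day).  Species missing from the genomic dataset and
extinct species enter through an allometric census-mass regression with a
Duan smearing correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .trajectories import NeTrajectory, SpeciesTraits, window_mean

__all__ = [
    "HOLOCENE", "BASELINE", "CARBON_FRACTION",
    "NcRatio", "EcosystemTotals", "ne_to_nc", "census_through_time",
    "totals", "baseline_contrast", "CensusMassRegression",
    "census_mass_regression", "calibrate_ratio", "risk_summary",
]

log = logging.getLogger(__name__)

HOLOCENE = (0.0, 11_700.0)
BASELINE = (100_000.0, 742_000.0)
#: fraction of adult body mass that is carbon
CARBON_FRACTION = 0.15
KG_PER_GT = 1.0e12
KJ_PER_PJ = 1.0e12


@dataclass(frozen=True)
class NcRatio:
    species_id: str
    holocene_ne: float
    baseline_ne: float
    iucn_nc: float | None
    ne_to_nc: float | None        # Holocene Ne / current census
    baseline_ratio: float | None  # baseline Ne / current census

    @property
    def defined(self) -> bool:
        return self.ne_to_nc is not None


@dataclass(frozen=True)
class EcosystemTotals:
    window: str
    total_census: float
    total_biomass_gtc: float
    total_energy_pj_day: float
    n_species: int


def ne_to_nc(traj: NeTrajectory, traits: SpeciesTraits,
             holocene: tuple[float, float] = HOLOCENE,
             baseline: tuple[float, float] = BASELINE) -> NcRatio:
    """Time-weighted Holocene and baseline mean Ne and their census ratios.

    A missing IUCN census yields a record with undefined (None) ratios, not
    zeros.
    """
    lo, hi = traj.support
    h = (max(holocene[0], lo), min(holocene[1], hi))
    b = (max(baseline[0], lo), min(baseline[1], hi))
    if h[0] >= h[1] or b[0] >= b[1]:
        raise ValueError(f"{traj.species_id}: trajectory does not cover the "
                         "Holocene and part of the baseline period")
    h_ne = window_mean(traj, h)
    b_ne = window_mean(traj, b)
    if traits.iucn_census is None or not np.isfinite(traits.iucn_census):
        return NcRatio(traj.species_id, h_ne, b_ne, None, None, None)
    return NcRatio(traj.species_id, h_ne, b_ne, float(traits.iucn_census),
                   h_ne / traits.iucn_census, b_ne / traits.iucn_census)


def census_through_time(traj: NeTrajectory, ratio: NcRatio,
                        windows: list[tuple[float, float]]) -> dict[str, float]:
    """Per-window census: window-mean Ne divided by the species' Ne/Nc ratio.

    The special window label ``"current"`` maps to the IUCN census directly.
    """
    if not ratio.defined:
        raise ValueError(f"{ratio.species_id}: undefined Ne/Nc ratio")
    out = {}
    for w in windows:
        if w == "current":
            out["current"] = ratio.iucn_nc
            continue
        label = f"{int(w[0]/1000)}-{int(w[1]/1000)}kya"
        out[label] = window_mean(traj, w) / ratio.ne_to_nc
    return out


def totals(census: dict[str, float], traits_list: list[SpeciesTraits],
           window: str) -> EcosystemTotals:
    """Sum census, biomass (Gt C) and energy turnover (pJ/day) over species.

    ``census`` maps species_id -> individuals for one window.  Species
    without a metabolic rate are excluded from the energy total only.
    """
    by_id = {t.species_id: t for t in traits_list}
    tot_c = tot_b = tot_e = 0.0
    n = 0
    for sid, c in census.items():
        t = by_id[sid]
        tot_c += c
        tot_b += c * t.mass_kg * CARBON_FRACTION / KG_PER_GT
        if t.met_rate_kj_day is not None:
            tot_e += c * t.met_rate_kj_day / KJ_PER_PJ
        else:
            log.info("%s: no metabolic rate; excluded from energy total", sid)
        n += 1
    return EcosystemTotals(window, tot_c, tot_b, tot_e, n)


def baseline_contrast(totals_by_window: dict[str, EcosystemTotals],
                      baseline: EcosystemTotals) -> pd.DataFrame:
    """Percent change of each parameter vs the baseline-period totals."""
    rows = []
    for label, t in totals_by_window.items():
        row = {"window": label}
        for attr in ("total_census", "total_biomass_gtc", "total_energy_pj_day"):
            base = getattr(baseline, attr)
            if base == 0:
                raise ZeroDivisionError(f"baseline {attr} is zero")
            row[attr.replace("total_", "pct_change_")] = \
                100.0 * (getattr(t, attr) - base) / base
        rows.append(row)
    return pd.DataFrame(rows)


class CensusMassRegression:
    """OLS of log10 census on log10 mass with Duan smearing retransformation.

    Used to impute census sizes for extinct species and extant species
    missing from the genomic dataset.
    """

    def __init__(self, mass_kg: np.ndarray, census: np.ndarray):
        mass_kg = np.asarray(mass_kg, float)
        census = np.asarray(census, float)
        if len(mass_kg) < 10:
            raise ValueError("need at least 10 species with mass and census")
        if np.any(mass_kg <= 0) or np.any(census <= 0):
            raise ValueError("mass and census must be positive")
        X = sm.add_constant(np.log10(mass_kg))
        self.fit = sm.OLS(np.log10(census), X).fit()
        resid = self.fit.resid
        self.smearing = float(np.mean(10.0 ** resid))

    @property
    def params(self) -> np.ndarray:
        return np.asarray(self.fit.params)

    def predict(self, mass_kg) -> np.ndarray:
        mass_kg = np.atleast_1d(np.asarray(mass_kg, float))
        if np.any(mass_kg <= 0):
            raise ValueError("mass must be positive")
        log_pred = self.params[0] + self.params[1] * np.log10(mass_kg)
        return self.smearing * 10.0 ** log_pred


def census_mass_regression(traits_list: list[SpeciesTraits]) -> CensusMassRegression:
    rows = [(t.mass_kg, t.iucn_census) for t in traits_list
            if t.iucn_census is not None and np.isfinite(t.iucn_census)]
    m, c = zip(*rows) if rows else ((), ())
    return CensusMassRegression(np.array(m), np.array(c))


def calibrate_ratio(reference: list[tuple[str, float]],
                    implied_census: dict[str, float]) -> float:
    """Historical-calibration factor for census reconstructions.

    ``reference`` lists (species_id, historical census); ``implied_census``
    maps species to the model-implied pre-industrial census.  The factor is
    the geometric mean of historical/implied over the references and
    multiplies all census reconstructions.
    """
    if not reference:
        raise ValueError("empty reference set")
    ratios = []
    for sid, hist in reference:
        if sid not in implied_census:
            raise KeyError(f"no implied census for reference species {sid!r}")
        ratios.append(hist / implied_census[sid])
    return float(np.exp(np.mean(np.log(ratios))))


def risk_summary(ratios: list[NcRatio], traits_list: list[SpeciesTraits]) -> dict:
    """Extinction-risk view of the Ne/Nc ratios.

    Median baseline Ne / current census, the share of species whose
    baseline effective size exceeds their current census (strict > 1), and
    the Spearman correlation of the Holocene Ne/Nc ratio with log10 mass.
    """
    by_id = {t.species_id: t for t in traits_list}
    rows = [(r, by_id[r.species_id]) for r in ratios
            if r.defined and r.species_id in by_id]
    if len(rows) < 3:
        raise ValueError("need at least 3 species with defined ratios")
    base = np.array([r.baseline_ratio for r, _ in rows])
    nenc = np.array([r.ne_to_nc for r, _ in rows])
    logm = np.log10([t.mass_kg for _, t in rows])
    rho, p = sps.spearmanr(nenc, logm)
    return {
        "n_species": len(rows),
        "median_baseline_ratio": float(np.median(base)),
        "share_baseline_ratio_gt1": float(np.mean(base > 1.0)),
        "spearman_ratio_mass": float(rho),
        "spearman_p": float(p),
    }
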