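"""Synthetic study-input generator with known ground truth.

Emulates the structure of the real inputs end to end: PSMC-style log-spaced
time windows, log-linear population trajectories with a late-Quaternary
breakpoint, mass-dependent decline slopes, climate-coupled fluctuations,
post-arrival logistic/exponential/linear suppression, and observation noise
on log10 Ne (PSMC uncertainty is approximately scale-free, so noise is
multiplicative on Ne).  :func:`simulate_dataset` writes a complete fixture
bundle — species TSV, climate CSV, arrival TSV, trajectory CSV, per-species
PSMC-format files (via the inverse scaling transform) and a ground-truth
JSON — so every downstream stage is testable without downloads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import trends
from .psmc import trajectory_to_run, write_psmc
from .trajectories import (ClimateSeries, NeTrajectory, SpeciesTraits,
                           window_mean, write_climate, write_traits,
                           write_trajectories)

__all__ = [
    "ScenarioParams", "ArrivalWindow", "DEFAULT_ARRIVALS", "default_grid",
    "simulate_climate", "simulate_species", "simulate_trajectory",
    "simulate_dataset", "read_arrivals", "write_arrivals",
]

SCENARIOS = ("stable", "piecewise_decline", "climate_forced",
             "human_logistic", "human_exponential", "human_linear")

#: smallest megafauna body mass admitted by the study design (kg)
MASS_FLOOR_KG = 22.0


@dataclass(frozen=True)
class ArrivalWindow:
    """Bounds (years BP) on *H. sapiens* arrival in a biogeographic realm."""

    realm: str
    earliest_yr: float
    latest_yr: float

    def __post_init__(self):
        if not (self.earliest_yr > self.latest_yr >= 0):
            raise ValueError("need earliest_yr > latest_yr >= 0 (BP axis)")

    def draw(self, rng: np.random.Generator) -> float:
        return float(rng.uniform(self.latest_yr, self.earliest_yr))


#: arrival (or, for the Afrotropic, establishment) windows used by default
DEFAULT_ARRIVALS = {
    "Afrotropic": ArrivalWindow("Afrotropic", 200_000.0, 120_000.0),
    "Palearctic": ArrivalWindow("Palearctic", 55_000.0, 40_000.0),
    "Australasia": ArrivalWindow("Australasia", 60_000.0, 45_000.0),
    "Nearctic": ArrivalWindow("Nearctic", 23_000.0, 14_000.0),
    "Neotropic": ArrivalWindow("Neotropic", 18_000.0, 12_000.0),
}

_REALMS = tuple(DEFAULT_ARRIVALS)


@dataclass(frozen=True)
class ScenarioParams:
    """Generating parameters for one trajectory scenario.

    Slopes are d log10 Ne per decade of log10 time toward the present
    (negative = decline); the human-trend drop ``delta`` is in log10 units
    (delta = 1 is a 90% suppression at saturation).
    """

    scenario: str = "piecewise_decline"
    base_log10_ne: float = 4.3
    pre_slope: float = -0.01
    post_slope: float = -0.45
    breakpoint_yr: float = 50_000.0
    temp_coef: float = 0.0
    precip_coef: float = 0.0
    temp_lag_coef: float = 0.0
    precip_lag_coef: float = 0.0
    human_rate: float = 1.0
    human_delta: float = 1.15
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.human_delta < 0:
            raise ValueError("human_delta must be >= 0")


def default_grid(n_intervals: int = 63, t_min: float = 1_000.0,
                 t_max: float = 3_000_000.0) -> np.ndarray:
    """PSMC-like boundaries: 0, then log-spaced from ``t_min`` to ``t_max``."""
    return np.concatenate([[0.0], np.geomspace(t_min, t_max, n_intervals)])


def simulate_climate(duration_yr: float = 742_000.0, window_yr: float = 1_000.0,
                     period_yr: float = 100_000.0, temp_amp: float = 4.0,
                     precip_amp: float = 150.0, temp_mean: float = -2.0,
                     precip_mean: float = 900.0, noise_sd: float = 0.15,
                     seed: int = 0) -> ClimateSeries:
    """Glacial-cycle-like temperature and precipitation on fixed windows.

    A sawtooth (slow cooling, rapid deglacial warming) plus a shorter
    sinusoidal component, with small Gaussian window noise; precipitation
    co-varies with temperature, as in glacial records.
    """
    if temp_amp <= 0 or precip_amp <= 0:
        raise ValueError("amplitudes must be positive")
    if duration_yr < 2 * period_yr:
        raise ValueError("duration must cover at least two glacial cycles")
    n = int(round(duration_yr / window_yr))
    if abs(n * window_yr - duration_yr) > 1e-6:
        raise ValueError("window_yr must divide duration_yr")
    rng = np.random.default_rng(seed)
    b = np.arange(n + 1, dtype=float) * window_yr
    mid = 0.5 * (b[:-1] + b[1:])
    phase = (mid % period_yr) / period_yr
    # sawtooth: rapid warming at cycle start (recent side), slow cooling back
    saw = 1.0 - 2.0 * phase
    osc = 0.35 * np.sin(2 * np.pi * mid / (period_yr / 2.43))
    signal = saw + osc
    temp = temp_mean + temp_amp * signal + noise_sd * temp_amp * rng.standard_normal(n)
    precip = (precip_mean + precip_amp * signal
              + noise_sd * precip_amp * rng.standard_normal(n))
    return ClimateSeries(b, temp, np.clip(precip, 1.0, None))


def simulate_species(n: int, mass_log_mean: float = 2.08, mass_log_sd: float = 0.6,
                     mass_slope_effect: float = -0.1, base_slope: float = -0.45,
                     seed: int = 0) -> tuple[list[SpeciesTraits], pd.DataFrame]:
    """Draw species traits with mass-dependent true decline slopes.

    Masses are log-normal (median ~120 kg) with a 22 kg floor enforced by
    resampling.  The per-species true post-breakpoint slope is
    ``base_slope + mass_slope_effect * z(log10 mass)``.  Generation time,
    mutation rate, metabolic rate and census follow standard mammalian
    allometries with log-normal scatter.  Returns the traits and a
    ground-truth table (species_id, mass_kg, true_post_slope).
    """
    if n < 1:
        raise ValueError("need n >= 1 species")
    rng = np.random.default_rng(seed)
    masses = np.empty(n)
    filled = 0
    while filled < n:
        draw = 10.0 ** rng.normal(mass_log_mean, mass_log_sd, size=n - filled)
        ok = draw[draw >= MASS_FLOOR_KG]
        masses[filled:filled + len(ok)] = ok
        filled += len(ok)
    logm = np.log10(masses)
    z = (logm - logm.mean()) / (logm.std() if n > 1 and logm.std() > 0 else 1.0)
    slopes = base_slope + mass_slope_effect * z
    traits, rows = [], []
    for i in range(n):
        m = masses[i]
        gen = 10.0 * (m / 100.0) ** 0.20 * 10.0 ** rng.normal(0, 0.05)
        mu = 1.0e-8 * (gen / 10.0) ** 0.5 * 10.0 ** rng.normal(0, 0.05)
        met = 600.0 * m ** 0.75  # field metabolic rate, kJ/day
        census = 10.0 ** (6.2 - 0.5 * np.log10(m) + rng.normal(0, 0.3))
        sid = f"Genus{i:03d}_species{i:03d}"
        traits.append(SpeciesTraits(
            species_id=sid, mass_kg=float(m), gen_time_yr=float(gen),
            mu=float(mu), realm=_REALMS[i % len(_REALMS)], biome="terrestrial",
            iucn_census=float(census), met_rate_kj_day=float(met),
            status="extant_included",
        ))
        rows.append({"species_id": sid, "mass_kg": float(m),
                     "true_post_slope": float(slopes[i])})
    return traits, pd.DataFrame(rows)


def _signal_log10_ne(t_mid: np.ndarray, params: ScenarioParams,
                     climate: ClimateSeries | None,
                     boundaries: np.ndarray,
                     t_arr: float | None) -> np.ndarray:
    u = -np.log10(np.maximum(t_mid, 1.0))
    y = np.full_like(u, params.base_log10_ne)
    if params.scenario == "piecewise_decline":
        u_bp = -np.log10(params.breakpoint_yr)
        du = u - u_bp
        y = params.base_log10_ne + np.where(
            du <= 0, params.pre_slope * du, params.post_slope * du)
    climate_coefs = (params.temp_coef, params.precip_coef,
                     params.temp_lag_coef, params.precip_lag_coef)
    if params.scenario == "climate_forced" or any(c != 0 for c in climate_coefs):
        if climate is None:
            raise ValueError("climate-coupled scenario needs a ClimateSeries")
        lo, hi = climate.support
        tw = np.empty(len(t_mid)); pw = np.empty(len(t_mid))
        tl = np.empty(len(t_mid)); pl = np.empty(len(t_mid))
        for k in range(len(t_mid)):
            w = (max(boundaries[k], lo), min(boundaries[k + 1], hi))
            wl = (min(boundaries[k + 1], hi - 1.0), min(boundaries[k + 2], hi)) \
                if k + 2 < len(boundaries) else w
            if w[0] >= w[1]:
                w = (lo, min(hi, lo + 1.0))
            tw[k] = window_mean(climate, w, "temp")
            pw[k] = window_mean(climate, w, "precip")
            if wl[0] >= wl[1]:
                wl = w
            tl[k] = window_mean(climate, wl, "temp")
            pl[k] = window_mean(climate, wl, "precip")

        def zsc(v):
            s = v.std()
            if s <= 1e-9 * max(1.0, abs(v.mean())):
                return np.zeros_like(v)
            return (v - v.mean()) / s

        y = y + (params.temp_coef * zsc(tw) + params.precip_coef * zsc(pw)
                 + params.temp_lag_coef * zsc(tl) + params.precip_lag_coef * zsc(pl))
    if params.scenario.startswith("human_"):
        if t_arr is None:
            raise ValueError("human scenario needs an arrival window")
        trend = params.scenario.removeprefix("human_")
        y = y + trends.human_term(trend, t_mid, t_arr,
                                  params.human_rate, params.human_delta)
    return y


def simulate_trajectory(traits: SpeciesTraits, params: ScenarioParams,
                        grid: np.ndarray | None = None,
                        climate: ClimateSeries | None = None,
                        arrival: ArrivalWindow | None = None,
                        rng: np.random.Generator | None = None
                        ) -> tuple[NeTrajectory, dict]:
    """Generate one noisy trajectory under a scenario; returns (traj, truth).

    The deterministic scenario signal is evaluated at window midpoints,
    Gaussian noise of sd ``params.noise_sd`` is added on log10 Ne, and the
    result is exponentiated.  For human scenarios the arrival time is drawn
    uniformly from the realm's window (matching the fitting-side prior).
    """
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    t_arr = None
    if params.scenario.startswith("human_"):
        if arrival is None:
            arrival = DEFAULT_ARRIVALS.get(traits.realm)
        if arrival is None:
            raise ValueError(
                f"human scenario for realm {traits.realm!r} without arrival window")
        t_arr = arrival.draw(rng)
    t_mid = 0.5 * (grid[:-1] + grid[1:])
    y = _signal_log10_ne(t_mid, params, climate, grid, t_arr)
    y = y + params.noise_sd * rng.standard_normal(len(y))
    traj = NeTrajectory(traits.species_id, grid, 10.0 ** y)
    truth = {"species_id": traits.species_id, "scenario": params.scenario,
             "t_arr": t_arr, "params": asdict(params),
             "log10_ne_signal": ( _signal_log10_ne(t_mid, params, climate, grid, t_arr)).tolist()}
    return traj, truth


def read_arrivals(path) -> dict[str, ArrivalWindow]:
    df = pd.read_csv(path, sep="\t")
    return {str(r["realm"]): ArrivalWindow(str(r["realm"]), float(r["earliest_yr"]),
                                           float(r["latest_yr"]))
            for _, r in df.iterrows()}


def write_arrivals(arrivals: dict[str, ArrivalWindow], path) -> None:
    pd.DataFrame([{"realm": a.realm, "earliest_yr": a.earliest_yr,
                   "latest_yr": a.latest_yr} for a in arrivals.values()]
                 ).to_csv(path, sep="\t", index=False)


def simulate_dataset(config: dict, out_dir) -> dict:
    """Write a complete synthetic fixture bundle; returns the ground truth.

    ``config`` keys (all optional): ``n_species``, ``seed``, ``scenario``
    (or ``scenario_mix``: mapping scenario -> weight), ``noise_sd``,
    ``ne_to_nc``, plus overrides for any :class:`ScenarioParams` field.
    Outputs: species.tsv, climate.csv, arrivals.tsv, trajectories.csv,
    psmc/<species>.psmc (three -p runs each) and ground_truth.json.
    """
    n = int(config.get("n_species", 20))
    if n < 1:
        raise ValueError("config must request at least 1 species")
    seed = int(config.get("seed", 0))
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    (out / "psmc").mkdir(parents=True, exist_ok=True)

    climate = simulate_climate(seed=seed)
    traits, truth_species = simulate_species(
        n, mass_slope_effect=float(config.get("mass_slope_effect", -0.1)),
        base_slope=float(config.get("base_slope", -0.45)), seed=seed)
    mix = config.get("scenario_mix")
    if mix is None:
        mix = {str(config.get("scenario", "human_logistic")): 1.0}
    names = sorted(mix)
    w = np.array([mix[k] for k in names], float)
    w = w / w.sum()
    ne_to_nc = float(config.get("ne_to_nc", 0.5))

    trajs, truths = [], []
    param_over = {k: config[k] for k in (
        "base_log10_ne", "pre_slope", "breakpoint_yr", "temp_coef",
        "precip_coef", "temp_lag_coef", "precip_lag_coef", "human_rate",
        "human_delta", "noise_sd") if k in config}
    for i, tr in enumerate(traits):
        scen = names[int(rng.choice(len(names), p=w))]
        post = float(truth_species.loc[i, "true_post_slope"])
        params = ScenarioParams(scenario=scen, post_slope=post,
                                seed=seed + 1000 + i, **param_over)
        traj, truth = simulate_trajectory(tr, params, climate=climate, rng=rng)
        trajs.append(traj)
        truths.append(truth)
        # three -p runs per species; the middle one carries the most
        # recombination events and must be the one selected downstream
        runs = []
        for j, pat in enumerate(("4+25*2+4+6", "6*1+24*2+4+6", "10*1+15*2")):
            base_events = 50.0 + 100.0 * (1 if j == 1 else 0)
            run = trajectory_to_run(
                traj, tr.mu, tr.gen_time_yr, p_pattern=pat,
                n_recomb_events=tuple(base_events + k for k in range(len(traj.ne))))
            runs.append(run)
        write_psmc(runs, out / "psmc" / f"{tr.species_id}.psmc")

    # census sizes consistent with the generated trajectories and the true
    # Ne/Nc ratio so that ecosystem accounting has a recoverable ground truth
    holocene = (0.0, 11_700.0)
    baseline = (100_000.0, 742_000.0)
    traits_final = []
    per_species = []
    for tr, t in zip(trajs, traits):
        h_ne = window_mean(tr, holocene)
        b_ne = window_mean(tr, baseline)
        census = h_ne / ne_to_nc
        traits_final.append(SpeciesTraits(
            species_id=t.species_id, mass_kg=t.mass_kg, gen_time_yr=t.gen_time_yr,
            mu=t.mu, realm=t.realm, biome=t.biome, iucn_census=float(census),
            met_rate_kj_day=t.met_rate_kj_day, status=t.status))
        per_species.append({"species_id": t.species_id, "holocene_ne": h_ne,
                            "baseline_ne": b_ne, "iucn_census": float(census),
                            "true_ne_to_nc": ne_to_nc})
    baseline_census = sum(p["baseline_ne"] / ne_to_nc for p in per_species)
    current_census = sum(p["iucn_census"] for p in per_species)
    truth = {
        "seed": seed, "n_species": n, "scenario_mix": {k: float(v) for k, v in mix.items()},
        "ne_to_nc": ne_to_nc,
        "true_census_decline_pct": 100.0 * (1.0 - current_census / baseline_census),
        "species": per_species,
        "trajectories": truths,
        "true_slopes": truth_species.to_dict(orient="records"),
    }
    write_traits(traits_final, out / "species.tsv")
    write_climate(climate, out / "climate.csv")
    write_arrivals(DEFAULT_ARRIVALS, out / "arrivals.tsv")
    write_trajectories(trajs, out / "trajectories.csv")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return truth
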