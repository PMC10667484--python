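# megadecline

Post-PSMC analysis of megafauna population histories: when did wild
large-mammal populations start collapsing, what drove the collapse —
climate or *Homo sapiens* — and what did it cost ecosystems in
individuals, biomass and energy turnover?

The package is aimed at population geneticists and macroecologists who
have PSMC demographic reconstructions (one diploid genome per species) and
want to analyse many of them jointly. It consumes raw PSMC text output and
provides, as composable library modules with a thin `megadecline` CLI on
top:

- **Trajectory ingestion** — parsing PSMC output (RD/TR/RS/PA blocks),
  selecting among `-p` runs by recombination-event support, and scaling
  coalescent units to calendar years and diploid individuals via
  N₀ = θ₀ / (4 µ s) (s = 100-site bins), Nₑ(k) = N₀ λₖ,
  tₖ[yr] = 2 N₀ tₖ g. A log–log OLS of µ on generation time imputes
  missing mutation rates.
- **Breakpoint regression** — a continuous two-segment fit of log₁₀ Nₑ on
  log₁₀ t with profiled grid search + bounded refinement, bootstrap CIs,
  and pooled global/per-realm fits. Slopes are reported per decade of
  log₁₀ time toward the present (negative = decline).
- **Hierarchical slope model** — per-species decline slopes partially
  pooled around α + β·z(log₁₀ mass), with the species effects integrated
  out analytically and only the hyperparameters sampled by MCMC; a
  phylogenetic variant correlates slope residuals through a
  Brownian-motion covariance with an estimated λ weight.
- **The 32-model trajectory family** — 12 climate-only models
  ({linT, quadT} × {noP, linP, quadP} × ±lag), 4 human-only models
  (logistic / exponential / linear post-arrival suppression, or a
  probability-of-presence ramp), and 16 combined models; fitted per
  species over the last 742 kyr, compared by PSIS-LOO (arviz), with
  climate-only hold-out prediction of the last 100 kyr and paired
  observed-vs-predicted contrasts per 25-kyr window.
- **Ecosystem accounting** — Holocene-Nₑ/IUCN-census ratios, census
  reconstructions through time, totals in individuals, Gt C (mass × 15 %
  carbon) and pJ/day (summed field metabolic rates), contrasts against the
  100–742 kya baseline, an allometric census–mass regression (with Duan
  smearing) for missing and extinct species, and a historical-census
  calibration variant.
- **Synthetic data** — a first-class generator producing PSMC-format
  fixture files, species traits, glacial-cycle climate, arrival windows
  and ground-truth JSON, so the entire pipeline is testable with known
  answers and no downloads.

## Worked example

Simulate a 20-species cohort with a late-Quaternary breakpoint, ingest it,
and fit the global two-segment model:

```python
import numpy as np
from megadecline import (simulate_dataset, read_trajectories, read_traits,
                         grouped_fits, segment_change, decline_severity,
                         spearman_ne_time)

simulate_dataset({"n_species": 20, "seed": 7,
                  "scenario": "piecewise_decline"}, "out/")
trajs = read_trajectories("out/trajectories.csv")
traits = read_traits("out/species.tsv")

fit = grouped_fits(trajs, traits, grouping="global", n_boot=500, seed=7)["global"]
print(fit.summary())
```

```
Two-segment log-log regression of Ne on time
==============================================
n points            1260
breakpoint          52,049 yr BP   95% CI [46,545, 63,527]
slope (pre, older)  -0.0134  SE 0.0075  p=0.0742
slope (post)        -0.4387  SE 0.0073  p=0
RSS                 18.4505
```

The cohort was generated with a breakpoint at 50 kyr, a pre-breakpoint
slope of −0.01 and mass-dependent post-breakpoint slopes around −0.45; the
pooled fit recovers all three. Evaluating the fitted curve,

```python
segment_change(fit, 9e5, fit.breakpoint_yr)   #  3.74 % decline before
segment_change(fit, fit.breakpoint_yr, 0.0)   # 86.97 % decline after
spearman_ne_time(trajs)                       # rho = 0.81, p < 1e-200
np.median([decline_severity(t).severity for t in trajs])  # 0.93
```

i.e. almost the entire fitted reduction in effective population size falls
in the post-breakpoint period, effective sizes rank-correlate strongly
with time before present, and the median species loses ~93 % of its peak
population — the qualitative signature the pipeline is built to detect and
attribute.

The same objects drive the model comparison
(`TrajectoryModel(traj, spec, climate=..., arrival=...).fit()` →
`.loo()`, `rank_models`), hold-out prediction (`fit_predict_holdout`) and
accounting (`ne_to_nc`, `census_through_time`, `totals`,
`baseline_contrast`).

## Command line

```bash
megadecline simulate --seed 3 --n-species 20 --out run/data
megadecline ingest --psmc-dir run/data/psmc --traits run/data/species.tsv --out run/ingest
megadecline breakpoint --trajectories run/data/trajectories.csv \
    --traits run/data/species.tsv --group global --nboot 1000 --seed 3 --out run/bp.json
megadecline models ...   # 32-model comparison
megadecline consequences ...  # census/biomass/energy contrasts
```

Every stage writes a manifest with input hashes, settings and the seed.

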