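# Methods

This note documents the models implemented in `megadecline`, their
assumptions, the tunable parameters that matter, the synthetic-data
generator used throughout the test suite, and the numerical and design
choices made where more than one reasonable option existed.

## Time axis and conventions

All step functions (effective population size, climate) live on a
years-before-present axis with right-open windows `[b_k, b_{k+1})`; larger
values are older. Population sizes are analysed on the log₁₀ scale.
Rates of population-size change ("slopes") are reported as d log₁₀ Nₑ per
decade of log₁₀ time moving **toward the present**, so a declining species
has a negative slope. Internally regressions use u = −log₁₀ t, which makes
that orientation the natural coefficient sign.

## PSMC ingestion

A PSMC run is read from its final EM iteration block: θ₀ from the `TR`
line, atomic intervals `(t_k, λ_k)` from `RS` lines (a fourth numeric
column, when present, is read as the per-interval recombination-event
count), and the `-p` pattern from `PA`. Concatenated runs are split where
the round counter resets. Among a species' runs (typically three `-p`
settings) the default selection criterion maximises the **minimum**
per-interval recombination-event count — the interval worst supported by
recombination events is the binding constraint on trajectory quality — with
the run-total sum available as `criterion="total"`.

Scaling uses the standard PSMC transformation with a bin size of 100 sites
(the PSMC default; exposed as a parameter): N₀ = θ₀/(4µs), Nₑ = N₀λ,
t[yr] = 2N₀tg. RS lines carry interval start times only, so the terminal
(oldest) boundary closes the last interval by continuing the run's own
log-spaced grid one step; no Nₑ values are extrapolated. Missing mutation
rates are imputed by OLS of log₁₀ µ on log₁₀ generation time over a
calibration table of extant mammals, back-transformed at the query.

## Breakpoint regression

The decline marker is a continuous two-segment linear fit of log₁₀ Nₑ on
log₁₀ t. Estimation profiles the residual sum of squares over breakpoint
candidates placed at midpoints between sorted unique abscissae, solving an
OLS at each, then refines continuously inside the winning bracket with a
bounded scalar minimiser (tolerance 1e−10). This is deterministic,
globally optimal on the candidate set (asserted against a 1,000-point grid
oracle in the tests), and recovers noiseless two-segment inputs exactly.
An iteratively linearised estimator in the style of the segmented-
regression literature was deliberately not used: the profiled search is
verifiable by exhaustive oracle and cannot converge to a local optimum.

Uncertainty comes from a case-resampling bootstrap (percentile interval;
draws with fewer than six usable points are rejected and redrawn).
A fit is flagged `no_breakpoint_support` when a single line achieves the
same RSS (relative tolerance 1e−10) or the two slopes coincide. Pooled
fits stack all window midpoints of a group's species as raw points —
species with more windows therefore carry proportionally more weight; an
inverse-weighting variant was considered and left out because window
counts are nearly equal across species by construction of the PSMC grid.
Slope significance is a two-sided t-test from the segment OLS with the
breakpoint counted as one extra parameter.

At the generator's study conditions (observation noise 0.1–0.15 on log₁₀
Nₑ, ~60 windows/species), a single species constrains the breakpoint only
to ~0.1–0.15 decades; pooled 10-species fits reach a median absolute error
below 0.05 decades, and bootstrap 95 % intervals cover the generating
breakpoint at close to nominal rate (checked at 100 replicates × 200
bootstrap draws).

## Bayesian machinery

pyMC-style NUTS is not part of this package's dependency set; three
complementary posterior routes are used instead, each chosen to be exact
or independently checkable:

- **Conjugate linear models.** Gaussian regressions (all climate-only
  trajectory models, the pH-ramp human model, the severity regression) use
  the exact normal–inverse-gamma posterior (prior b | σ² ~ N(0, 100σ²I),
  σ² ~ InvGamma(0.01, 0.01) on standardised predictors). This also
  furnishes the closed-form Student-t leave-one-out predictive density
  used as the exact-refit oracle for PSIS-LOO.
- **Ensemble MCMC (emcee).** Nonlinear posteriors are sampled with the
  affine-invariant ensemble sampler; walkers are partitioned into 4 groups
  that play the role of chains in split-R̂/ESS diagnostics (arviz), with
  the default budget of 2000 warm-up + 2000 sampling iterations and 1000
  thinned posterior draws for reported summaries. Fits with R̂ ≥ 1.01 are
  flagged, never silently returned.
- **Laplace + importance resampling.** For large simulation studies each
  nonlinear fit uses a multivariate-t proposal (df 7, scale 1.3× the
  inverse Hessian at the posterior mode, mode found by L-BFGS-B with
  jittered restarts) corrected by sampling-importance-resampling. Proposal
  standard deviations are capped at 5 in the unconstrained parameterisation
  because the arrival-time direction can be posterior-flat within its
  window, which would otherwise inflate the proposal and starve the
  weights. On single-fit comparisons this route reproduces ensemble-MCMC
  LOO scores to within ~1–2 elpd units at ~50× less cost.

HPDIs are computed by the exact narrowest-contiguous-window scan over
sorted draws.

## Hierarchical slope model

For species i with window points (x_ij, y_ij), x centred −log₁₀ time and
y = log₁₀ Nₑ:

    y_ij = a_i + s_i x_ij + e_ij,   e ~ N(0, σ²)
    a_i ~ N(µ_a, τ_a²),   s_i ~ N(α + β z_i, τ_s²)

with z the standardised log₁₀ body mass. β is the mass effect on the
decline rate. Priors (the upstream analyses do not publish theirs, so
these are the package's own weakly-informative defaults on standardised
quantities): N(0,1) on α and β, N(ȳ, 10) on µ_a, half-N(0,1) on σ, τ_a,
τ_s. Because a_i and s_i are conditionally Gaussian they are integrated
out analytically — the marginal likelihood needs only per-species
sufficient statistics and 2×2 Woodbury identities — leaving a 6-parameter
posterior that mixes quickly; per-species slope draws are then sampled
exactly from their conditional Gaussians given the retained hyperparameter
draws. Replicate studies (50 cohorts of 60 species, noise 0.1, reduced
500+500 iterations) show ≥90 % HPDI coverage of a true β = −0.1 and ≤10 %
false exclusion of zero under β = 0.

The phylogenetic variant replaces the slope prior by
s ~ N(α + βz, τ_s²[λC + (1−λ)I]) with C the Brownian-motion correlation
(shared branch length over maximum depth, unit diagonal) computed from a
newick tree via dendropy, and λ ∈ (0,1) a free weight (uniform prior,
logit-sampled). The marginalisation generalises to a 2S×2S solve. λ = 0
reduces exactly to the independent model (asserted in tests); a star
phylogeny gives C = I, making the two models agree up to Monte-Carlo error.

Decline severity is 1 − min Nₑ/max Nₑ over all windows (reported as %
reduction), with argmin/argmax timed at window midpoints and ties broken
toward the present. The severity regression uses a logit link (severity is
a proportion; the link is this package's choice) on standardised log₁₀
mass and the years BP of the minimum- and maximum-Nₑ windows, with
predictor importance ranked by mean absolute standardised effect.
Severities of exactly 0 or 1 are winsorised to (1e−6, 1−1e−6) with a
warning.

## The 32 trajectory models

Enumeration: climate-only = {linT, quadT} × {noP, linP, quadP} × ±lag
(12; quadratic terms always include the linear term; the lag adds the
adjacent older window's temperature and precipitation, the oldest usable
window reusing its own values with a flag); human-only = logistic,
exponential and linear post-arrival trends plus the presence-probability
ramp (4); combined = 4 configured climate specs × 4 human trends (16,
additive on the log₁₀ Nₑ scale, no interactions). The default combined
block uses linT_linP, linT_linP_L, quadT_quadP and quadT_quadP_L — the
linear-in-both model is the strongest climate form in this model space and
the other three probe lag and curvature; the set is a constructor argument.

Human suppression terms, with elapsed time e = (t_arr − t)/10,000 yr
(the 10-kyr scale keeps rate parameters order one):

- logH: −δ / (1 + exp(−k e))
- expH: −δ (1 − exp(−k e))
- linH: −min(δ, b e)
- pH: a free coefficient times a ramp rising linearly from 0 at the
  earliest arrival bound to 1 at the latest (the simplest monotone
  "probability of human presence").

All terms are zero before arrival and monotone non-increasing in elapsed
time (a property test). The arrival time t_arr is a latent parameter with
a uniform prior over the species' realm arrival window (for the Afrotropic,
the establishment window); k, b, δ and σ carry half-N(0,1) priors after
scaling. These specific functional forms are this package's
parameterisation of monotone post-arrival suppression, not a reproduction
of any external code.

Model comparison sums PSIS-LOO elpd (arviz) across species per spec, with
the SE combined in quadrature; scores with >10 % of Pareto k above 0.7 are
flagged unreliable. PSIS-LOO is validated against exact conjugate
leave-one-out refits on 20-window problems (agreement within 2 SE). On
synthetic cohorts generated under logistic suppression the logH spec ranks
first in ≥80 % of cohorts; under pure climate forcing a climate-family
spec outranks every human-only spec — the package's model-selection
operating characteristics.

Hold-out prediction fits on window midpoints in (100, 742] kyr and
predicts midpoints ≤ 100 kyr (climate covariates standardised with
fit-side statistics), aggregating squared errors into the four 25-kyr
intervals. Under climate-plus-human generation with arrival inside the
held-out period the 0–25 kya MSE exceeds the 75–100 kya MSE in ≥90 % of
replicates; species whose realm arrival predates the split (Afrotropic
establishment) genuinely lack this signature because their suppression is
absorbed by the fit period. Window contrasts are paired t-tests of
species-mean observed minus predicted log₁₀ Nₑ with Cohen's d = mean
difference / SD of differences; the reported degrees of freedom default to
n (the convention used in the published contrasts of this analysis style),
with n−1 behind a flag.

## Ecosystem accounting

Per species, ne_to_nc = (time-weighted Holocene mean Nₑ, 0–11.7 kyr) /
IUCN census; past census = window-mean Nₑ / ne_to_nc; "current" uses the
IUCN census directly. The baseline is the time-weighted mean over 100–742
kya (an unweighted window-average variant exists behind a flag). Missing
censuses yield undefined ratios — never zeros — and exclude the species
from totals with a logged count. Totals: biomass = Σ census·mass·0.15 /
10¹² Gt C; energy = Σ census·(kJ/day) / 10¹² pJ/day; both additive over
species partitions and homogeneous in census (asserted). Extinct and
missing extant species enter through an OLS of log₁₀ census on log₁₀ mass
with Duan smearing retransformation, their baseline census held constant
across pre-extinction windows (a documented stand-in; extinction dates are
out of scope). The historical-calibration variant multiplies all
reconstructions by the geometric mean of historical/implied census over
reference species. End-to-end, a generated cohort with a known ~93 %
total-census decline is reported to within a fraction of a percentage
point, because the accounting is exact given the trajectories; the ±3 %
acceptance band absorbs generator seed-to-seed variation.

## Synthetic-data generator

The generator emulates: PSMC-like grids (boundary 0, then 63 log-spaced
boundaries from 1 kyr to 3 Myr); log-linear trajectories with a
late-Quaternary breakpoint (default 50 kyr, pre-slope −0.01,
mass-dependent post-slopes around −0.45); glacial-cycle climate on 1-kyr
windows (100-kyr sawtooth with rapid deglacial warming plus a ~41-kyr
sinusoid, precipitation co-varying, small window noise); uniform latent
arrival times within realm windows (Afrotropic 200–120 kya establishment;
Palearctic 55–40; Australasia 60–45; Nearctic 23–14; Neotropic 18–12 kya —
round literature values); logistic/exponential/linear suppression with
default drop δ = 1.15 log₁₀ units (a ~93 % decline at saturation, matching
the depth of decline this analysis family reports) and rate 1 per 10 kyr;
and Gaussian observation noise (default 0.1) on log₁₀ Nₑ, i.e.
multiplicative on Nₑ, because PSMC uncertainty is approximately
scale-free. Species masses are log-normal with median ~120 kg and a 22 kg
floor (the smallest megafauna admitted by the study design), with
generation time, mutation rate, field metabolic rate (600·m^0.75 kJ/day)
and census following standard mammalian allometries with log-normal
scatter. PSMC fixture files are produced by the exact inverse of the
scaling transform (noise injected before writing), so the
parse-and-rescale round trip is exact to printing precision (<1e−9
relative).

What the generator does **not** emulate: PSMC's time-dependent estimation
variance and window-to-window autocorrelation, population structure and
migration (which bias real PSMC trajectories), realm-specific climate, or
interactions between climate and human pressure. Passing tests therefore
demonstrate correctness of the estimators under the generative model and
calibrated recovery of its parameters — not that the real-data
conclusions follow, which would require the deposited study data.

## Problem sizes and seeds

The simulation studies in the test suite and `scripts/acceptance.py` run
at deliberately modest sizes chosen as the smallest giving stable
operating characteristics: hierarchical-model calibration at 50 replicates
× 60 species with 500+500 iterations; model-selection recovery at 20
cohorts × 4 species × all 32 specs with Laplace-SIR posteriors; bootstrap
coverage at 100 replicates × 200 draws; hold-out asymmetry at 20 species.
All randomness is seeded; the acceptance script derives every stream from
its single `--seed`.

## Known limitations

- The breakpoint model allows exactly one breakpoint; multiple-regime
  histories will be summarised by the dominant slope change.
- PSIS-LOO on importance-resampled (SIR) posteriors inflates Pareto-k
  diagnostics (duplicated draws); scores remain accurate to ~1–2 elpd but
  the unreliability flag fires conservatively there.
- The hierarchical slope model assumes a single linear trend per species
  on the log–log scale; fitted over a full trajectory containing a
  breakpoint it estimates the time-averaged slope, attenuating the mass
  effect relative to the post-breakpoint value.
- Ne→Nc scaling inherits every caveat of the Holocene-Nₑ/IUCN-census
  ratio: recent bottlenecks and census error propagate multiplicatively
  into all reconstructed totals.
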