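# Methods

This note records the modelling assumptions, parameter choices and numerical
decisions behind `whaletrack`, in the spirit of a model-description appendix.
It states no empirical results beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Process model

Movement is a first-difference correlated random walk (DCRW) on a regular
grid of 2 h (fin) or 4 h (blue) steps, switching between two behavioural
states. For displacement `d_t = x_t − x_{t−1}` (lon/lat degrees):

    d_t | d_{t−1}, b_t ~ N₂( γ_{b_t} · T(θ_{b_t}) · d_{t−1}, Σ )

- `θ = (θ₁, θ₂)` mean turn angles (radians, counterclockwise positive in the
  lon/lat plane). Transiting tracks turn little (`θ₁ ≈ 0`); ARS tracks often
  reverse (`θ₂` near ±π).
- `γ = (γ₁, γ₂) ∈ [0,1]²` move persistence, with the identifying constraint
  `γ₁ > γ₂` (transiting is more persistent). The constraint also fixes the
  label-switching ambiguity of the two-state mixture.
- `Σ` is a single 2×2 process covariance shared by both states. The
  transition equation indexes only `θ` and `γ` by behaviour, so a shared `Σ`
  is the faithful reading; it is also better identified on short tracks.
- Behaviours follow a first-order Markov chain with
  `α = (P(1|1), P(1|2))`. The source model family does not restate this
  prior structure; first-order Markov switching is its standard form and is
  what the generator uses too.
- The first displacement of each track and the initial behaviour get flat
  priors (improper for `d₁`; uniform over the two states for `b₁`). Both are
  anchored by data immediately.

The state space is raw lon/lat degrees, as in the source model family: no
projection, acceptable at mid-latitudes and for the desk-scale synthetic
studies here. This is a documented limitation — at high latitudes a degree
of longitude shrinks, and the isotropy of `Σ` in degrees becomes
geographically anisotropic.

Hierarchy: `θ, γ, α, Σ` are shared by all animals of a species (the fit is a
single model over all tracks simultaneously); locations and behaviours are
per-animal. There are no per-individual movement parameters.

## Observation model

Each Argos fix `y` with grid coordinates `(t, j)` (so that
`time = t0 + (t + j)·dt`, `j ∈ [0,1)`) is modelled as

    y ~ (1−j)·x_t + j·x_{t+1} + scaled-t error

with independent t errors in lon and lat whose degrees of freedom `ν_c` and
scales `τ_c` depend on the fix's Argos location class `c ∈ {3,2,1,0,A,B}`.
The linear interpolation weight `j` is not part of the printed model but is
the standard treatment of irregular Argos times in this family.

The per-class `(ν, τ)` table ships as editable YAML
(`whaletrack/data/argos_error_model.yml`). The study this package follows
cites externally estimated values without printing them, so the shipped
defaults encode the published magnitude ordering of Argos class accuracies
(class 3 ≈ 0.25 km scale with mild tails, degrading to class B ≈ 2.5 km
with heavy tails, ν = 3). They are configuration, not constants: replace the
file to use your own estimates. All six classes must be present.

## Priors

- `θ₁ ~ Uniform(−π/4, π/4)` — transiting turn angles near 0.
- `θ₂ ~ Uniform(−π, π]` (circular; proposals wrap).
- `γ₁ ~ Beta(2,1)`, `γ₂ ~ Beta(1,2)`, truncated to `γ₁ > γ₂`.
- `α₁, α₂ ~ Beta(1,1)`.
- `Σ` via independent HalfNormal(0.1°) priors on the two standard deviations
  and Uniform(−1,1) on the correlation.

## Sampler

A custom vectorised Metropolis-within-Gibbs sampler (no probabilistic-
programming backend is assumed). Per sweep:

1. **States** — single-site random-walk Metropolis. A site `x_t` interacts
   with `x_{t±1}, x_{t±2}` through the process terms, so sites with equal
   `t mod 3` are conditionally independent and each of the 3 colours is
   updated as one vectorised block across all animals. Each site's
   acceptance ratio sums its ≤ 3 process terms and the observation terms of
   fixes attached to it.
2. **Behaviours** — exact Gibbs draws; `b_t` touches `b_{t−1}, b_{t+1}`
   only, so odd/even sites form 2 vectorised blocks.
3. **Parameters** — component-wise random-walk Metropolis on transformed
   scales (logit for `γ, α`; log for the standard deviations; atanh for the
   correlation; wrapped for `θ₂`) with the appropriate Jacobians.

Proposal scales adapt toward target acceptance rates (0.35 states, 0.44
scalars) in windows of 100 iterations during burn-in only, so retained
samples come from a fixed kernel. States initialise at the linear
interpolation of the observed fixes (plus small jitter); parameters
initialise from their priors, giving overdispersed chain starts. A
non-finite initial likelihood triggers re-initialisation (5 attempts).

Default protocol: 2 chains × 50 000 iterations, 45 000 burn-in, thin 5
(2 000 retained samples), matching the source study. The tests and the
acceptance script use scaled-down protocols (documented inline) to fit CI
budgets; the synthetic-data studies show these suffice for the well-
separated default scenario.

Convergence: classic Gelman–Rubin potential scale reduction per scalar
parameter, floored at 1.0 (the unfloored estimator gives √((n−1)/n) < 1 for
identical chains; flooring makes "identical chains → exactly 1" hold, and
when the within-chain variance is 0 with equal means the result is defined
as 1.0).

## Behaviour classification

`b` at each grid time is the mean of the retained MCMC samples (values 1 or
2): transiting if `b < 1.25`, ARS if `b > 1.75`, otherwise uncertain.
Positions are posterior medians with central 95% intervals. The behaviour
of grid time `t` is that of the displacement ending at `t`; the first grid
time mirrors the first displacement.

## Derived analyses

- **Kinematics**: haversine distances (R = 6371 km), speeds per grid
  interval (each interval inherits its starting state's class), headings as
  forward azimuths, turn angles as wrapped azimuth differences in (−π, π],
  counterclockwise positive so a reversal is +π and the convention matches
  `T(θ)`. Zero-length displacements make adjacent turn angles NaN, never 0.
  Posterior-median positions are used (the study does not say median vs
  mean; the median is robust to the heavy-tailed state posteriors).
- **Departure rule**: first run of consecutive grid intervals, total
  elapsed ≥ 48 h, each strictly faster than the pooled median ARS speed.
  Strictness follows the wording "higher than"; the 48 h window is summed
  elapsed time, since states live on the grid. Departure time is the start
  of the run. No qualifying run → censored at track end.
- **Kaplan–Meier** (lifelines backend, validated against hand product-limit
  oracles): events precede censorings at tied times; quartiles are the
  smallest t with S(t) ≤ 0.75 / 0.5 / 0.25.
- **Logistic departure curve** (statsmodels binomial GLM / IRLS, validated
  against a likelihood grid-search oracle): for each whole day since
  tagging, animals with working tags form the binomial denominator and the
  already-departed the numerator — exactly the "weighted by working tags"
  construction. The curve is fit on the departure scale, so
  `dst_at_half = −intercept/slope` is the DST with a 50% chance of having
  departed. A step-function outcome (no mixed day) raises a perfect-
  separation error.
- **ARS areas**: maximal runs of ≥ 3 consecutive ARS states (uncertain
  breaks a run), sized as the convex hull on a Lambert azimuthal equal-area
  plane centred at each run's centroid (no projection is named in the source;
  equal-area keeps sizes comparable across latitudes). Collinear/duplicate
  sets get area 0 with a degeneracy flag.
- **Time budgets**: fraction of grid intervals per class; monthly grouping
  pools across years.
- **Diel profiles**: cyclic-harmonic (sin/cos of 2πkh/24, default k ≤ 2)
  regressions — OLS for speed, binomial-logit GLM for ARS occurrence — on
  solar-local hour (UTC + lon/15, since tracks span many longitudes; the
  choice of solar-local over clock-local time is ours and is flagged).
  These deliberately replace smoother/random-effect fits: all computation
  is transparent and testable, but only qualitative profile shapes (peak
  timing, flat vs peaked) are comparable to smooths, and per-animal
  heterogeneity is reported by fitting per-animal profiles rather than
  random effects.
- **Solar events**: the NOAA algorithm (fractional year, equation of time,
  declination, hour angle at zenith 90.833°), with polar situations
  reported as `midnight_sun` / `polar_night` / `no_full_darkness` (the last
  = sun never 12° below the horizon, the incomplete-darkness criterion).
- **Circular homogeneity**: the likelihood-ratio circular ANOVA is replaced
  by a seeded permutation test on the same null; statistic = Σ_g n_g·R̄_g
  (size-weighted mean resultant lengths), p = (1 + #{perm ≥ obs})/(n_perm+1).
  Groups with zero resultant length contribute 0 and are handled naturally.

## Synthetic data: what it emulates, and what a green test shows

The generator runs the process model forwards (Markov behaviours, DCRW
displacements, cumulative positions) and observes it through a homogeneous
Poisson process of fixes with class-dependent scaled-t noise. Presets echo
the source study's telemetry regimes: `fin_2009_2012` (2 h grid,
~12 fixes/day, 30-day tracks, 8 animals, start 38°N 28°W) and
`blue_2009_2011` (4 h grid, ~7 fixes/day, 45-day tracks, 3 animals). The
default movement parameters are the well-separated regime used throughout
the tests: γ = (0.9, 0.3), θ = (0, π), Σ = diag(0.03°²), α = (0.95, 0.10) —
transiting ≈ 4 km/h and directed, ARS ≈ 1–2 km/h with reversals, dwell
times of ~40 h / ~20 h. Where the study prints only ranges, single values
were chosen once from those ranges and are configuration, not claims.

Not emulated: duty-cycling of tags (the 500 messages/day cap),
environment-driven switching (prey fields, bathymetry), tag-failure models
beyond a fixed track end, and antimeridian-crossing tracks. A green
parameter-recovery or decoding test therefore establishes that the
implementation inverts its own generative model under realistic error and
sampling regimes — not that real whale tracks meet these assumptions.

## Numerical choices

- Grid: `t0` = first fix, `n_states = ceil(span/dt) + 1`; fixes mapped to
  `(t, j)` reconstruct their timestamp to ≤ 1 s (times are whole seconds).
  A fix landing exactly on the final node keeps `j = 0` and ignores the
  (non-existent) next state.
- Duplicate-time fixes (different classes at one timestamp): first kept,
  rest logged — the study does not state its handling.
- Longitudes use (−180, 180]; tracks jumping > 180° between fixes are
  rejected (mid-Atlantic study region; no antimeridian unwrapping).
- `Σ` is inverted in closed form; a non-positive determinant raises.
- Behaviour means are exact sample means; the cut-offs are strict
  inequalities, so `b = 1.25` and `b = 1.75` are both "uncertain".
- Seeds: all randomness flows through `numpy.random.SeedSequence` spawns of
  one user seed (chains, animals and observation streams get independent
  child streams), making every artefact byte-reproducible.

## Known limitations

- Degrees-based state space (above); speeds/areas are computed on the
  sphere afterwards, but the process noise itself is isotropic in degrees.
- No error propagation from the state posterior into speeds, turn angles or
  MCP areas: downstream analyses consume posterior medians.
- Single shared `Σ` and population-level movement parameters can misfit
  heterogeneous populations.
- The Kaplan–Meier median from rounded residence tables need not match a
  median computed from exact event times; the estimator is validated
  against hand-computed oracles, not against any published rounded value.
- Short tracks (< 4 grid states) cannot enter the fit.
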