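# whaletrack

Behaviour-discriminating analysis of satellite-tracked baleen whales:
from raw Argos location tables to behavioural states, residency, discrete
foraging areas and diel activity profiles.

Argos satellite fixes are irregular in time and carry class-dependent,
heavy-tailed position errors, so neither locations nor behaviour can be read
off the raw track. `whaletrack` implements the standard remedy from movement
ecology — a Bayesian **hierarchical switching state-space model (hSSSM)** —
together with the downstream ecology built on top of it: area-restricted
search (ARS) detection, residence-time survival analysis and hour-of-day
activity rhythms. It is written for biotelemetry researchers who want a
self-contained, fully testable Python implementation; a synthetic-track
generator reproduces the relevant data regimes so every stage can be
validated without access to real telemetry.

## The model

Movement follows a first-difference correlated random walk (DCRW) on a
regular time grid (2 h for fin whales, 4 h for blue whales). With
`d_t = x_t − x_{t−1}` the displacement between successive latent positions
(lon/lat, degrees),

```
d_t | d_{t−1}, b_t  ~  N₂( γ_{b_t} T(θ_{b_t}) d_{t−1} , Σ )
```

where `T(θ)` is the rotation matrix, `γ ∈ [0,1]` the move-persistence
coefficient (combined autocorrelation in speed and direction) and
`b_t ∈ {1,2}` a latent behavioural state switching by a first-order Markov
chain with probabilities `α`. State 1 (*transiting*) has turn angles near 0
and high persistence; state 2 (*ARS*, the foraging proxy) has low
persistence and frequent reversals. Movement parameters are shared across
all animals of a species; states and behaviours are per-animal. Each Argos
fix `y` in grid interval `(t, j)` is modelled as the interpolated state
`(1−j)x_t + j·x_{t+1}` plus independent scaled-t errors whose scale and
degrees of freedom depend on the fix's location class (3, 2, 1, 0, A, B).

Inference is MCMC (adaptive Metropolis-within-Gibbs; default protocol
2 chains × 50 000 iterations, 45 000 burn-in, thin 5), checked with the
Gelman–Rubin diagnostic. The posterior mean `b` at each grid time classifies
it as transiting (`b < 1.25`), ARS (`b > 1.75`) or uncertain.

Downstream: departure from the tagging area is the first ≥ 48 consecutive
hours faster than the pooled median ARS speed; residence times (right-censored
when tags die early) feed a Kaplan–Meier estimator and a weighted logistic
departure curve; a discrete ARS area is ≥ 3 consecutive ARS positions,
sized by its minimum convex polygon on a local equal-area projection; diel
profiles are cyclic-harmonic regressions against solar-local hour, with
sunrise/sunset from the NOAA solar algorithm.

## Worked example

```python
import numpy as np
import whaletrack as wt

# a synthetic population in the fin-whale telemetry regime
cfg = wt.preset_config("fin_2009_2012", seed=7, n_animals=4, duration_days=15.0)
truths = wt.simulate_tracks(cfg)
tracks = wt.observe_tracks(truths, cfg)

fit = wt.fit_hssm(tracks, dt_hours=2.0, seed=1,
                  mcmc={"n_chains": 2, "n_iter": 3000, "burn_in": 2000, "thin": 2})
states = wt.classify_behaviour(fit)
kins = [wt.speed_series(s) for s in states]
```

prints (via the obvious summaries; full script in the docstrings):

```
R-hat (max): 1.21
gamma transiting: 0.907  (true 0.90)
gamma ARS:        0.264  (true 0.30)
behaviour decoding accuracy: 96.1%
median ARS speed: 1.23 km/h
discrete ARS areas: 8; largest 54 km2
animal sim01 time budget: transiting 0.71, ARS 0.12, uncertain 0.18
```

The fitted persistence coefficients recover the two regimes the tracks were
generated from (directed transit vs erratic search), 96% of grid times are
decoded to the correct true behaviour, and the slow, reversal-rich ARS bouts
condense into a handful of small discrete search areas — the quantities a
residency/foraging analysis consumes. At this deliberately short MCMC
setting R-hat is still slightly above 1.1; the default protocol drives it
down further.

The same pipeline is scriptable from the shell:

```sh
whaletrack simulate --preset fin_2009_2012 --seed 42 --out sim/
whaletrack fit --input sim/tracks.csv --dt 2 --iterations 3000 --burn-in 2000 \
    --thin 2 --seed 1 --out sim/fit.npz
whaletrack classify --fit sim/fit.npz --out sim/states.csv
whaletrack residency --states sim/states.csv --out sim/residency.json
# or everything at once from a YAML config:
whaletrack run --config demo.yml
```

## Acceptance script

`scripts/acceptance.py` re-runs the whole method from scratch — simulate a
population, fit the hSSSM (scaled-down MCMC), classify behaviours, and run
the kinematic, residency and diel analyses — logging a summary to stderr and
writing the results JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/whaletrack/track_io.py` — Argos CSV I/O, regular time grid, state output
- `src/whaletrack/ssm.py` — the hSSSM: densities, MCMC sampler, diagnostics, classification
- `src/whaletrack/movement_metrics.py` — great-circle distances, speeds, headings, turn angles
- `src/whaletrack/residency.py` — departure rule, Kaplan–Meier, logistic curve, ARS areas, budgets
- `src/whaletrack/diel.py` — NOAA solar events, harmonic diel profiles, circular permutation test
- `src/whaletrack/synthetic.py` — the two-regime track generator and presets
- `src/whaletrack/cli.py` — the `whaletrack` command
- `docs/methods.md` — modelling assumptions, priors, numerical choices, limitations
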