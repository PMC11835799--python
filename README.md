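# dirswarm

Simulation and analysis of **directional swarmalators** — agents that
simultaneously *swarm* (move in the plane), *oscillate* (bounce to a beat),
and *gaze* (carry a heading that restricts whom they attend to).  The model
targets collective dynamics on dance floors: groups of dancers hearing
possibly different rhythmic stimuli (a silent disco), moving toward, looking
at, and entraining to each other.

## The model

Each agent *s_j* carries five state variables: position **x**_j ∈ ℝ²,
oscillation phase θ_j, gaze azimuth δ_j, spontaneous frequency ω_j, and the
phase φ_j of its external stimulus.  Writing w_jk = 1/|**x**_j − **x**_k| for
proximity and α_kj for the azimuth from *s_j* to *s_k*:

**Translation** — global attraction, pairwise repulsion, and
phase-and-gaze-gated attraction:

    ẋ_j = −A x_j |x_j|^{a−1}
          − (R/N) Σ_{k≠j} w_kj^r (x_k − x_j)/|x_k − x_j|
          + (P/N) Σ_{k≠j} w_kj^p Ω(θ_k − θ_j) Υ(α_kj − δ_j) (x_k − x_j)/|x_k − x_j|

**Rotation** — gaze is pulled toward proximal, phase-similar peers:

    δ̇_j = (D/N) Σ_{k≠j} w_kj^d Υ′(α_kj − δ_j) Ω(θ_k − θ_j)

**Oscillation** — spontaneous frequency plus auditory and visual entrainment:

    θ̇_j = ω_j + U sin(φ_j − θ_j) + (V/N) Σ_{k≠j} w_kj^v Υ(α_kj − δ_j) sin(θ_k − θ_j)

The phase kernel Ω(θ) = (1 + cos θ)/2 gates interaction on phase similarity.
The gaze kernel Υ(θ; c) = ((1 + cos θ)/2)^c, normalized to unit integral over
the circle, models a restricted visual field; the *constriction* exponent
c ≥ 0 narrows it (c = 0 is panoramic vision).

Group-level self-organization is quantified per frame by circularity κ
(SD of distances from the centroid; 0 for a perfect circle), grouping
coefficient ρ (intraclass correlation of positions across stimulus groups),
gaze locking γ, centroidal alignment χ, Kuramoto phase coherence R, and a
spatially localized coherence R^σ.  For empirical data, per-agent position
and gaze come from two head markers, and the bounce phase is the Hilbert
(analytic-signal) phase of the vertical head velocity.

The two rotational parameters — constriction c and gaze strength g ≡ D —
are fitted by simulated annealing against end-of-run target configurations,
minimizing the summed absolute differences of spatial variance, ρ, and χ
across datasets.

## Worked example

Simulate 12 agents in two stimulus groups (120 BPM, second group shifted by
180°) for 60 s at 120 Hz, then measure self-organization:

```sh
dirswarm simulate --seed 42 --out states.csv
dirswarm measure --states states.csv --sigma 1.0 --out measures.csv
```

```
wrote 7201 frames x 12 agents to states.csv
wrote 7201 measure rows to measures.csv
```

The same in Python, inspecting start and end of the run:

```python
from dirswarm import ModelParams, run_simulation
from dirswarm.measures import MeasureConfig, measure_series
from dirswarm.synthetic_data import ScenarioSpec, build_schedule, generate_initial_config

spec = ScenarioSpec(seed=42)          # 12 agents, 6+6, 120 BPM, 180 deg shift
state = generate_initial_config(spec)
traj = run_simulation(state, build_schedule(spec), ModelParams(), duration=60.0)
df = measure_series(traj, MeasureConfig(sigma=1.0, downsample=120))
print(df[["time_s", "spatial_variance", "rho", "chi", "R"]].iloc[[0, -1]].round(3))
```

```
    time_s  spatial_variance    rho    chi      R
0      0.0             5.231  0.069  0.071  0.014
60    60.0             3.120  0.032  0.041  0.008
```

The group contracts (spatial variance falls from 5.2 to 3.1 square length
units) while each agent locks to its own group's beat — the two groups are
in antiphase, so the *global* Kuramoto order R stays near zero even though
every agent is entrained: the per-group columns of the same series show
`R_g1 = 0.983`, `R_g2 = 0.975` at 60 s.

To fit the rotational parameters against synthetic ground truth:

```python
from dirswarm.calibration import calibrate
from dirswarm.synthetic_data import generate_calibration_suite

targets = generate_calibration_suite(c_true=0.25, g_true=0.25, seed=1)
result = calibrate(targets, seed=1, budget=200)
print(result.best_c, result.best_g, result.best_error)
```

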