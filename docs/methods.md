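# Methods

## Model

A directional swarmalator couples three first-order dynamics. Translation
combines a global pull toward the arena origin (strength `A`, growth
exponent `a`), pairwise repulsion decaying with distance (strength `R`,
proximity exponent `r`), and attraction toward peers gated by phase
similarity and visibility (strength `P`, exponent `p`). Rotation pulls the
gaze azimuth toward proximal, phase-similar peers (strength `D`, exponent
`d`). Oscillation advances each phase at its spontaneous frequency,
entrained to the agent's own auditory stimulus (strength `U`) and to
visible peers (strength `V`, exponent `v`).

Two kernels shape the interaction. The phase kernel is the raised cosine
`Ω(θ) = (1 + cos θ)/2`: 1 for phase-aligned pairs, 0 for antiphase pairs.
The gaze kernel is `Υ(θ; c) = ((1 + cos θ)/2)^c` normalized by its integral
over `(−π, π]`, so it is a density on the circle for every constriction
`c ≥ 0`: `c = 0` is panoramic vision (uniform 1/2π), larger `c` narrows the
attended sector. The normalization constant is closed-form at `c = 0` (2π)
and `c = 1` (π) and computed once per `c` by adaptive quadrature otherwise
(cached). A closed Wallis-type form, `2√π · Γ(c + ½)/Γ(c + 1)`, is used as
an independent oracle in the tests.

The rotation kernel `Υ′` is implemented in its closed printed form,
`(c sin θ / 2) · ((1 + cos θ)/2)^{c−1}`, with a **positive** sign and
**without** the density normalization. The positive sign makes gaze rotate
toward attractive targets, which is the stated behavior of the rotational
dynamics; the literal derivative of the normalized density would rotate
gaze away. Setting `ModelParams.normalized_gaze_derivative = True` divides
by the same normalization constant as `Υ`, which makes the kernel the exact
derivative of the density (up to the sign choice); this variant exists for
sensitivity analysis and is off by default. At exactly `θ = π` with
`c < 1` the closed form is a 0·∞ limit; it is defined as 0 by odd symmetry
(for `0 < c < 0.5` the kernel is unbounded as `θ → π`, which is integrable
and harmless at time step 1/120 s in practice).

## Parameters

Defaults (`ModelParams`) are the values used for model fitting:

| parameter | symbol | default | unit |
|---|---|---|---|
| attraction_strength | A | 0.1 | s⁻¹ |
| attraction_exponent | a | 1 | — |
| repulsion_strength | R | 1.5 | s⁻¹ |
| repulsion_decay | r | 2 | — |
| pg_attraction_strength | P | 0.5 | s⁻¹ |
| pg_spatial_decay | p | 1 | — |
| gaze_strength | D ≡ g | 0.25 | s⁻¹ |
| gaze_spatial_decay | d | 1 | — |
| auditory_strength | U | 0.8 | s⁻¹ |
| visual_strength | V | 0.4 | s⁻¹ |
| visual_spatial_decay | v | 1 | — |
| constriction | c | 0.25 | — |
| freq_mean | μ | 4π | rad/s |
| freq_sd | σ_ω | 0.2 | rad/s |
| min_distance | ε | 10⁻⁶ | length |

`gaze_strength` and `constriction` default to the rounded fitted optimum
(0.25 each). Spontaneous frequencies are Normal(μ, σ_ω); μ = 4π rad/s is
the 120 BPM tactus and σ_ω = 0.2 rad/s keeps detuning well inside the
auditory locking range (|Δω| < U), the regime in which dancers
instructed to bounce on the beat actually operate. Spatial units are
dimensionless; the default arena radius (3) and the attraction/repulsion
balance give order-1 interagent distances.

Angle convention throughout: radians, counterclockwise positive, azimuths
from the +x axis, wrapped to `(−π, π]` (half-open; −π maps to +π).

## Integration

Forward Euler with a fixed step, 1/120 s by default to match 120 Hz motion
capture; a 60 s run spans 7201 frames. The stimulus phase is *not*
integrated — it is re-evaluated from the beat schedule
`φ = wrap(2πft + offset)` every step, so it tracks the beat exactly.
Pairwise sums exclude the self-term; distances are clipped below at ε so
coincident agents cannot produce infinite proximities. Runs abort with the
offending frame index if any coordinate exceeds a divergence bound
(default 10³) or any derivative becomes non-finite.

Two integration loops implement the identical update: a pure-numpy
reference stepper and a numba-compiled whole-run loop (the default when
numba imports; `engine="numpy"` forces the reference). They agree exactly
over short horizons; over 60 s they drift apart by ~10⁻⁶ in position purely
through float summation order, which is far below any quantity interpreted
scientifically. Euler is first-order: halving the step moves the 60 s
endpoint by O(dt), verified in the tests.

## Measures

Circularity κ uses the population (1/N) standard deviation, which makes
κ = 0 exact for regular polygons of any N. The grouping coefficient ρ is
the multivariate intraclass decomposition: within-group and between-group
sums of squared 2-D distances about group/global centroids, each divided by
N; ρ = between/(between + within), and 0 is returned in the fully
degenerate all-coincident case. The local coherence kernel sum includes the
self-term (`k = j`, weight 1). Centroidal alignment skips (with a warning)
agents sitting exactly on the centroid, whose bearing is undefined. The
"group size" used in calibration is the spatial variance — the mean squared
distance from the global centroid (trace of the population positional
covariance); the per-frame series also exposes κ, so either convention of
group size can be read off.

## Empirical state estimation

Position is the horizontal midpoint of the left and right head markers.
Gaze is the azimuth of the right→left marker vector rotated −90°, so a
person with the left marker at (−w, 0) and the right at (+w, 0) faces +y;
the rotation sign is configurable for mirrored marker conventions. The
bounce phase is `angle(v + i·H(v))` where `v` is the vertical velocity of
the head midpoint by central differences at the native rate and `H` the
Hilbert transform; the first and last 0.5 s are flagged edge-unreliable.
No filtering is applied by default; an optional zero-phase Butterworth
band-pass on the velocity is exposed for noisy recordings. Marker files
are long-format TSV/CSV on a uniform grid; gaps up to a configurable
length (default 12 frames = 0.1 s) are linearly interpolated, longer gaps
are an error.

## Calibration

The composite error of a parameter pair (c, g) against one dataset is the
sum of absolute differences of three summary metrics — spatial variance,
grouping coefficient, centroidal alignment — between the simulated and the
target configuration at the end of a 60 s run; the total error sums over
datasets (a joint fit). Oscillatory measures are deliberately excluded from
the error. Spontaneous frequencies are frozen inside each dataset's initial
state, so the error surface is deterministic and the error of a synthetic
dataset at its generating parameters is exactly zero. An option evaluates
the metrics as a trailing-window average (sampled at 10 Hz) instead of the
final frame only; the default is the final frame.

The optimizer is simulated annealing (`scipy.optimize.dual_annealing`,
local-search phase disabled) over the box [0, 1]², chosen because the
grouping coefficient makes the error non-smooth. Every evaluation is
logged; the reported optimum is the best logged point (the starting point
is evaluated first, so the result can never be worse than it), and the
evaluation budget is enforced by truncating the log. A flat landscape
returns the starting point with a warning. `error_surface` evaluates the
same error exhaustively on a lattice.

### Identifiability of (c, g) in recovery studies

The 60 s endpoint of a 12-agent run depends sensitively on (c, g):
trajectories decorrelate under parameter changes of ~0.02, so near the
generating parameters the error surface of a synthetic dataset is an
isolated exact zero sitting on a rugged floor (~0.05–0.15 per dataset)
rather than a smooth funnel, superimposed on a large-scale bowl. Because
the floor is a sum of |Δ| terms, it concentrates around its smooth
expectation as datasets are added, and the bowl — whose minimum is at the
generating parameters — becomes resolvable at finer scales. A single
dataset's three scalar targets do not identify the pair at all (near-zero
error can occur far from the truth); four datasets identify c but leave g
marginal. The packaged recovery experiment therefore fits **eight**
synthetic datasets jointly (four per phase-shift condition, 90° and 180°,
each with its own initial configuration and spontaneous frequencies),
evaluating trailing 10 s averages; this mirrors the joint multi-recording
fit of the original procedure while giving the two parameters enough
independent constraints. Consistent with the model's structure, the error
is distinctly more sensitive to the constriction c than to the gaze
strength g.

## Synthetic data

The generators emulate the reference silent-disco setting: 12 agents in two
groups of 6; 120 BPM beat (2 Hz); the second group phase-shifted by 180°
(or 90°), or sped up by a configurable ratio (default 1.25). Initial
positions are uniform in a disc of radius 3, gazes uniform on the circle,
phases at the assigned stimulus phase plus 0.2 rad Gaussian jitter.
Synthetic head markers bounce sinusoidally at the stimulus phase
(`z = z₀ + A sin φ(t)`, amplitude 0.05, head height 1.6) around a slowly
drifting horizontal midpoint, with a fixed marker half-width of 0.08 and
optional additive Gaussian noise. Every generator is a pure function of
(spec, seed).

What the synthetic data does *not* emulate: biomechanical bounce kinematics
(asymmetric down-beats, knee-flexion waveforms), marker occlusion/swap
artifacts, visual-search head rotations, or the erratic repositioning real
dancers show. Passing the pipeline tests on synthetic bounces therefore
validates the estimators' correctness (geometry, analytic-signal phase,
schema handling), not their robustness to every artifact of real optical
capture.

## Known limitations

- Forward Euler only; the step size is part of the study conditions, and no
  higher-order integrator is provided.
- The fitted optimum reported for the original recordings (c = 0.252,
  g = 0.251, errors 1.60 vs 1.81 without heading dynamics) cannot be
  reproduced here because those recordings are not deposited; the package
  reproduces the *machinery* (error, annealing, surface scan) and validates
  it on synthetic ground truth, including the qualitative result that
  fitting with heading dynamics (c > 0) beats c = 0 on targets generated
  with a restricted visual field.
- Gaze is 2-D azimuth only; no elevation, anticipation, or gaze noise.
- The recovery experiment's problem sizes (eight 60 s datasets, 200
  evaluations) were chosen as the smallest design the identifiability
  analysis above supports.
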