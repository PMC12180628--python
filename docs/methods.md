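# Methods

## Model

The observer model composes two stages.

**Perceptual stage (efficient Bayesian observer).** Heading direction θ
lives on the circle, represented internally in radians in [−π, π) and in
degrees at every public interface (0° straight ahead, negative left).
The prior p(θ) is a two-component von Mises mixture; under efficient
coding it is the normalized reciprocal of the discrimination threshold,
which for human heading is smallest straight ahead and straight back,
hence peaks at 0° and 180°. Encoding maps θ through the cumulative prior
F(θ) = ∫₋π^θ p(ϑ)dϑ into a sensory space where Fisher information is
uniform. F ∈ [0, 1] is rescaled to the sensory circle as F̃ = 2πF − π so
that the von Mises noise model is 2π-periodic and its concentration κ is
an ordinary circular concentration. The measurement is m = F̃(θ₀) + η,
η ~ vonMises(0, κ); the likelihood over θ is
p(m|θ) = exp(κ cos(m − F̃(θ)))/(2π I₀(κ)). The posterior follows by
pointwise Bayes on the stimulus grid, and the estimate θ̂(m) is the
posterior **circular** mean. A linear mean is ill-defined on the circle;
for the concentrated posteriors of the forward-heading regime the two
coincide, and the circular choice keeps the estimator total for very
broad posteriors.

**Response stage (perception-action mapping).** The report is
θ̂ᵣ = α·θ̂, scaled about straight ahead, with one scaling factor α per
response-range condition; α > 1 expands reports, α < 1 compresses them.
Finite probes (line or arc of range w) clip reports at ±w/2; the mass
pushed onto the boundary is carried as explicit boundary atoms of the
response distribution. The full circle wraps instead of clipping. The
probe geometry (line vs arc vs circle) is metadata only — the model
depends on the range through α alone.

**Predictions.** The response density for a true heading θ₀ pushes
p(m|θ₀) through m ↦ α·θ̂(m) by change of variables along the decoder,
which is verified to be a monotone degree-one circular map at
construction. Predicted bias is the circular mean of θ̂ᵣ under p(m|θ₀)
minus θ₀ (wrapped, degrees); predicted spread is the circular SD
σ = √(2(1 − R)) with R the mean resultant length, converted to degrees.
This σ is the standard circular statistic; because the measurement
distribution is symmetric about F̃(θ₀), the circular-mean bias
reproduces the linear-mean algebra exactly (e.g. b = (α−1)θ₀ under a
flat prior), which is the identity the response-scaling account turns
on.

## Fitting

Four free parameters per fit: κ shared across conditions, one α per
condition. The negative log-likelihood sums −log of the response density
at each reported heading; reports on a finite probe's boundary
(clipped trials) contribute the boundary atom's probability mass
instead of a density value. Densities are floored at 1e−12 before the
log and floored trials are counted in the result. An optional
constraint pins α = 1 for full-circle conditions, required when both
stimulus and response range span 360°.

Optimization runs from 5 seeded start points (the first warm-started
from the empirical bias slopes, the rest random in a broad box), each
with a short Nelder-Mead descent followed by an exact
profile-likelihood polish: for fixed κ the NLL separates into
independent one-dimensional problems per condition's α — the decoder
depends on κ only — so the polish is a bounded scalar search over log κ
with Brent solves for the α's inside. This removes the premature
stalling a pure simplex exhibits in the curved κ–α valley; restart
optima then agree to ~1e−7 NLL. Bounds: κ ∈ [0.05, 500] (log scale
internally), α ∈ [0.1, 3]. Group-level fits pool all participants'
trials; individual-level fits run per participant. Fits are
deterministic given (data, seed).

The `recovery_study` harness refits data simulated from known
parameters and reports mean/SD of the recovered values per design cell.

## Synthetic experiments

`make_design` reproduces the structure of the three reference designs:
12 headings (±3°…±33°, the stimulus range all experiments share);
exp1 — between-subject line (80°, 40 reps/heading/block) vs circle
(360°, 15 reps/block), each group with one constant- and one
triangular-speed block (480 / 180 trials per block); exp2 —
within-subject line80/arc80/circle360 at 20 reps (240 trials per
block); exp3 — arc80/arc160/arc240 fully interleaved at 15 reps
(540 trials). The stated alternative total of 720 trials for the
interleaved session is available via `exp3_reps_per_heading=20`; the
12×3×15 arithmetic gives 540, and the discrepancy between the two
stated totals is surfaced as this option rather than hidden.

`generate_trials` simulates the generative chain exactly as the
response density models it (same branch convention for decoding and
clipping), so empirical histograms converge to `response_density` by
construction — verified by Monte-Carlo tests. The (heading, condition)
schedule is shuffled by a generator seeded from the **design**, while
sensory noise is seeded from the `generate_trials` seed: the schedule
is a property of the design and identical across noise seeds. With
more than one synthetic participant, per-participant κ is drawn
log-normally around the shared value (σ_log = 0.3, emulating the
individual variation seen in per-participant fits); a single
participant uses the shared κ exactly, so recovery studies run at the
nominal parameters.

Speed profiles (constant 1.5 m/s vs triangular 0→3→0 m/s at 12 m/s²,
0.5 s, both 0.75 m travel) are design metadata: the observer model is
profile-blind, matching the empirical null effect, and
`travel_distance` checks the kinematic identity in closed form.

What the generator does **not** emulate: lapses, reaction-time or
sequential effects, motor noise beyond the scaled sensory noise, the
small near-0° "wiggle" attributed to categorical perception, and
dot-level optic-flow rendering. Passing recovery tests therefore show
identifiability of (κ, α) under the model's own assumptions, not
robustness to these real-data features.

## Numerics

All densities are tabulated on uniform circular grids (default 1024
points, endpoint identified), integrated with the periodic trapezoid
rule, which is spectrally accurate for these smooth integrands; with
κ ≤ 500 the von Mises Fourier tail at the grid Nyquist frequency is
negligible. The cumulative prior is a trapezoid cumsum renormalized so
F(π) = 1 exactly. Likelihood/posterior products are computed in log
space to survive large κ. The decoder table is built on a measurement
grid matching the stimulus grid and stored unwrapped; measurement
nodes for response densities are oversampled 4× relative to the
decoder grid (they cost no decoder rebuild) so that the trapezoid mass
of the report density is exact to ~1e−7. Full-circle response
densities are folded onto the canonical interval [−180°, 180°] with
the CDF cut at −180°, summing overlapping periodic images when α ≠ 1.

Fitting uses a 512-point grid (the Model layer re-tabulates the prior);
predictions default to 1024. Doubling the grid changes predicted bias
and SD by < 0.001°, far inside the 0.05° convergence requirement, and a
540-trial fit takes about 20 s. Degenerate inputs fail loudly: zero
posterior resultant length, non-monotone decoding, all-zero prior
weights, missing condition scalings and malformed trial rows all raise
with the offending quantity named.

## Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| prior peaks | 0, 180 | deg | straight ahead / straight back |
| prior concentrations | 2.0, 2.0 | — | placeholder matching the qualitative two-peak shape; the reference fit's parameters are not published, so defaults are explicit and overridable |
| prior weights | 0.5, 0.5 | — | symmetric peaks |
| κ (simulation default) | 4.0 | — | report SDs of ~10–25° over the probe set, the magnitude range of human heading reports |
| α (simulation defaults) | 0.85 / 1.0 / 1.15 for 80/160/240° | — | compressive→expansive progression producing the bias-slope reversal |
| grid resolution | 1024 (512 for fitting) | points | convergence verified |
| exp3 repetitions | 15 (540 trials) | — | see design note above |

The bias-reversal demonstration (slopes across α = 0.85/1.0/1.15
straddling zero) is evaluated at κ = 16: with the broad default prior,
efficient-coding repulsion contributes a positive perceptual slope that
decays with κ (≈ +0.26 at κ = 4, ≈ +0.08 at κ = 16), and the straddle
is a property of the regime where response scaling dominates that
residual repulsion. Monotonicity of the slope in α holds at every κ.

## Known limitations

- The default prior is a stand-in of the correct shape, not a fit to
  discrimination data; `prior_from_thresholds` exists for users with
  threshold tables.
- The α-scaling is linear about straight ahead; at ±180° with α ≠ 1 it
  is kept total by clipping/wrapping, but data near straight back were
  never in view and the mapping there is an extrapolation.
- No motor/readout noise beyond the scaled sensory noise; if real
  reports carry extra jitter, κ̂ will absorb it downward.
- Group-level fitting pools trials rather than modelling participant
  heterogeneity hierarchically.
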