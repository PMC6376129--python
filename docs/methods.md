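# Methods

`watermaze` simulates landmark learning and goal-directed swimming in
the Morris water maze. Two coupled models run per simulated rat: a
trial-level Rescorla–Wagner (RW) learner that acquires associative
strengths for each distal cue, and a step-level directed random walk
with feedback heading control that turns those strengths into swim
paths, escape latencies and probe-trial search patterns.

## World model

Origin at the pool centre, +y north, +x east; bearings in degrees
clockwise from north, so position updates are `x += Δr·sin α`,
`y += Δr·cos α`. Units are cm, s, degrees. The default arena is a
170 cm diameter pool with a 9 cm diameter platform in the NE quadrant
(bearing 45°, 42.5 cm from centre), two landmarks outside the pool at
120 cm from the centre — `Near` at NE, `Far` at NW — and the standard
protocol: 4 × 60 s trials/day for 10 days from {N, S, E, W} in a daily
pseudorandom order, plus a 60 s platform-absent probe from SW. The
platform bearing/eccentricity and cue mounting radius are not uniquely
determined quantities; the defaults are standard placements and all are
configurable. Quadrants are half-open 90° sectors ([0°, 90°) = NE, …)
so boundary points classify deterministically; probe scoring also uses
a circular "platform area" (default radius 20 cm, configurable) and its
rotational equivalents in the other quadrants.

## Learning model

Cue usage is competitive: with saliences α_i ∈ [0, 1],

    ΔV_i,use = α_i · β_use · (λ_use − Σ_j V_j,use),

all cues updated simultaneously against the pre-update total (with a
proportional rescale in the pathological case where a single increment
would overshoot λ_use). One cue's gain therefore limits the other's —
the substrate of overshadowing. Direction and distance knowledge are
independent per cue:

    ΔV_i,dir = α_i · β_dir · (λ_dir − V_i,dir),   likewise for dist.

Updates are applied once per trial, unconditionally (no
performance-gating; the model's learning trajectory depends only on the
salience schedule). Saliences across a presented compound are treated
as complementary shares (a lone training cue takes α = 1; two equal
cues take 0.5 each). Defaults β_use = 0.15, β_dir = β_dist = 0.2,
λ = 1 put a two-equal-cue learner above 98.5 % of every asymptote
within the 40-trial protocol, which is the regime the acquisition
curves require; the usage-capacity result (a cue trained against a
competitor holding 0.7 of the capacity tops out at 0.3) is independent
of these rates.

## Platform inference

When the rat engages a cue it samples a platform estimate: the cue's
true polar offset to the platform (r, φ) perturbed by zero-mean normal
errors whose spread shrinks with knowledge, σ_ch = 1 − V_ch:

    Var(ε_dist) = 200 · σ_dist  [cm²],   Var(ε_dir) = 75 · σ_dir  [deg²].

The 200/75 constants scale the error **variance** (`error_model=
"variance_linear"`, the default): at full uncertainty the distance
error std is √200 ≈ 14 cm and the direction error std √75 ≈ 8.7°.
Read instead as standard-deviation multipliers (`"std_linear"`, also
implemented) a fully uncertain channel would scatter estimates with a
200 cm std — 2.3 pool diameters — and no parameterisation of the
swimmer brings the single-channel escape-time regimes (means of 7–12 s
with sds of 3–8 s) within reach: those statistics require guess scatter
of order 10 cm. The variance-linear reading is therefore the model
default; both options are regression-tested.

A sampled radius below zero is reflected through the anchor (bearing
flipped 180°; truncation at zero available). Estimates are not clipped
to the pool: they are steering targets, and the wall rule handles
containment.

**Cue misidentification is configural.** When a learned relationship is
applied to a different physical landmark (the cue-removal,
generalization and misinterpretation scenarios), the learned bearing is
rotated by the angular offset between the two cues' bearings from the
pool centre. A rat that misreads the NE landmark as its NW-learned cue
therefore places the platform at the SE mirror position, and the
converse misreading points NW. Plain re-anchoring without the rotation
was implemented first and rejected: for any geometry with the platform
between the cues it sends the misread estimate just inside the NE
sector (the y-component r_p·cos β_p of the rotated-platform position is
always positive), which contradicts the SE/NW search patterns this
class of generalization experiment shows. The rotation also makes the
misread estimate land inside the pool rather than beyond the wall.

## Swimming model

Step size is Rayleigh-distributed; the heading change follows an AR(2)
process driven by a proportional controller on a low-pass-filtered
heading error:

    Δα_t = A1·Δα_{t−Δt} + A2·Δα_{t−2Δt} + K·ê_t + ν_t,
    ê_t = (1 − F)·ê_{t−Δt} + F·(α_desired − α_t),  ν_t ~ N(0, noise_std²),

with angles wrapped to (−180°, 180°]. A step that would exit the pool
is radially clamped to the wall with heading preserved (reflection
available). Platform contact is centre-to-centre distance ≤ platform
radius, evaluated along the straight step segment (the swimmer moves
continuously between samples; endpoint-only checking skips a 4.5 cm
platform at 20 cm steps and is available as `contact_rule="endpoint"`).

## Integration: the five-step behavioural loop

Each trial iterates: (1) select a learned relationship — cue i with
probability V_i,use, none with 1 − ΣV_use; (2) if none, swim uncued for
n_steps = 7 steps; (3) if a cue, steer toward the presented landmark
for 7 steps, re-aiming each step; (4) draw a fresh platform estimate
and steer toward it until within `goal_tolerance` or 2·n_steps elapse
(the estimate may be unreachable); (5) repeat until platform contact or
the 60 s limit (latency then censored at 60 s). Release is at the rim
facing the pool centre. Interpretation policies decide which learned
relationship a presented landmark engages: `identity` (each cue is
itself; also the behaviour of every policy when the full trained cue
set is visible), `indistinguishable`/`generalize_to_salient` (a
relationship is drawn with probability equal to its V_use and applied
to the visible landmark — at extreme saliences this is deterministic
generalization, at a 50:50 split the two policies coincide by
construction), and `probabilistic_misinterpretation` (a named dim cue
is read as itself with probability 1 − p and as the other cue with
probability p, the chosen relationship engaging with its own V_use).

Uncued episodes are run-and-tumble: the controller is disengaged
(ê ≡ 0, so the input is pure noise) *and* the episode starts with a
fresh uniform-random heading. With the calibrated heading noise (4° per
step) a drifting uncued walk is nearly ballistic and wall-following;
the reorientation makes undirected search diffusive at the trial scale,
which is what gives an untrained animal pool-wide coverage and makes
probe search with an uninformative cue quadrant-uniform. Pure drift
(`uncued_reorient=False`) and literal steer-to-north
(`uncued_steer_north=True`) variants are kept for comparison.

## Calibration of the swimming defaults

The controller constants are not identifiable from first principles;
they were calibrated (`scripts/calibrate_swim.py`, a grid search the
repository ships) against behavioural anchors: an untrained swimmer
should meander and mostly fail within 60 s; a fully informed swimmer
released at the rim should escape in ~5–10 s; and the four
single-channel conditions (one cue always used, one vector channel at
association 0.95, the other fully uncertain) should fall in their
reference regimes of roughly 11 s (Near-direction), 7.8 s
(Far-direction), 6.9 s (Near-distance) and 12.1 s (Far-distance), with
Far-direction reliably beating Near-direction and Near-distance beating
Far-distance. Frozen defaults: A1 = 0.25, A2 = 0.05, K = 0.95,
F = 0.92, Rayleigh scale 20 cm, noise 4°, Δt = 0.5 s, goal tolerance
2 cm. Two calibration observations are worth recording. First, the
step scale is an *effective* behavioural parameter, not a literal
stride: a 7-step cue-approach episode then spans the pool, and the
Far-cue advantage in direction learning emerges precisely from such
pool-spanning episodes (shorter episodes wash it out). Second, the
deterministic closed loop at these gains drives a 120° heading error
below 0.2° within 10 steps, and the tests verify the step dynamics
against an independently iterated scalar recursion.

At these defaults (n = 1000, several seeds): single-channel means
≈ 10.0 / 8.7 / 8.0 / 11.5 s, both orderings significant at p < 10⁻³
(Mann–Whitney), untrained mean ≈ 51 s, trained-both mean ≈ 6.5 s. The
Far-direction latency distribution is not narrower than Near-direction
here (sds ≈ 8 vs 7 s), although its mean is reliably lower.

## Reliability of latency vs probe occupancy

For a trained equal-cue cohort the package contrasts the across-rat CV
of a single post-training escape latency (start drawn from the
acquisition start set) with the CV of probe time-in-platform-area
(60 s, SW release, 20 cm scoring circle). At the defaults CV(latency)
≈ 0.45–0.53 and CV(occupancy) ≈ 0.10–0.11, ratio ≈ 4–5: occupancy is
several-fold the more reliable readout, but the contrast is weaker than
the order-of-magnitude sometimes reported. The floor on CV(occupancy)
in this integration is structural: a probe contains ~9 behavioural
cycles, and per-cycle dwell variability divided by √9 leaves ≈ 0.11;
a much larger contrast would require many more within-trial averaging
cycles than the 7-step episode structure admits at these scales. No
parameter was adjusted toward this target after measurement.

## What the simulations do and do not show

All inputs are synthetic by construction (the package ships no data);
the generator defaults *are* the study conditions: arena and protocol
above, salience splits 0.5/0.5 (equal), 0.3/0.7 and 0.83/0.17
(unequal), 1/0 (dominant), the (0.2, 0.8) + 50 % misinterpretation
uncertainty model, and cohort sizes of 50 (group comparisons) to 1000
(latency distributions). Passing tests show that the *model* reproduces
the qualitative phenomenology — acquisition curves, overshadowing,
generalization to the salient cue, bimodal search with ambiguous cues,
concentration of search with salience — under these conditions. They
do not validate the model against real trajectories: real rats show
thigmotaxis, speed modulation with learning, wall-distance knowledge
and inter-individual parameter variability, none of which are modelled;
the wall-clamped swimmer produces a thigmotaxis-like artifact only as a
side effect of chasing out-of-pool estimates.

## Numerical and degenerate-case choices

Angle wrapping to (−180°, 180°] throughout; quadrant ties broken by
half-open sectors; the pool centre classifies as NE. Zero-salience cues
never learn; an all-zero V_use cohort never engages a cue (pure random
search) and pooled guess sampling then raises rather than inventing a
mixture. Censored trials contribute the full trial duration to latency
summaries and are flagged; occupancy uses step midpoints weighted by
Δt, unbiased for piecewise-linear paths. Every cohort derives per-rat
generators from (master seed, rat index), so any rat's result is
bit-reproducible and independent of cohort size or execution order.

## Known limitations

* The absolute latency scale depends on the calibrated step scale and
  gains; only the regime, not the kinematics, is meaningful.
* The latency-vs-occupancy reliability contrast saturates near 5× (see
  above).
* One-cue-at-a-time inference: the two landmarks are never fused into a
  joint estimate.
* No learning during probes (evaluation only), no configural compound
  learning, no pool-wall cue, no more-than-two-cue scenario scripts
  (the data model supports n cues; the scenario battery scripts two).
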