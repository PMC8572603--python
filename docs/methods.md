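# Methods

## Model structure and assumptions

The simulator composes three layers, evaluated sample by sample along a
uniformly sampled joint-angle trajectory:

1. **Path geometry.** Motion is planar (sagittal `xOz` plane); the
   elbow is treated as an ideal hinge at the frame origin, with x
   anterior, z superior, and the forearm along −z at full extension.
   Flexor paths are straight origin→insertion lines whose insertion
   rotates with the forearm; biarticular flexors carry a fixed
   shoulder-side segment `l_0` (the shoulder is assumed stationary).
   The triceps heads share a single olecranon tendon wrapping the
   humeral trochlea, modelled without explicit arc geometry: the
   common moment arm shrinks linearly with flexion,
   `r(θ) = r_0 − k_s·θ/90`, and the path lengthens by the wrapped arc
   `θ_rad · r(θ)`. Brachioradialis and anconeus are excluded (small
   torque contributions); so are out-of-plane and shoulder effects.
2. **Tendon.** Tendon compliance is collapsed to a fixed stretch: the
   tendon is always 1.02× its resting length, so fiber length is the
   path length minus that constant. This removes the tendon-equilibrium
   iteration of compliant-tendon models at the cost of ignoring tendon
   dynamics — acceptable at elbow movement speeds.
3. **Hill fiber model.** Active force–length is a Gaussian of width
   `γ` in normalized fiber length; force–velocity is hyperbolic in the
   shortening range (zero at the normalized shortening speed −1,
   velocities beyond it clamped to zero force rather than made
   negative) and saturates at `f_M` while lengthening; passive force is
   zero at or below optimal length and exponential above it, reaching 1
   at strain `ε₀`. Pennation follows the constant-thickness relation
   `l_m sin φ = l_mopt sin φ₀`; only the `cos φ` component transmits
   force. The viscous damping element is negligible at these speeds and
   is omitted. Fiber velocity is obtained numerically from the fiber
   length series (central differences interior, one-sided ends),
   normalized by `v_max = 8·l_mopt` per second.

Torques are assembled as moment arm × force with flexion positive;
muscle forces themselves are kept nonnegative and the extensor sign is
applied at assembly. The resultant is a plain sum, so it is linear in
each muscle's `F_0` and additive over muscles — both used as test
invariants, along with the virtual-work identity
`|d l_mt / dθ| = r` that ties the straight-line moment arm to the
path-length derivative.

## Parameters

Shared curve constants (defaults): `γ = 0.5`, `A_s = 0.25`,
`f_M = 1.8`, `v_max = 8·l_mopt` s⁻¹, `k_PE = 4`, `ε₀ = 0.5`,
`k_s = 0.004` m per 90°, tendon stretch 1.02. Per-muscle constants
(optimal fiber length, resting tendon length, maximum isometric force,
rest pennation, flexor path points and `l_0`) are the published values
for a reference subject, shipped in `data/arm_default.yaml`; other
subjects can be approximated by a single uniform length scale
(`ArmModel.scaled`), which scales every length and coordinate but not
`F_0`, since strength does not scale geometrically.

Two values have no published source and are explicit package choices:

* `A` (EMG→activation nonlinearity): −1.0, mid-range of the [−3, 0)
  interval used in EMG-driven modelling. The study workflow feeds
  solver-computed activations directly, bypassing this map, but it is
  exposed for genuine EMG inputs.
* `r_0` (triceps moment arm at full extension): 0.022 m in the shipped
  fixture, within the range reported for the elbow extensors, and
  labelled a fixture choice in the parameter file. It is a required
  field with no silent default.

The two-muscle baseline (`data/arm_baseline.yaml`) lumps the biceps
heads onto the long-head path and the triceps heads onto a straight
posterior line — the classic model's known anatomical shortcut — with
summed maximal forces; its lumped fiber is placed at optimal length at
full extension. All lumping values are fixture choices, marked as such.

## Numerical and design choices

* **Extensor path baseline.** The musculotendon length of an arc-path
  muscle at full extension is `l_mopt + 1.02·l_topt`, so the fiber sits
  exactly at optimal length at 0° and stretches during flexion —
  producing the passive triceps force near 90° that the flexion
  narrative requires. The alternative reading (baseline `l_mopt`
  alone, tendon subtracted afterwards) is retained behind
  `ModelOptions(extensor_base="literal")` for audit, but it yields a
  negative fiber length for the triceps long head
  (0.134 − 1.02·0.143 < 0) and cannot run with the shipped constants.
* **Arc term units.** The wrapped arc is `θ_rad·r = θ·π·r/180`;
  `literal_eq15: true` switches to the π-less degree form for
  comparison with formulations that leave degrees unconverted.
* **Moment-arm slope form.** The flexor moment arm uses the
  slope-intercept point–line distance; vertical lines (equal x) fall
  back to the exact distance `|x₁|`. Tests check it against the
  cross-product distance everywhere.
* **Velocity sign.** Shortening is `v_n < 0`, forced by the
  force–velocity curve vanishing at the concentric limit −1.
* **Trajectory sampling.** Default Δt = 0.01 s over 2 s (201 samples),
  which puts the two-group ANOVA at df = (1, 400) and the critical
  value 3.865 at α = 0.05.
* **Degenerate inputs.** Coincident path points, infeasible postures
  (non-positive fiber length) and fiber lengths below the pennation
  sheet width raise named errors identifying the muscle and angle
  rather than propagating NaNs.

## Synthetic inputs

The generator stands in for motion-tracking solver exports. The
planned trajectory is `θ = 45 + 45·sin(πt − π/2)` degrees (0→90→0 in
2 s). Activations are Gaussian bumps per muscle on a 0.02 floor
(solvers keep activations slightly above zero): flexors peak during the
lift (0.5–0.8 s, peaks 0.35–0.55), triceps bumps are small (≤ 0.15)
and centred at peak flexion, where they stabilise the joint. Optional
seeded Gaussian noise is clipped back to [0.02, 1].

These traces reproduce the *shape constraints* of solver output —
bounds, floor, smoothness, timing — but not its dynamics: real
computed-muscle-control activations solve a tracking problem coupled to
limb inertia and gravity, co-vary across muscles, and fluctuate before
movement end. Passing tests therefore validate the mechanics pipeline
and the statistics protocol, not agreement with any particular solver's
output; published agreement values against such output depend on
unpublished activation exports and are not recomputable here. A
`.sto`/`.mot` reader lets genuine exports replace the generator without
code changes.

## Agreement statistics

Two series are compared by Pearson correlation, banded at the
conventional |r| ≥ 0.8 threshold for "extremely strong correlation"
(the protocol's only used label; every reported value exceeds 0.94, so
any standard banding reproduces the labels), and by one-way ANOVA
treating the two series as independent groups, verdict "no significant
difference" when F < F_crit(α). Treating autocorrelated time series as
independent samples inflates the effective degrees of freedom; the
protocol is reproduced as published and every report carries that
caveat. The ANOVA is cross-checked in tests against the two-group
F = t² identity and an independent permutation null.

## Known limitations

Planar, single-hinge elbow; stationary shoulder (biarticular lengths
held fixed on the shoulder side); rigid-scaled tendon; no activation
dynamics (first-order excitation→activation filtering); no
inverse/forward dynamics of the forearm (gravity and inertia enter only
through whatever activations the user supplies); no parameter
calibration. The problem size throughout (201 samples, 6 muscles) is
the study task itself; all suites run in seconds.
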