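# Methods

## The model

`crowdcontacts` estimates age-structured social contact matrices by
simulating pedestrian crowds instead of collecting contact diaries.  Each
agent *i* is a disk of radius *r_i* obeying Newtonian dynamics

    m_i dv_i/dt = f_self + f_soc + f_obs

with three force terms:

* **Self-driven force** `f_self = m_i (v_d,i e_d,i − v_i) / τ_i`: the agent
  relaxes to its desired speed *v_d,i* along its desired direction with
  time constant τ.
* **Social repulsion**, summed over all neighbours *j* closer than the
  agent's desired interpersonal distance *d_soc,i*:

      f_ij = A_soc · exp((d_ij − d_soc,i)/β_soc)
             · (γ + (1 − γ)(1 + cos φ_ij)/2) · e_ij,   d_ij < d_soc,i

  and exactly zero outside that support.  `e_ij` points from *j* to *i*
  (repulsion), `φ_ij` is the angle between *i*'s desired direction and the
  direction from *i* to *j*, so agents react with full strength to people
  ahead of them and with the reduced weight γ to people behind.  Note the
  unusual profile: the force takes its *maximum* `A_soc` at the
  desired-distance shell and decays with depth of intrusion — the shell
  acts as a finite barrier of height ≈ `A_soc`, not a diverging core.
* **Wall repulsion** of the same exponential form with amplitude `A_obs`,
  fall-off `β_obs` and cutoff `d_obs`, from the four boundaries of a
  square 50 m × 50 m domain with no interior obstacles.

Crowds are heterogeneous: 16 five-year age bins ("0–5" … "over 75") with
per-bin Gaussian desired speeds and desired distances.  The distance
distributions live inside one of the Hall proxemic zones per activity
area — intimate (0–0.46 m) in households, personal (0.46–1.22 m) in
schools and workplaces, social (1.22–2.10 m) in shopping centres and
other public spaces.  Truncation is by rejection sampling, which keeps
the Gaussian shape near the mean rather than piling mass at the bounds.

Movement is purposeless wandering: agents start at rest at uniformly
random non-overlapping positions with uniformly random desired
directions; every 10 s a random 30 % of the crowd redraws its desired
direction uniformly on the circle; an agent reaching a boundary has its
desired direction and normal velocity reflected inward.

## Contacts and matrices

A **contact** is a sustained proximity event: two agents whose centre
distance stays below 1.8 m for 30 consecutive seconds (a safety-distance
and inhaled-dose argument for respiratory infection).  The dwell
accumulator resets when a pair separates beyond the radius; once a pair
has registered a contact it is never counted again.  Both choices are
configuration switches (`cumulative`, `unique_pairs`) for pathogens with
different exposure profiles.

Registered pairs aggregate into the symmetric count matrix `C_ij` over
age bins; `m_ij = C_ij / n_i` is the per-capita matrix, which satisfies
the reciprocity identity `C_ij = m_ij n_i = m_ji n_j` exactly — a
same-bin pair increments the diagonal by 2 (each participant reports one
contact), which is what makes the identity hold at i = j.  Short
simulated windows are extrapolated linearly to the activity duration
(8 h work/school, 5 h household, 11 h shopping, 16 h other) and flagged
as extrapolated.  Assortativity is summarized by `Q = (Tr(P) − 1)/(n − 1)`
for the row-normalized mixing matrix `P`: 0 is proportionate mixing, 1
fully within-group mixing; rows with no contacts contribute nothing to
the trace.

## Parameters

| Parameter | Default | Units | Notes |
|---|---|---|---|
| domain side | 50 | m | square, four walls, no obstacles |
| n agents | 300 | — | same density in every activity area |
| dt | 0.02 | s | see *Numerical choices* |
| τ | 0.5 | s | standard social-force calibration |
| r | 0.2 | m | body disk radius; rendering/placement only |
| A_soc | 700 | N | repulsion barrier height; swept 700–3000 in sensitivity runs |
| β_soc | 0.08 | m | fall-off of the repulsion inside the shell |
| γ | 0.2 | — | weight of interactions behind the back |
| A_obs, β_obs, d_obs | 2000, 0.08, 0.5 | N, m, m | wall force |
| contact radius | 1.8 | m | safety distance |
| dwell | 30 | s | exposure time |
| reroute | 30 % every 10 s | — | direction refresh |
| mass | N(70, 12²) on [30, 130] | kg | area-level, age-independent |

The force constants that are not age-dependent (τ, β_soc, γ, the wall
force) were fixed once from standard social-force calibrations before
any sensitivity run and are exposed in the configuration schema.

## The fixture configurations are synthetic

`fixture_location_configs()` provides five self-consistent activity-area
parameterizations (demographic weights per area, age curves of desired
speed with an area-level factor, distance Gaussians centred inside the
area's proxemic zone with a mild age trend).  They honour every
constraint stated above but are **not** a published calibration table:
the demographic weights are a plausible young-skewed national pyramid,
and the per-age speed/distance tables are built from literature-shaped
age curves.  A green scenario test therefore establishes the *mechanism*
(e.g. distancing collapses contacts; panic raises contacts exactly where
baseline distances are personal) — not any specific published percentage.
Real calibrations can be supplied as YAML (`crowdcontacts.config`).

## Numerical choices

* **Integrator** — semi-implicit (symplectic) Euler: velocity first from
  the summed forces, then position from the new velocity, then the
  boundary rule, so no agent ends a step outside the domain.
* **Time step** — the repulsion jumps discontinuously to `A_soc` at the
  `d_soc` shell and *decays* inward, so the shell-crossing timescale is
  `β_soc / v ≈ 0.03 s`.  At dt = 0.05 s agents tunnel through the shell
  and the velocity-sweep threshold is badly wrong (it even moves the
  wrong way as `A_soc` grows).  A convergence study of the threshold
  velocity fixed the default at **dt = 0.02 s**, whose sweep argmax
  agrees with dt = 0.01 s for amplitudes up to 1700 N; for
  `A_soc = 3000 N` use dt ≤ 0.01 s.  The contact *level* (not location of
  the peak) still drifts a few percent between 0.02 and 0.01 — thresholds
  and scenario ratios are the quantities this package reports.
* **Dwell bookkeeping** — one observation per step on the pre-step
  positions (the configuration the step's forces see); an observation
  adds dt to the pair's accumulator, and a pair registers at the
  observation where the accumulator reaches the dwell time (a 1 ns
  epsilon guards float accumulation at the threshold).
* **Neighbour search** — the compiled engine uses a linked-cell grid with
  cell size equal to the largest interaction cutoff; a single-cell grid
  degrades gracefully to the brute-force pair loop.  The vectorized
  numpy reference path computes all pairs; both paths consume identical
  pre-drawn random streams and agree bitwise over short horizons.  The
  dynamics are chaotic (neighbouring trajectories separate by roughly a
  factor e per second), so over minutes the two engines — which sum
  forces in different orders — produce statistically, not bitwise,
  identical runs.  A seed fully determines a run *within* an engine.
* **Degenerate overlap** — below 1 µm separation the pair force has
  magnitude `A_soc` along a deterministic pseudo-random direction keyed
  on the pair ids: finite, reproducible, and symmetric on average.
* **Reroute count** — round(0.3 n) to the nearest integer, half-ties up
  (exactly 90 of 300).
* **Ties in the threshold** — `find_threshold_velocity` returns the
  smallest grid value attaining the maximum and warns when the maximum
  sits on the grid boundary; thresholds are resolved only to the grid
  spacing (5/12 m/s on the default grids).

## Design choices on open points

* `e_ij` orientation is from *j* to *i* (the law is repulsive); the
  angular factor uses the direction from *i* to *j*.  Both are regression
  tested.
* `d_ij` is centre-to-centre, both in the force law and in the contact
  definition; radii only affect initial placement (minimum separation
  2r) and rendering.
* Sweeps use fully homogeneous crowds (every agent shares the swept value
  and all non-swept parameters, mass 70 kg, τ 0.5 s), since the swept
  quantity is meant to be isolated.
* Scenario runs reuse the baseline's sampled populations and simulation
  random streams (common random numbers), so scenario-minus-baseline
  differences are pure treatment effects.  Distancing replaces every
  desired distance by 2 m (warning when that leaves the area's proxemic
  zone — the counterfactual wins); panic replaces every desired speed by
  2.5 m/s and multiplies `A_soc` by 0.5 (the weakening factor is not
  pinned by any source; it is exposed in the configuration and manifest).
* Because a panic "decrease" can be negative, scenario reports emit both
  encodings side by side: `decrease = 1 − s/b` and `increase = s/b − 1`.
* Per-bin reductions use the row sum of the per-capita matrix as the
  bin's contact rate.

## What the scenario tests actually show

Two emergent behaviors of the bundled fixture world are worth knowing
before interpreting scenario output:

* **Wall pinning under distancing.**  With every desired distance forced
  to 2 m (above the 1.8 m contact radius), interior contacts collapse as
  expected, but a residual of wall contacts survives: the wall force has
  the same inward-decaying profile as the social force (maximum `A_obs`
  at the `d_obs` cutoff, almost nothing at the wall itself), so crowd
  pressure can push agents onto the boundary, where the position clamp
  holds them and nearby pairs dwell below 1.8 m indefinitely.  In the
  fixture configurations this caps the overall distancing reduction near
  60 % (84 % in households, ~32 % in the social-zone areas) instead of
  the near-total suppression the interior dynamics alone would give.
* **Panic signs follow the threshold velocity.**  Whether panic
  (homogeneous 2.5 m/s, halved repulsion) raises or lowers an area's
  contacts depends on whether 2.5 m/s lies on the rising or falling side
  of that area's contacts-vs-speed curve.  With the fixture constants the
  intimate-distance threshold sits at ≈ 2.58 m/s — just above 2.5 — so
  panic increases contacts in *every* area.  A calibration whose
  intimate-distance threshold falls below 2.5 m/s (one grid step away)
  flips the household/shopping/other signs to decreases.  The sign
  pattern is therefore a statement about the calibration tables, not a
  structural property of the model.

## Known limitations

* The fixture parameter tables are stand-ins (above); absolute contact
  counts and percentages depend on them and on the linear duration
  extrapolation, which ignores saturation of the unique-pair rule over
  hours.
* No interior obstacles, exits, goal-directed navigation or granular
  body-contact forces; panic here is only "faster and less repulsed",
  not evacuation phenomenology.
* The contact level at fixed dt is not fully converged (a few percent
  between dt = 0.02 and 0.01); comparisons should hold dt fixed, as the
  scenario engine does.
* Demographic sampling treats gender only through the per-age-bin
  Gaussians; no separate gender-specific distributions are bundled.
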