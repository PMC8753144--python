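# Methods

## Physical model

A test particle is a rigid disc of radius r, thickness h, bulk density
ρp = m/(π r² h), always broadside to a purely vertical wind. Two forces act:
weight, and the momentum flux of the relative flow on the disc face. With a
drag coefficient fixed at unity (full stagnation of the incident flow) the
wind force is sgn(w − v) ρ π r² (w − v)², so the equation of motion is

    dv/dt = −g + sgn(w − v) λ (w − v)²,   λ = ρ(z)/(ρp h).

The sign factor keeps the force aligned with the relative wind; its value at
exactly zero relative wind is set to +1, which is immaterial because the
force vanishes quadratically there. Air resistance against the particle's
own motion beyond the relative-wind term is neglected: the particle is
treated as riding a directed flow, not falling through still air.

This is a continuum description applied at Knudsen numbers far above 1
(Kn ≈ 2.4×10⁴ for a micron disc at 90 km). The justification is that the
observed winds are long-lived directed streams: the bulk momentum flux is
the zeroth-order force, and kinetic (Brownian) fluctuations, which would
require a 3D stochastic treatment, are deliberately out of scope, as are
horizontal dynamics, particle charging, photophoresis and ice microphysics.

Key derived quantities, all closed-form:

- threshold velocity w_th = √(g ρp h / ρ): the minimum updraft supporting
  the weight; identically the terminal fall speed relative to the air.
  Depends on the particle only through the column density ρp·h.
- steady-state velocity v_ss = w − w_th (signed; negative values are
  quasi-steady descent at terminal speed relative to the wind).
- relaxation time τ = 1/√(λ g): e-folding scale of the approach to steady
  state. Sub-second to a few seconds for all particles and altitudes of
  interest, versus minutes-to-hours wind variation — the separation of
  timescales behind the quasi-steady mode.
- transient from rest, for w > w_th: with u* = w_th and
  E = exp(−2 t √(λ g)),

      v(t) = w − u* · [(w + u*) + (w − u*)E] / [(w + u*) − (w − u*)E].

  v(0) = 0 and v → w − u* as t → ∞; v approaches but never reaches w. The
  closed form is verified against an independent fourth-order RK
  integration of the ODE on randomized cases to 10⁻⁶ relative error in the
  test suite; outside its domain of validity (w ≤ w_th) it raises rather
  than extrapolating.

## Atmosphere

The embedded profile is the US Standard Atmosphere 1976 on a geometric
altitude grid: 2 km steps to 70 km and 1 km steps from 70 to 200 km, so the
worked-example altitudes (90, 100 km) are exact nodes. Below 86 km the
values come from the analytic seven-layer barometric formula; above 86 km,
from published USSA 1976 anchor values (density, kinetic temperature, mean
molecular weight) densified to 1 km with the same log-linear density rule
the interpolator uses, so tabulation and interpolation agree by
construction. The mean free path column follows the USSA definition
λ_mfp = 1/(√2 π σ² n) with σ = 3.65×10⁻¹⁰ m and n = ρ N_A / M.

Interpolation is log-linear in density and mean free path (both span many
decades and decay near-exponentially; log-linearity preserves positivity
and is exact at nodes) and linear in temperature. Altitudes outside the
tabulated span raise a range error naming the span — the model makes no
claims beyond its table.

Gravity defaults to inverse-square, g(z) = g₀ (R/(R+z))² with
g₀ = 9.80665 m s⁻² and R = 6371 km; this choice reproduces the classic
desk estimates at 100–115 km (constant g₀ misses them by ~1 m s⁻¹ in the
steady-state velocities and is available as a config switch). Any table
with the same columns, or any callable returning (ρ, T, λ_mfp), can replace
the embedded profile; an NRLMSISE-00-style empirical backend plugs in
through `AtmosphereProfile.from_backend` without changes downstream. Note
that empirical thermospheric densities run somewhat below USSA 1976: the
virus-sized disc's 50 m s⁻¹ ceiling is ≈111 km on the embedded table,
versus the ≈115–120 km such a particle reaches under empirical-model
densities.

## Particle presets

- `standard_dust`: ρp = 1000 kg m⁻³, r = h = 1 nm, m = π×10⁻²⁴ ≈ 3×10⁻²⁴ kg.
- `h1n1_virus`: defined by the H1N1 virion mass 0.8 fg and size 109 nm,
  with **both** the disc radius and thickness set to 109 nm. That
  convention is what yields the quoted bulk density ≈196 kg m⁻³ from the
  mass, and the preset keeps it deliberately (a geometric quirk, since a
  109 nm "diameter" might suggest r = 54.5 nm; the quoted density fixes
  the convention).
- `bacterial_organelle`: ρp = 2000 kg m⁻³, r = 2 µm, h = 40 nm,
  m ≈ 10⁻¹⁵ kg.

Constructors accept any three of (m, r, h, ρp); the stored quadruple is
validated to 10⁻¹² relative tolerance.

## Trajectory integration

Within each step (default dt = 1 s) the density, gravity and wind are
frozen; density is re-read from the profile at the start of every step, so
multi-kilometre climbs see the exponential fall-off. Quasi-steady mode sets
v to the local steady state each step (valid when episode durations ≫ τ;
the suite checks 1% final-altitude agreement with the full ODE in that
regime). Full-ODE mode integrates the equation of motion with classical
RK4 at internal sub-steps of at most 0.05 τ (capped at 2000 per step),
which resolves the transient stiffly enough that halving dt moves final
altitudes by < 0.1% on the worked scenarios. Per-episode constant-density
overrides support estimates made at an assumed frozen density. Crossing the
table floor or ceiling truncates the trajectory at the boundary and records
the reason in the metadata rather than raising or extrapolating.

The ceiling solver searches the monotone segment above 70 km (below the
mesopause the threshold-vs-altitude relation need not be monotone),
brackets the root of w_th(z) = w on the table grid and refines with Brent's
method to 1 m. Sub-threshold winds over the whole searched span return an
explicit no-ascent result; winds exceeding the threshold even at the table
top return the table top flagged as a lower bound.

Horizontal excursion is the elementary u·t drift compared against a
configurable correlation length (default 300 km, the maximum horizontal
coherence observed for arc-aligned vertical winds); the boundary counts as
within. The 8.4 km / 20 min climb estimate is reproduced via a stated mean
ascent speed (7 m s⁻¹, a heuristic halving of the 13 m s⁻¹ peak over the
wind's growth period) rather than an assumed wind ramp, since no ramp shape
is specified by the observations.

## Synthetic winds

The generator emulates the oscillatory structure of observed series:
w(t) = mean_offset + amplitude·sin(2πt/period) + N(0, noise_sd), seeded
(numpy `default_rng`) and bit-reproducible for a fixed seed. Defaults —
amplitude 30 m s⁻¹ about a 10 m s⁻¹ upward offset, 25-minute period,
5 m s⁻¹ noise, 10 s sampling for one hour — put peaks near 40–50 m s⁻¹,
troughs downward, and growth-to-maximum in ~20–30 min, matching the
reported ranges. What it does not emulate: altitude dependence,
non-stationarity, intermittency and multi-scale spectra of real winds, or
correlated measurement error. Tests passing on synthetic series therefore
demonstrate the transport machinery, not skill against real observations;
real series enter through the same CSV path. A series is segmented into
episodes as maximal runs at/above a threshold, each carrying the run-mean
wind — conservative relative to the run maximum — with durations of one
sample interval per sample so episode durations sum exactly to the series
duration.

## Numerical choices and edge cases

- Log-linear interpolation makes the density at a node exact and at a
  midpoint the geometric mean of the node values.
- The transient solution is evaluated in a form whose t = 0 cancellation is
  exact to rounding; tests use 10⁻⁹ absolute tolerance there.
- Quasi-steady rows record the (z, v, w, ρ) triple actually used for that
  step, so each row satisfies v = v_ss(ρ, g(z), w) to 10⁻⁹.
- Episode/series forcing with zero remaining time is guarded by a relative
  10⁻¹² cutoff to avoid spurious zero-length steps.
- Scenario configs are validated (pydantic) before any computation;
  synthetic winds require an explicit seed; CLI errors are single-line on
  stderr with exit code 1, while boundary truncation is reported in the
  summary, not as a failure.

## Problem sizes

All worked estimates are desk-scale (single closed-form evaluations or
≤ 3600 integration steps); the randomized oracle suite uses 100 cases ×
3 evaluation times with a 4000-step RK4 reference, and the full test suite
runs in a few seconds on one CPU.

## Known limitations

One-dimensional by design: no horizontal advection of the particle between
wind regions (the random-walk picture of alternating up/down exposure is
explicitly future work), no Brownian/kinetic fluctuations, no lift or
shape-dependent drag (Cd ≡ 1, broadside orientation assumed stable), no
charging, hygroscopic growth or ice nucleation, and a static atmosphere
with no latitude, season or solar-activity dependence. Results above ~150 km
lean on the least certain part of the standard-atmosphere table and on the
directed-flow continuum approximation at extreme Knudsen number, and should
be read as order-of-magnitude.
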