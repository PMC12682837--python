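# Methods

## Scope and model overview

`rhizoconduct` simulates young maize (B73) plants as rooted trees of
cylindrical segments and computes the root-system conductance
K_rs of the growing plant per soil-phosphorus treatment.  The model chain
is: per-treatment architecture parameter tables → stochastic plant
construction → age/type-dependent segment hydraulic properties →
steady-state xylem flow → K_rs, SUF and per-segment flows.  Everything runs
from packaged plain-text inputs; a synthetic-data module generates
ground-truth inputs for validation.

## Organ growth

Every organ (root or leaf) elongates along the negative-exponential law

    l(t) = l_max · (1 − exp(−r t / l_max)),

with initial elongation rate `r` (cm/d, the derivative at emergence) and
asymptotic maximal length `l_max` (cm).  The closed-form inverse
`age(l) = −(l_max/r)·ln(1 − l/l_max)` dates every point along an organ and
converts distance-based hydraulic profiles to age-based ones.

Axial roots (primary, seminal, crown) use a fixed `l_max` of 139 cm taken
from the literature; lateral maxima come from the measured tables.  Rate
fitting holds `l_max` fixed and minimizes the residual sum of squares over
`r ∈ (0, 50]` by bounded scalar minimization (tolerance 1e-12 on `r`); the
one-parameter problem is convex in practice and the bound prevents runaway
on degenerate series.  For leaves, trailing observations are discarded once
the finite-difference daily increment falls below 20 % of the maximum
observed increment — an operationalization of "before the phase of declining
daily elongation"; the stated rule is qualitative, the 20 % threshold is
this package's choice.

## Plant construction

**Timing is analytic, not stepped.**  Because each organ's extension is a
deterministic function of its realized `(r, l_max)`, node creation times are
computed exactly with the inverse growth law rather than by dt-stepping;
`simulate_plant` accepts a `dt` argument for API compatibility but results
do not depend on it.  A segment's age at query time `t` is
`t − creation_time`, and restricting the network to `creation_time ≤ t`
reproduces the plant at any earlier day exactly.

**Emergence schedule.**  The primary root emerges at sowing.  Seminals start
at `first_B` and appear every `delay_B` days up to a realized `max_B`; crown
whorls appear at `first_SB + k·delay_RC` with a realized `n_C` roots each,
spaced `delay_SB` within the whorl.  Fractional counts (e.g. `max_B = 3.5`)
are realized by Bernoulli rounding (3 or 4 with p = 0.5), preserving the
printed mean.

**Stochastic parameters.**  Each numeric organ parameter is drawn per organ
from normal(mean, s.d.), truncated below at 1e-4 of the mean so radii and
lengths stay positive.  At mean/s.d. ratios typical of the tables
(radius ≈ 4.5 s.d. from zero) the truncation bias is far below one standard
error of the mean and is verified to be negligible in the test suite.  All
draws flow through a single `numpy.random.Generator`; identical seeds give
bit-identical plants.

**Branching.**  Laterals occupy an axial root between the basal zone `l_b`
and the apical zone, spaced by fresh draws of the inter-branch distance
`l_n`.  `l_delay` is interpreted as the apical unbranched-zone *length*
(cm): a branch site at arc length `s` produces its lateral when the parent
axis reaches `s + l_delay`.  (The parameter catalogue prints cm/d for this
entry, but the printed magnitudes, 0.19–2.6, only read sensibly as
centimetres; this interpretation is recorded as an assumption.)  Lateral
type is sampled from the measured successor probabilities (l-lateral vs
s-lateral on axial roots); l-laterals bear s-laterals, s-laterals are
unbranched.

**Geometry.**  Headings start at the insertion angle θ (drawn per organ)
about the parent's local direction with uniform azimuth, then follow a
gravitropism-biased random walk: per dx step, N candidate headings are drawn
(Gaussian deflection, s.d. 0.2 rad per cm of growth) and the most downward
is kept.  N defaults to 1.5 for axial roots and 1 for laterals; the tables
print no tropism values, so these are documented package defaults, as are
the axial insertion angles (primary 0, seminal 1.0, crown 1.2 rad from
vertical — θ is only printed for laterals).  The maximal segment length dx
defaults to 0.25 cm, which resolves the radial-conductance integration
without excessive segment counts.

**Shoot.**  The below-ground stem (mesocotyl) connects the seed at
[0, 0, −3] cm to the collar at the soil surface; crown whorls attach to it
at a vertical spacing equal to the stem inter-node distance `l_n` (the
dedicated crown-spacing parameter has no printed value).  Above-ground, the
stem grows linearly at its measured rate (no maximal stem length is
printed) and leaves appear every `delay_lat` days, growing by the same
negative-exponential law with area `min(l·Width_Blade, Area_max)`.  Leaves
and the above-ground stem carry no hydraulic segments: only the collar
boundary and the below-ground path matter for K_rs.  Note: the printed stem
`l_n` for P1 (0.153 cm) is an order of magnitude below the other treatments
(≈1.5–1.7 cm); it is used as printed.

## Hydraulics

Potentials are water heads (cm).  Per root segment,

    Kr = 2π a dl k_r(age, type)        (radial, cm²/d)
    Kx = K_x(age, type)                (axial, cm³/d)

with k_r and K_x piecewise-linear in age between knots and constant beyond
the last knot, identical across P treatments (treatment differences enter
only through architecture, including radii).  Stem segments: k_r = 0 and
Hagen–Poiseuille axial conductance K_x = π a_xyl⁴/(8 μ) with the head-based
viscosity constant μ = η/(ρg) = 1.002e-3 Pa·s / 9810 N·m⁻³ ≈ 1.18e-10 cm·d
(water at 20 °C).  The equivalent stem xylem radius defaults to 0.1 × the
stem radius; the test suite verifies that halving or doubling this fraction
moves whole-plant K_rs by less than 1 % — the stem is never the limiting
resistance.

**Discretization and solver.**  Potentials live at segment end nodes.  The
axial law is discretized per segment as `Jx = Kx (ψ_dist − ψ_prox)/dl`; the
radial exchange uses the segment midpoint potential (mean of the end nodes)
with the inflow split half to each end node.  This is second-order accurate
and converges to the single-root closed form
`K_rs = √(2πa·k_r·K_x)·tanh(L√(2πa·k_r/K_x))` (verified to 0.1 % at
dx = 0.1 cm).  Mass balance at every node yields one sparse symmetric
positive-definite system solved by direct sparse factorization; an
independently assembled dense oracle agrees to 1e-8 relative on random trees
up to 200 segments.  A branch-by-branch analytic elimination would give the
identical solution; the sparse assembly was chosen for its simpler
correctness argument.

**K_rs and SUF.**  With uniform soil potential, SUF_i = Jr_i / T_act (sums
to 1, non-negative) and K_rs = T_act/(ψ_sr − ψ_collar).  For non-uniform
soil, ψ_sr,eff = SUFᵀψ_sr with SUF from a uniform-soil solve.  By linearity
K_rs is invariant to the boundary potentials; defaults (ψ_sr = −300 cm,
ψ_collar = −15000 cm) are arbitrary and documented as such.  A system where
every radial conductance is zero is rejected as degenerate.

## Packaged hydraulic profile (synthetic stand-in)

The packaged `hydraulic_profiles_synthetic.csv` is **not** measured data: it
is a synthetic stand-in with literature-shaped curves — radial conductivity
decreasing with segment age (suberization), axial conductance increasing
(xylem maturation), crown roots with higher proximal axial conductance than
other axial types, laterals with higher k_r and much lower K_x.  Magnitudes
were scaled once, jointly across all knots, so that a simulated 28-day
high-P plant's K_rs falls inside the published young-maize range
[7.0e-5, 2.37e-2] cm²/d.  Conclusions that depend on the *absolute* K_rs
level therefore inherit this calibration; treatment *contrasts* (orderings,
time courses) are driven by the measured architecture tables and are
insensitive to a joint rescaling, which by linearity multiplies every K_rs
equally.

## P-response functions

Three responses convert soil P (mg P per 100 g soil) into architecture:

* axial radius: `a_ax(P) = α_a P + a_P0`, ordinary least squares on the
  per-treatment means with the three axial types pooled (the analysis treats
  "axial root radii" as one response); per-type offsets are preserved by
  scaling each type's mean by the fitted line's ratio at `P` versus the
  anchor `P_ref` (the mean observed P, where the pooled line passes through
  the base set's pooled mean).  Valid only on the observed window
  [P_min, P_max] = [1.8, 7.7]; no extrapolation.
* crown elongation: `r_c = α_rc · min(PB, PB_max)` with `PB = P/DM_plant`.
  The slope is fitted through the origin with the changepoint profiled over
  observed PB values (closed-form slope per candidate, best RSS wins,
  smaller cap on ties).  When all observations sit below the best cap the
  cap is flagged unidentifiable and defaults to the maximum observed PB.
* leaf elongation: `r_l(P) = α_rl P + r_P0`, OLS, same validity window.

**Dry matter.**  PB needs whole-plant dry matter, which is not part of the
packaged tables; `dry_matter_synthetic.csv` provides clearly-labelled
synthetic stand-in values (0.8–2.6 g across treatments) and `DM_plant`
remains a user input everywhere.  Response-driven parameter sets built on
this stand-in reproduce the qualitative treatment contrasts (volumes
strictly increasing in P) but differ from the tabulated sets by up to
≈25 % in ensemble mean volume at the intermediate P level — the crown
response at synthetic PB values overshoots the (non-monotone) printed
crown-rate means.  With measured dry matter the agreement is expected to
tighten; this is a known limitation, surfaced by the acceptance suite.

## Synthetic data generators

The generators emulate: per-root rhizotron length series (growth law plus
Gaussian tracing noise, s.d. 0.5 cm, clipped non-decreasing), RSML time
series of a simulated plant projected to the rhizotron plane (y written as
zero; primary root always listed first; stable root ids across days; node
creation times included), age-profile stand-ins (scalable), and
linear/capped-linear response data (5 % relative noise, PB design grid
[1.5, 2.0, 2.5, 3.2] with the default true changepoint on the grid, since
the profiling estimator can only return observed PB values).  They do *not*
emulate: segmentation or tracing errors beyond additive noise, root
occlusion at the rhizotron wall, 2D growth confinement, root decay, or
temperature/water effects on growth.  Passing recovery tests therefore
demonstrates estimator correctness under the stated noise model, not
robustness to real imaging artefacts.

## Numerical choices and degenerate inputs

* dx = 0.25 cm (architecture), 0.1 cm where closed-form comparisons need it.
* Truncated-normal floor: 1e-4 of the parameter mean.
* Elongation fit: bounded Brent, `xatol` 1e-12, bounds (0, 50] cm/d.
* Inverse growth law rejects `l ≥ l_max`; profile conversion names the
  offending entry.  The inverse is ill-conditioned within float epsilon of
  the asymptote; property tests bound ages at 10·l_max/r for this reason.
* Ensembles use seeds `base_seed + index`; replicates are individually
  replayable, and ensemble statistics are independent of seed order.
* Ties in the changepoint profile resolve to the smaller cap (first minimum
  encountered on the sorted candidate grid).

## Problem sizes

Default experiment: 4 treatments × 100 replicates × 28 days (≈7000 segments
per mature plant), K_rs at 7/14/21/28 DAS; about 70 s on one CPU.  The test
suite scales ensembles to 25 replicates for the K_rs levels and 100 for the
volume rank checks.

## Known limitations

* The hydraulic profile is a calibrated synthetic stand-in (above); absolute
  K_rs levels are conditional on it.
* Ensemble mean volume under the *tabulated* parameter sets is not strictly
  monotone in P (the intermediate treatments overlap within a few percent);
  monotonicity holds for the response-driven sets.
* The rhizotron's 2D confinement is not modelled; simulated plants grow in
  3D.
* No root lifetime/decay, carbon costs, soil water flow or perirhizal
  resistance: K_rs is an intrinsic architecture-and-anatomy property, and
  soil potential is an input.
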