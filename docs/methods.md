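# Methods

## The windward-area model

The model idealises a falling winged ovule as a rigid rotor: `n`
identical wings attached radially and symmetrically to the long axis,
autorotating about that axis as the diaspore descends. Dispersal
ability is compared through the windward area the wings present to the
relative airflow, because in the inertia-dominated regime the thrust on
the diaspore is proportional to that area (see below).

**Windward area.** Each wing has maximum windward area `S_wing`
(attained when the wing is perpendicular to the flow). At rotation
angle `θ` the wings sit at azimuths `θ + 2πk/n`, and wing `k`
contributes `S_wing·|sin(azimuth_k)|`. The body shadows the rotor's far
side, so at most two wings are counted: `S(θ)` is `S_wing` times the
sum of the two largest `|sin|` projections (the single projection when
`n = 1`). For `n ≤ 4` this "two-largest-projection" rule collapses to
simple closed forms — `|sin θ|`, `2|sin θ|`, `√3·cos(π/3 − θ)` on the
fundamental domain `[π/6, π/3]`, and `2·max(|sin θ|, |cos θ|)` — and
for larger `n` it is the minimal consistent extrapolation of those
cases. All `n ≥ 5` results are flagged `extrapolated` in the API and
CLI output: no independent closed form constrains them.

**Accumulated area and efficiency.** Over one rotation the rotor
accumulates `D = ∫₀^{2π} S(θ) dθ` (units `S_wing·radian`): 4, 8, 6√3
and 8√2 per unit `S_wing` for one to four wings. The control is the
same diaspore *not* rotating, wings held facing the wind; it presents
one full wing for `n = 1` and two for `n ≥ 2`, i.e. `D_control =
2π·S_wing·min(n, 2)`. This asymmetric control is deliberate: a single
wing cannot present two wings' worth of area, and the convention makes
the one- and two-winged rotating cases land on the same relative
efficiency `Er = D/D_control = 2/π ≈ 63.66 %`. Three wings give
`3√3/2π ≈ 82.70 %`, four `2√2/π ≈ 90.03 %`. `Er` is dimensionless and
independent of `S_wing`; the percent rendering rounds half-up to two
decimals.

**Stability.** The windward *stability* `min S / max S` over one period
is the package's quantitative proxy for steadiness of autorotation: a
rotor whose projected area collapses to zero at edge-on angles (one and
two wings) experiences a strongly pulsating thrust, while three wings
keep `S` within `[1.5, √3]·S_wing` — a ratio of `√3/2 ≈ 0.866`, higher
than four wings' `√2/2 ≈ 0.707`. The ordering `stability(3) >
stability(4) > stability(2) = stability(1) = 0` is the model's
formalisation of the claim that three-winged diaspores spin most
steadily. The distinct qualitative argument about resonance in
even-winged rotors is not modelled; no formula exists for it, and the
stability ratio is the only steadiness metric implemented.

**Angle convention.** `θ` is the angle between the airflow and a
reference wing, in radians, measured in the rotation plane; all inputs
are reduced modulo the fundamental period (π for `n = 1`, `2π/n` for
even `n`, `π/n` for odd `n ≥ 3` — the absolute value halves the naive
rotational period for odd counts). The wing-tip radius `r` is stored on
the rotor for descriptive completeness but enters no formula.

## Numerical choices

* **Quadrature.** `D` by `scipy.integrate.quad` applied piecewise
  between the integrand's kink points (wing-ranking switchovers and
  `|sin|` folds, all at multiples of `π/(2n)`), with `epsabs = epsrel =
  1e-12` on the unit-swing problem. The test suite checks it against
  the closed forms (`n ≤ 4`) and against an independent per-piece
  Gauss–Legendre oracle (`n = 5..8`) at 1e-9 relative tolerance.
* **Stability extrema.** On each smooth piece the projection sum is a
  single sinusoid, so per-piece bounded scalar minimisation
  (`xatol = 1e-10`) plus the kink values locate the global extrema;
  value error is far below the 1e-9 tolerances used in tests.
* **Degenerate angles.** `S` at exact multiples of π evaluates through
  floating-point `sin`, so "zero" minima are zero only to ~1e-16;
  stability comparisons for one and two wings use absolute tolerances.

## Aerodynamic relations

Thrust on the windward face is `F = c·ρ·v²·S` with a free, user-chosen
coefficient `c` (no value is fixed by the fossil material); it is the
form-drag law valid when inertial forces dominate, which the
Reynolds-number check makes explicit: `Re = ρ·v·L/μ` with the
characteristic length `L` defaulting by convention to the ovule length
(≈ 30 mm; neither wing span nor tip diameter is obviously preferable,
and the regime predicate is insensitive to the choice), and the
inertial band taken as `10³ ≤ Re ≤ 10⁴`. Terminal velocity scales as
`v_ter ∝ √(w/A_W)` — the square-root dependence on wing loading that
dimensional analysis and the samara literature require — so only
*ratios* between two diaspores are meaningful; `compare_terminal_velocity`
exposes exactly that and nothing absolute, since no fossil masses
exist. Air defaults: `ρ = 1.225 kg·m⁻³`, `μ = 1.8e-5 Pa·s` (sea-level
air at ~15 °C).

## Morphometrics

The diagnoses of the three genera are encoded as numeric trait ranges
(mm, fractions, degrees) plus categorical characters (wing count,
cupule, attachment, wing folding, distal wing curvature). Design
choices where the published ranges leave room:

* Ranges are **inclusive** at both ends; an "up to 76 mm" branch length
  becomes `(0, 76]` with an open lower bound.
* The "ca. 10–11.7 mm" nucellus length is kept as a hard range but
  carries an `approximate` flag so reports can soften their wording.
* `free_fraction` (wing free length / ovule length) is validated
  against its own 32–45 % band rather than against ratios of the two
  length ranges, whose extremes are not jointly attained.
* **Missing measurements never fail validation** — fossils are
  incomplete — they only lower a completeness score (fraction of
  diagnosis traits actually measured). Removing a measurement can
  therefore never turn a conforming specimen into a non-conforming one.
* Measurements for traits a diagnosis does not define are warnings, not
  failures.

The four-winged genera carry categorical characters only: this package
records no numeric ranges for them, since re-measuring material
described elsewhere is out of scope. The comparative table joins those
characters with each taxon's model-implied `Er` and stability.

## Synthetic specimens

The generator emulates the *measurement structure* of a diagnosis so
the validation pipeline can be exercised end to end: each in-range
record satisfies every numeric range jointly. Wing free length is drawn
conditionally on ovule length through the free-fraction band
(independent draws from the two printed ranges can violate their
ratio), with the band intersected with the free-length range itself.
Defaults: uniform draws over each range; a `truncated_normal`
alternative centres on the range midpoint with sd = width/4. Outlier
records displace exactly one trait outside its range by 10–50 % of the
range width and carry that trait's name as ground-truth provenance; the
displaceable traits are restricted to the five that neither participate
in the free-fraction constraint nor can leave their physical domain
(positive lengths, angles inside (0°, 180°)) under a half-width
displacement, so each outlier fails on exactly its labelled trait.
Missing data is per-trait random omission that never removes an
outlier's displaced trait.

What the generator does **not** emulate: measurement error,
taphonomic deformation or compression geometry, correlations between
traits beyond the free-fraction constraint, and between-specimen size
allometry. Passing the recovery test therefore shows that the validator
classifies *cleanly labelled* in-range/out-of-range records perfectly;
it says nothing about distinguishing real taxa from noisy or deformed
material.

Randomness is NumPy's `default_rng` (PCG64) under a single explicit
integer seed, recorded with the full configuration in a JSON provenance
sidecar next to every generated CSV; populations are byte-identical
across runs with the same seed.

## Problem sizes

The test suite and the acceptance script run the quadrature oracle for
one to eight wings, the recovery pipeline at 1 000 records, and the
distributional check at 10 000 records — sizes at which every
quantity is stable to well below the tolerances asserted, with the full
suite completing in a few seconds.

## Known limitations

* The shadowing rule for `n ≥ 5` is an extrapolation with no external
  check; treat those efficiencies as model output, not measurement.
* The control convention (`min(n, 2)` wings facing the wind) is a
  definition, not a derivation; efficiencies compare only within it.
* No lift/drag estimation, blade-element theory or 3-D descent
  trajectories: the model compares windward areas, not flight paths.
* Absolute terminal velocities are out of reach without masses; only
  wing-loading ratios are computed.
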