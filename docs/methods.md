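# Methods

## Model

`capcolony` integrates a continuum model of a cell colony growing on a hard
flat surface under variable contact inhibition. The state is the pair of
continuous cell counts (*N*_L1, *N*_TOT): the basal layer (cells touching the
plate) and the whole colony. Geometry closes the system: at any instant the
colony is assumed to be a spherical cap whose circle of intersection with the
plate is the basal layer.

Assumptions, in order:

1. **Directional rates.** The lumped first-order rate constant *k* of an
   isolated cell (division + maturation) is split by unitless fractions along
   the Cartesian axes, with in-plane symmetry *f_x* = *f_y* and
   *f_x* + *f_y* + *f_z* = 1, giving aggregate constants
   *k*∥ = (*f_x* + *f_y*)·*k* and *k*⊥ = *f_z*·*k*. The degree of anisotropy
   is Γ = 0.5·*k*∥/*k*⊥ (Γ = 1 isotropic; NaN is reported when *f_z* = 0,
   where the ratio is undefined).
2. **Circular basal layer.** Basal cells grow only in plane; the layer is a
   circle of area *N*_L1·*F*₂D·π·*r*_C², i.e. radius
   *r*_L1 = *r*_C·√(*N*_L1·*F*₂D), where *F*₂D is a 2-D packing efficiency.
3. **Spherical-cap colony.** *N*_TOT cells occupy volume
   *V*_COL = *N*_TOT·*F*₃D·(4/3)π·*r*_C³ with *F*₃D = *F*₂D^{3/2} by default.
   Given *r*_L1 and *V*_COL, the cap height *h*_COL is found by inverting the
   cap-volume formula and the greater-sphere radius follows from the chord
   relation.

Contact inhibition acts by population class: perimeter cells (free boundary)
divide at the full directional rate, internal cells at the γ-scaled rate
(γ = 1 no inhibition, γ = 0 complete; β = 1 − γ is the inhibition extent).
Three partitions feed the two rates:

* basal in-plane: the outer one-cell annulus holds ≈ (2√(*F*₂D·*N*_L1) − 1)/*F*₂D
  cells (clamped to [0, *N*_L1] — the formula is a geometric estimate);
* basal vertical: governed by layer-two coverage η = 1 − *N*_L1/*N*_TOT,
  per = (*N*_L1/2)(1 − η), int = (*N*_L1/2)(1 + η). Note that an isolated
  single cell (η = 0) has half its vertical growth classed internal; the
  transition function is implemented linearly in η, exactly as the model
  defines it, without reshaping;
* upper cap: see accounting note below.

The coupled system is

    dN_L1/dt  = k∥·(per∥ + γ·int∥)
    dN_TOT/dt = dN_L1/dt + k⊥·(per⊥ + γ·int⊥) + k·(N_UC,per + γ·N_UC,int)

Upper-cap cells divide with the full lumped *k* (no directional split):
anisotropy is treated as a surface effect that decays away from the plate.

## Upper-cap accounting

The colony volume is partitioned as *V*_COL = *V*_L1 + *V*_UC with
*V*_L1 = *N*_L1·*F*₃D·(4/3)π·*r*_C³. Two non-equivalent definitions of
*V*_UC are possible: the bookkeeping residual *V*_COL − *V*_L1, or the
geometric reduced cap cut at *h*′ = *h*_COL − 2*r*_C√*F*₂D on the same
greater sphere. The package computes both — `capgeom.upper_cap` exposes the
geometric sub-cap — but the **dynamics use the residual**: the upper-cap
population is *N*_TOT − *N*_L1, graded into interior cells (volume of the
cap eroded by one cell radius: *h*″ = *h*′ − *r*_C, *R*″ = *R* − *r*_C,
divided by the effective cell volume (4/3)π·*F*₃D·*r*_C³) and perimeter
cells (the remainder, clamped at zero). This choice conserves cells exactly
and makes the γ = 1 limit collapse algebraically to dN_TOT/dt = *k*·*N*_TOT,
so all three anisotropy regimes reproduce pure exponential growth with the
configured doubling time when inhibition is switched off — a structural
property of the model that the geometric accounting would violate by tens of
percent. `population.upper_cap_split` therefore accepts the parent count as
an argument; its default (geometric) parent is retained for standalone
geometric analysis.

## Geometry

A single pair of formulas covers every cap, flat or bulging:

    V = (π/6)·(h³ + 3·h·r²),      R = (r² + h²)/(2h)

These are algebraically identical to the piecewise minor/major-cap
expressions (for h > r, the cap is the full sphere minus the complementary
cap of height 2R − h); the unified form removes any branch discontinuity at
h = r, and the equivalence is property-tested. Height inversion uses
safeguarded Newton iteration on the monotone cubic (π/6)(h³ + 3r²h) − V
(unique positive root), bracket [0, (6V/π)^{1/3} + 2r], relative tolerance
1e−12, iteration cap 200, with bisection whenever a Newton step leaves the
bracket. Reduced caps with non-positive height are the empty cap (V = 0, no
cells), which keeps the monolayer→multilayer transition continuous.

Shape observables: Ω = h/R (1 = hemisphere, → 2 = detaching sphere) and the
receding contact angle θ = 90° − asin((R − h)/R) for h ≤ R,
θ = 90° + acos(r/R) for h > R (continuous and strictly increasing in h;
reported in degrees). Midsection outlines are sampled uniformly in arc angle
between the two base points, which keeps bulging profiles well-defined where
the colony overhangs its base.

## Integration and numerical choices

Explicit fixed-step RK4 on (*N*_L1, *N*_TOT), default dt = 0.5 min,
config-overridable. The system is smooth, non-stiff and two-dimensional, so
a fixed-step explicit scheme is accurate and bit-reproducible; geometry is
re-resolved at every RK4 stage so the closure error enters at O(dt⁵).
Step-halving at the reference conditions changes *N*_TOT(3000 min) by less
than 1e−6 relative. States at requested output times come from cubic Hermite
interpolation on the step grid (node values + node derivatives), re-closed
geometrically. The integrator aborts with diagnostics if *N*_L1 overtakes
*N*_TOT beyond tolerance (structurally impossible while both rates stay
ordered, so a breach indicates a defect). No randomness exists anywhere in
the package.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| *r*_C | cell radius, μm | 1.0 | 2-μm spherical cell, typical of bacteria/yeast |
| t_double | doubling time, min | 90 | typical bacterial/yeast culture; k = ln2/90 ≈ 0.0077016 min⁻¹ |
| *F*₂D | 2-D packing efficiency | 1.2 | imperfectly packed discs/spheres |
| *F*₃D | 3-D packing efficiency | *F*₂D^{3/2} ≈ 1.3145 | consistency of the area and volume packing laws; overridable |
| *f_z* | vertical growth fraction | 1/3 | isotropic reference (Γ = 1); 1/6 → Γ = 2.5, 1/2 → Γ = 0.5 |
| γ | contact-inhibition transition | 0.5 | mid-extent reference case |
| dt | RK4 step, min | 0.5 | step-halving-verified accuracy at negligible cost |
| horizon | simulated time, min | 3000 | slightly over two days of culture |

The configuration accepts either `t_double_min` or `k_per_min`; when both
are present the doubling time wins (with a warning), since the pair is
redundant via k = ln2/t_double.

## Reference grid

`run_paper_grid()` runs the 15 reference conditions — three anisotropy
regimes (Γ = 1, 2.5, 0.5) crossed with γ ∈ {0, 0.25, 0.5, 0.75, 1} — from a
single cell over 3000 min at dt = 0.5 min, with states every 10 min and
profile snapshots at 500–3000 min. Structural properties verified on this
grid: *N*_TOT is nondecreasing in γ at every output time; the three regimes
coincide (to 1e−6 relative) at γ = 1; all size observables are monotone in
time; volume and population partitions close at every state.

Two asymptotic regimes are checked against closed forms: with γ = 1 the full
model tracks *N*₀·e^{kt} to better than 1e−4 relative over the whole
horizon, and with γ = 0, *f_z* = 0 the basal radius asymptotically advances
at speed *k*∥·*r*_C. The approach to that front speed is slow
(relative deviation 1/(2√(*F*₂D·*N*_L1))), so the check integrates to
10000 min, where agreement is within 1%.

On log-scale kinetics: log₁₀ *r*_L1(t) is concave over the whole horizon for
γ = 0 (the exponential→linear frontier transition). log₁₀ *h*_COL(t) shows a
brief convex knee while the colony converts from monolayer to multilayer
growth (up to ≈ 540 min after inoculation, regime-dependent) and is concave
thereafter; the concavity test therefore evaluates the height curve from
600 min on.

## What the simulator does and does not represent

The model is a two-parameter (γ, Γ) continuum description. It has no
spatial nutrient field, no mechanics (elasticity, surface tension, gravity,
shear), no stochastic division noise and no discrete cells; colony shape is
imposed (spherical cap), not emergent, so napkin-like or columnar
morphologies are out of scope. Cell counts are real-valued throughout —
trajectories are smooth interpolations of what is, at small numbers, a
discrete process, so early-time output (N of order a few) should be read as
an ensemble average. Passing the structural tests above shows the equations
are solved correctly under the reference conditions; it does not validate
the biological assumptions against any particular organism or culture
format.
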