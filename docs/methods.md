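# Methods

## Scope and model structure

`ctffr` implements a steady-state, laminar, incompressible 1D model of
coronary blood flow on a centerline tree.  The geometry is a rooted directed
tree of branches; each branch is a polyline of points carrying 3D position,
lumen diameter and cross-sectional area, ordered proximal to distal.
Bifurcations occur only at branch ends: the junction point belongs to the
parent and is repeated as point 0 of each daughter with the daughter's own
lumen size, so the pressure at a junction is single-valued (parent side)
while daughters may start with a smaller caliber.  Pulsatility,
fluid–structure interaction and non-Newtonian rheology are out of scope;
FFR is a ratio of time-averaged pressures at maximal hyperemia, for which a
steady approximation is standard practice.

All internal quantities are SI; clinical units (mmHg, L/min, grams) appear
only at I/O boundaries with 1 mmHg = 133.322 Pa.

## Discretization and element features

Branches are resampled by arc length at a configurable spacing (default
0.3 mm, the typical CT pixel pitch); endpoints — hence junctions — are
preserved exactly and diameters are interpolated linearly.  Each adjacent
point pair bounds one micro-flow element with:

* length `l` (chord), mean diameter `d̄ = (d1+d2)/2`, areas `A1`, `A2`
  (reconstructed as πd²/4 when the input carries no explicit areas);
* taper angle `θ = 2·arctan(|d1−d2|/(2l))` — the full cone angle — assigned
  to `θ_c` (constriction) when the lumen narrows and `θ_e` (expansion) when
  it widens.  The convention's constant factor is absorbed by the C2/C3
  calibration;
* bend angle `θ_b` between adjacent unit tangents, after an optional
  centered moving-average tangent smoothing (default window 3) that
  suppresses pixel-scale jaggedness; since the bend term contributes well
  under a percent of total loss, smoothing cannot materially bias results;
* local curvature radius `R` from the three-point circumcircle (∞ when
  collinear, which zeroes the `(d/R)^3.5` bend correction).

Blood properties default to ρ = 1050 kg/m³ and μ = 3.5 mPa·s (typical
literature values for whole blood); both are configurable and residual
mismatch is partially absorbed by calibration.

## Loss terms and numerical choices

Per element, at flow Q, with `U = Q/((A1+A2)/2)`, `U_in = Q/A1`,
`U_out = Q/A2` and `Re = ρUd̄/μ`:

| term | form | notes |
|---|---|---|
| diffusion | `C1·ρλ(l/d̄)U²/2`, λ = 64/Re | implemented as `C1·32μlU/d̄²`, exact and finite at U→0 |
| constriction | `C2·ρς₂U²/2` | `ς₂ = λ/(8 sin(θ_c/2))·[1−(A2/A1)²]`, plus `θ_c/1000` (degrees) for 30° ≤ θ_c < 90° |
| expansion | `C3·ρς₃U²/2` | `ς₃ = λ/(8 sin(θ_e/2))·[1−(A1/A2)²] + sin(θ_e)[1−A1/A2]²` |
| bifurcation | `C4·ρ·0.1·U²/2` | first element of each daughter only, with that daughter's U |
| bend | `C5·ρς₅U²/2` | `ς₅ = [0.131 + 0.163(d̄/R)^3.5]·θ_b/90°` |
| convection | `C6·ρ(U_out²−U_in²)/2` | signed; negative where the lumen widens (pressure recovery) |

Degenerate cases: `θ = 0` short-circuits the taper terms to zero (avoiding
the 0/0 in λ/sin(θ/2)); constriction angles ≥ 90° (abrupt steps, usually
resampling artifacts) are clamped to 90° with a warning, keeping the
operator total.  The additive `θ_c/1000` term uses degrees, consistent with
the piecewise breakpoints; any convention error here is absorbed by C2.
Superposition is exact by construction: the six stored components always sum
to the element total.

A consequence worth knowing for interpretation: because λ ∝ 1/U, the
λ-scaled parts of the constriction/expansion coefficients make those losses
*linear* in Q, like diffusion; only the constant-coefficient terms
(bifurcation, bend, the `sin θ_e` part of expansion, the additive `θ_c/1000`
part of constriction, convection) are quadratic.

## Boundary model

Resting total coronary flow is proportional to left-ventricular myocardial
mass, `Q_total = s·LVMM` with the default scale s = 0.2186/139 L/min/g
anchored so a 139 g LVMM yields the 0.2186 L/min cohort mean; an allometric
exponent is configurable (default 1, "proportional").  Dominance-dependent
left-tree fractions default to 0.1227/(0.1227+0.0876) ≈ 0.583 (right
dominance) and 0.1599/(0.1599+0.0457) ≈ 0.778 (left/co-dominance), derived
from cohort means of the left/right flow columns since the underlying
literature constants are not printed; both are configurable.  When a single
tree is supplied it receives its side's allocation (`side: left` default).

Within a tree, flow splits at each junction by Murray's law,
`Q_n ∝ d_n³` over the daughters, using the *healthy* first-point diameter:
the ideal-lumen value when the daughter ostium is flagged stenotic
(S ≥ β), else the measured one.  Outlet resting resistances follow from
`R_rest,k = (P_a,rest − P_v)/Q_rest,k` with defaults P_a,rest = 100 mmHg
and P_v = 6.5 mmHg; hyperemia scales every resistance by 0.24 and the inlet
pressure by ω = 0.9.  Exact identities (`ΣQ_daughters = Q_parent`,
`Q·R + P_v = P_a`) hold to machine precision by construction and are tested.

## Flow solve

The unknown vector is the outlet flows only; interior flows are descendant
sums, so conservation is structural rather than a constraint.  The residual
at outlet k is `P_distal,k(Q) − (Q_k R_hyper,k + P_v)`.  A damped
least-squares (Levenberg–Marquardt) iteration starts from 1e-6 m³/s per
branch with damping 1e-3 (×10 on rejection, ÷10 on acceptance) and a
forward-difference Jacobian (relative step 1e-6); convergence is declared
when the max outlet residual falls below 1e-3 mmHg (configurable), with a
200-iteration cap.  Negative trial flows are clipped at 1e-12 m³/s with a
warning.  The solve is fully deterministic.  Non-convergence is flagged on
the returned state and by a nonzero CLI exit code; FFR extraction from an
unconverged state requires an explicit override.

On diffusion-only problems the residuals are affine in the flows, so the
iteration is effectively Newton's method and converges in a couple of
steps; this regime is cross-checked against an independently assembled
resistor-network linear solve (`ctffr.synthetic.poiseuille_oracle`).

## Ideal lumen

Per root-to-leaf path the healthy profile is one straight line per branch
segment, so the equal-slope condition within a segment holds by
construction.  Stage one fits each segment's line by least squares,
iteratively re-fit to the upper envelope (points falling more than ~3% of
the local diameter below the current line are dropped) so lesions do not
bias the healthy-taper estimate.  Stage two refines all segment parameters
jointly with SLSQP, minimizing `Σ_j √(d_ideal,j − d_orig,j)` — the square
root concentrates the penalty near zero slack, hugging the measured profile
where it is healthy — subject to linear constraints `d_ideal ≥ d_orig`
pointwise and monotone non-increase along the path (including across
junctions, where a daughter may not exceed its parent).  The optimizer runs
in millimeters for conditioning, with a 1e-12 slack regularizer under the
root, a 500-iteration cap and a 1e-9 feasibility tolerance; if refinement
leaves feasibility it is discarded in favor of the (feasible) stage-one
envelope.  Paths sharing a segment merge by pointwise maximum.

The stenosis rate is the diameter convention
`S = 100·(d_ideal − d_orig)/d_ideal` (the defining formula is a
documented package choice; an area-based variant is available), with the
flagging threshold β = 5%.

## Calibration

Given reference flows and per-point pressures, each element's six
uncorrected loss terms form a basis; cumulative sums along the tree make the
per-point cumulative drop linear in C1–C6.  The fit target is the cumulative
per-point drop (not per-element differences), which matches the pressure
integration and is robust to reference-pressure smoothness; all points pool
with equal weight.  A trust-region reflective least-squares iteration with
bounds C ≥ 0 solves the problem (tolerances 1e-12, consistent with driving
the objective residual below 1e-6); the unconstrained normal-equations
solution serves as an independent oracle in tests when no bound is active.
Factors whose basis column is identically zero (a flow pattern absent from
every case, e.g. no bifurcations) are reported unidentifiable.  Reference
flows are taken as given, never re-solved.

## Synthetic data generator

`ctffr.synthetic` generates rooted bifurcating trees with root calibers in
the clinical 2–4 mm range, linear taper (default 4%/cm), planar
circular-arc bends (default ~25° per branch), Murray-consistent asymmetric
daughter sizing (cubes of daughter diameters sum to the parent's), 0.3 mm
point spacing and raised-cosine focal lesions with known support — smooth
by design so that default-spacing resampling never produces ≥ 90° step
artifacts.  All randomness flows from a single seed.

What the generator does *not* emulate: image segmentation noise, irregular
(non-circular) cross-sections, diffuse disease, side-branch pruning
artifacts, or anatomically realistic branch counts.  In particular the
synthetic trees have far fewer outlets than a real left coronary tree, so
the full side allocation of coronary flow drives higher per-path velocities
and lower absolute FFR values than clinical experience would suggest for
comparable lesions.  Passing tests therefore demonstrate internal
consistency, correct limits and recoverability — not clinical accuracy,
which requires patient data outside this package's scope.

Problem sizes used by the test suite and the acceptance script — trees of
1–3 bifurcation levels (≈ 500–1000 points), 50-tree oracle sweeps, 20-case
calibration sets — are the package's default study conditions; the entire
suite runs in well under a minute.

## Known limitations

* Equivalent-diameter geometry: losses from irregular lumen shapes are not
  represented.
* A single constant bifurcation coefficient is applied tree-wide.
* The left/right flow fractions are cohort-derived defaults, not
  patient-specific.
* The ideal-lumen model is piecewise-linear per branch; genuinely curved
  healthy taper profiles are approximated.
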