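# Methods

This document specifies the physical model, the numerical methods, the
default parameters and the known limitations of `corovast`.

## 1. Scope and modelling strategy

The package assesses coronary stenosis severity *comparatively*: the
same reduced-order flow model is solved on the diseased (stenotic) tree
and on a virtually reconstructed healthy-reference version of the same
tree, under identical flow distributions. Indices are ratios between
the two solutions, so systematic model error and boundary-condition
uncertainty largely cancel.

Flow is modelled as steady, incompressible, Newtonian, and
one-dimensional per segment. A full 3D RANS simulation would resolve
the separated jet downstream of a stenosis directly; here those effects
enter through algebraic loss closures. The 1D reduction is what makes
the paired solve cheap enough for routine use, and the comparative
construction is precisely what makes its residual bias tolerable: both
trees share the same closure, so closure error enters the index ratio
only through the lesion itself.

## 2. Geometry model

A coronary tree is a rooted set of segments. Each segment is a sampled
centerline profile `(s, A(s))` — arc length in mm, lumen area in mm² —
with strictly increasing `s` and positive areas. Junctions occur only
at segment ends; leaves are outlets. Named *branches* (e.g. LAD) may
span several segments (`LAD_p`, `LAD_d`) because a branch is
interrupted by each bifurcation; `branch_chains` re-assembles them.

Diameters are equivalent-circle diameters, `D = 2√(A/π)`. Percent
diameter stenosis is `%DS = 100·(1 − √(A_min/A_ref))`.

Trees serialize to a versioned JSON document (schema
`corovast-tree-v1`) or to a CSV-per-segment manifest. Numbers are
written with 9 significant digits; round-tripped trees compare equal
under a relative tolerance of 1e-8 and re-serialize byte-identically.

### Synthetic generator

Templates: `left` (LM → LAD_p/LAD_d with D1, CX_p/CX_d with OM1),
`right` (RCA → PDA, PLV) and `single` (one tube). The left main is
4.32 mm in diameter; segments taper linearly; the sampling pitch is
0.25 mm. Lesions are cosine bumps in area,
`A(s) = A_healthy(s)·(1 − (1 − (1−ds)²)·bump(s))` with `ds = %DS/100`,
so the minimum-diameter ratio exactly equals `1 − ds` and a 0 % lesion
reproduces the healthy profile bitwise. Optional correlated
area noise (`noise_sd`, mm², Gaussian-filtered) models acquisition
roughness; it defaults to 0, so the generator is deterministic and
seed-independent unless noise is requested.

## 3. Lesion detection and virtual reconstruction

Detection operates on the diameter profile of each branch chain:

1. de-trend with a linear fit, then estimate the local healthy
   reference as a rolling 90th-percentile (window 10 mm,
   edge-replicated), re-adding the trend;
2. flag samples where `D < (1 − 0.25)·D_ref` (i.e. beyond 25 % local
   narrowing), grow each run until the diameter recovers to 98 % of
   the reference, and merge flagged intervals separated by less than
   6 reference diameters;
3. report per-lesion extent, minimum area, reference area at the
   minimum and `%DS`.

Reconstruction replaces the profile inside each lesion interval with a
monotone cubic (PCHIP) interpolant through median-diameter knots taken
from short healthy flanks (2 local diameters per side), clipped from
below by the measured profile (`np.maximum`) so reconstruction never
narrows the lumen. Outside lesion intervals the tree is bitwise
unchanged; the operation is idempotent and is a fixed point on healthy
trees.

The 25 % detection threshold, 98 % recovery criterion, 10 mm baseline
window and 6-diameter merge distance are implementation choices tuned
on the synthetic generator (detector severity error ≤ 3 percentage
points for 40–80 %DS; reconstructed areas within 5 % of the healthy
truth). They are exposed in `ReconstructionSettings`.

## 4. Hemodynamic model

### Segment losses

For volumetric flow Q through a segment:

- viscous: `ΔP_v = R_v·Q`, `R_v = ∫ 8πμ / A(s)² ds` (trapezoidal
  quadrature; exactly the Poiseuille resistance `128 μ L /(π D⁴)` for a
  uniform tube);
- separation: each converging–diverging feature (local area minimum
  found on the negated area profile with 5 % relative prominence)
  contributes a Borda–Carnot loss
  `ΔP_sep = K·Q²`, `K = K_sep·(ρ/2)·(1/A_min − 1/A_rec)²`, applied as a
  ramp from the throat to the downstream recovery point;
- the static pressure additionally exchanges reversibly with the
  dynamic head: `ΔP_static = ΔP_total + ½ρα(u_out² − u_in²)` with
  `u = Q/A` (pressure recovery in expansions).

Total pressure is `P_total = P + ½ραu²`. Static pressure is continuous
at junctions; total pressure then jumps only through the velocity
change, and mass is conserved exactly.

### Two-stage protocol

Stage 1 (pre-simulation, reference tree): inlet flow from the
allometric law `Q_in = β·D_in^n` (Q in ml/s, D in mm), all outlets at
the common zero-flow pressure `P0`. The solver linearizes each segment
as an effective resistance `R_eff = R_v + k_static·Q`, where `k_static`
folds the quadratic separation coefficient **and** the kinetic-energy
exchange into one coefficient,
`k_static = K + ½ρα(1/A_out² − 1/A_in²)`, guarded from below by
`0.1·R_v`. The tree is reduced exactly by series/parallel combination,
flows updated under relaxation 0.7 to a relative tolerance of 1e-5.
Linearizing the *static* drop (not the total-pressure drop) is what
makes a stage-2 solve with the stage-1 flows reproduce the common
outlet pressure `P0` to within solver tolerance.

Stage 2 (paired solve): both trees are solved at the aortic pressure
`P_a` with the stage-1 flow split prescribed identically at the
outlets. Pressures are marched from the root with the full nonlinear
losses. Microvascular resistances are reported as
`R_i = (P_i − P0)/Q_i` from the *reference* stage-2 outlet pressures
(the stage-1 outlet pressures are `P0` by construction and would give
zero).

An alternative solver mode, `pressure_outlets`, fixes outlet pressures
and iterates them toward the required mass flows with the update
`ΔP = ½ρ(ṁ² − ṁ_req²)/(ρA)²` (ṁ in kg/s), solving the interior flow
distribution with a nonlinear root find at each step. The two modes
agree to within 10× solver tolerance and serve as mutual checks.

### Measurement planes and indices

One measurement plane per named branch: at the branch terminus if the
branch is lesion-free; otherwise distal to the *worst* lesion of the
branch, offset by `min(6·D_ref, 0.9·remaining length)` past the lesion
end. If the offset degenerates the terminus is used with a warning.

At the plane, with identical flows in both solutions:

- `FFR_sten = P_d/P_a`, `FFR_rec = P_d,rec/P_a` (an `include_P0`
  variant subtracts the zero-flow pressure from both numerator and
  denominator);
- `EFR_total = P_total,d(sten)/P_total,d(rec)` — equal to the ratio of
  energy fluxes `EF = P_total·Q` since Q cancels;
- `EFR_static = FFR_sten/FFR_rec`, an algebraic identity in the report.

Significance flags: EFR ≤ 0.85, simulated FFR ≤ 0.81 (both calibrated
against invasive FFR ≤ 0.80).

## 5. Default parameters

| parameter | symbol | default | units |
| --- | --- | --- | --- |
| blood density | ρ | 1056 | kg/m³ |
| dynamic viscosity | μ | 3.4×10⁻³ | Pa·s |
| aortic (inlet) pressure | P_a | 26 | kPa |
| zero-flow pressure | P0 | 2.8 | kPa |
| allometric coefficient | β | 0.5 | ml/(s·mmⁿ) |
| allometric exponent | n | 2 | – |
| kinetic-energy coefficient | α | 1.0 | – |
| separation-loss coefficient | K_sep | 1.0 | – |
| convergence tolerance | – | 1e-5 | relative |
| relaxation factor | – | 0.7 | – |
| max iterations | – | 200 | – |
| plane offset | – | 6 | lesion reference diameters |
| detection threshold | – | 0.25 | fraction of local D_ref |
| EFR cut-off | – | 0.85 | – |
| FFR cut-off | – | 0.81 | – |

α = 1 corresponds to a flat (plug) velocity profile, consistent with
the high-Reynolds hyperemic regime; fully developed Poiseuille flow
would give α = 2. K_sep = 1 is the classical Borda–Carnot value for an
abrupt expansion. Both are exposed in `SolverSettings`.

## 6. Verification and statistics

- **Richardson extrapolation / GCI** for a three-grid study with
  constant refinement ratio r: observed order
  `p = ln|e32/e21| / ln r`, extrapolated value
  `φ_ext = φ1 + (φ1 − φ2)/(r^p − 1)`, fine-grid convergence index
  `GCI = 1.25·|e21/φ1| / (r^p − 1)`, numerical standard uncertainty
  `U_num = GCI/1.25`. Grid-converged (zero-difference) sequences give
  GCI = 0 with a warning; oscillatory convergence is flagged.
- **Validation uncertainty**: `U_val = √(U_num² + U_input² + U_D²)`
  (root-sum-square).
- **Diagnostic statistics** against invasive FFR: confusion counts at
  the cut-offs (significant = index ≤ cut-off), the five standard rates
  (any rate with an empty denominator is reported as `None` with a
  warning, never as 0), Pearson r with a Fisher-z 95 % CI, and
  Bland–Altman bias ± 1.96·SD limits of agreement.

## 7. Assumptions and limitations

- **Steady flow.** Cycle-averaged hyperemic flow; no pulsatility, no
  wave phenomena, no myocardial compression.
- **1D closures.** Separation losses are algebraic; tortuosity,
  non-planar junction geometry and secondary flows are not resolved.
  Absolute `FFR_sten` from a 1D model is biased for severe, long or
  serial lesions; the comparative indices are the intended output.
- **Laminar closure regime.** The Poiseuille-based viscous term assumes
  laminar flow. The solver logs the per-segment Reynolds number and
  warns above Re = 2000, where the separation closure is coarse.
- **Fixed-flow contract at extreme severity.** Stage 2 prescribes the
  healthy-reference flows in the stenotic tree. For very severe lesions
  (≈ 80 %DS and beyond at hyperemic flow) the prescribed flow can drive
  the computed distal total pressure below zero, making EFR negative.
  This is a declared regime limit of the fixed-flow comparison, not a
  numerical failure: physiologically such flows would not be attained.
  EFR remains strictly monotone in severity throughout; it is a valid
  fraction of unity for moderate lesions (≤ ~60–70 %DS at default
  settings).
- **Reconstruction is statistical, not anatomical.** The healthy
  reference interpolates adjacent healthy lumen; diffuse disease with
  no healthy flank biases the reference low, which biases EFR toward
  unity (toward missing disease).
- **Synthetic geometry.** The generator produces idealized tapered
  trees with cosine lesions for testing and demonstration; it is not a
  population anatomy model.
- **No empirical claims.** Diagnostic-rate examples in this repository
  are computed on synthetic cohorts; no clinical performance is claimed.
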