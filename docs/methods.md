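# Methods

## Scope and model structure

`hepavasc` models the liver (or any closed organ volume) as a purely
resistive 0D network embedded in 3D. Only the portal vein is modeled on
the inlet side — the hepatic artery's contribution (~25% of supply,
different operating pressures) is deliberately out of scope, matching
perfusion setups that cannulate the portal vein alone. The hepatic vein is
the outlet. Everything below the resolved trees — lobules, sinusoids,
capillaries — is lumped into *super lobules* (SLs): k equal-volume,
equal-resistance elements that are the only junctions between the two
trees. Flow is incompressible, laminar and Newtonian (Hagen–Poiseuille per
segment); vessels are rigid (no compliance, no vasomotion), viscosity is
constant (no shear-, hematocrit- or temperature-dependence), and blood and
CPA are assumed to have the same viscosity so displacement adds no
momentum coupling.

## Geometry and the super-lobule partition

The organ surface must be watertight; the inside-test is the generalized
winding number (vectorized van Oosterom–Strackee solid angles), which is
robust to near-degenerate triangles and needs no spatial index. Interior
points are rejection-sampled uniformly in the bounding box; k-means
(k-means++ init, 10 restarts, fixed seed) on a uniform cloud yields
clusters of near-equal volume, which is what justifies assigning all SLs
one shared resistance and one volume. The cluster-size coefficient of
variation is recorded in the run manifest as the evenness diagnostic.

The blood volume entering the budget V_SL,total = V_blood − V_vessels is
not derivable from the surface alone. It is exposed as
`blood_volume_fraction` (default 0.25 of the organ volume, ~400 mL for a
1.6 L liver — in the range reported for hepatic blood content). The
default is a modeling choice, not a measured constant; the budget only
shifts loading time scales, never the calibrated flows.

## Space colonization

Parameters D (step), d_k (kill), d_i (influence), defaults 5 / 10 / 15 mm
with a warning when D < d_k < d_i is violated. Smaller values give more
tortuous trees, larger values more direct ones; the suite asserts this
trend on a fixed cloud. Design choices where the procedure is
underdetermined:

- **Association**: each attractor influences only its *nearest* growable
  node (within d_i), preventing duplicate growth toward one attractor.
- **Mean direction**: unit vectors toward associated attractors are
  averaged and renormalized, so far attractors are not overweighted.
- **Degeneracy**: when directions cancel (‖mean‖ ≈ 0) or a step would land
  on an existing node (exactly symmetric target pairs oscillate
  otherwise), the node grows toward its smallest-index attractor with a
  deterministic jitter of 1e-6·D.
- **Targets**: SL centroids are target attractors; they persist until a
  node is placed exactly on them (sole associated attractor within D).
  Snapped nodes are terminal caps and grow no children, so after pruning
  leaves are exactly the SL terminals and every branch serves ≥ 1 SL —
  the precondition for the Murray invariants below.
- **Terminal edge length**: if the snapping node is closer than
  l_min = 0.25·D to the target, the terminal attaches to an ancestor
  instead. This avoids vanishing-volume terminal vessels, which would
  otherwise force the loading time step toward zero (stability requires
  Q·dt ≤ V per element). The bypassed nodes become dead ends and are
  pruned.
- **Two stages**: major branches first (2 inlet / 3 outlet anatomical
  targets, mildly asymmetric as in the real organ — the right lobe is
  larger), then the full model. The first stage uses the bounding-box
  diagonal as its sphere of influence: primary targets are tens of mm from
  the root, far beyond the main-stage d_i, and growth toward an explicit
  target needs the root to see it. D and d_k keep main-stage values.
- **Stagnation** (no growth while targets remain) raises an error naming
  the unreached SL ids; silently widening d_i would change topology
  unpredictably.

Pruning keeps exactly the union of terminal-to-root paths, verified in the
suite against an independent reverse-traversal oracle.

## Radii, resistances, linear system

With n_e the SL count served through an edge and N the total, the
downstream-weighted Murray law compounds to the closed form
r = r_root·(n_e/N)^(1/γ), so radii are constant along unbranched chains,
ω sums to 1 and Σ r_child^γ = r_parent^γ at every branch by construction.
Defaults: γ = 3 (laminar-flow optimum), root diameter 15 mm for both
trunks, μ = 3.5 cP.

Internal units are mm–dyn–s (1 mmHg = 13.332237 dyn/mm², 1 mL/min =
16.6667 mm³/s, 1 cP = 1e-4 dyn·s/mm²); all I/O uses mmHg, mL/min, cP,
dyn·s/mm⁵. Each colonization edge is one segment — chains are not merged;
a chain's series resistance is identical either way and per-edge
bookkeeping keeps pruning and radii simple.

The system x = [Q_vessels, Q_SLs, P_nodes] (n = j + k + l) stacks j + k
Ohm rows, l − 2 interior Kirchhoff rows and 2 boundary rows — either both
pressures, or an imposed inlet flow plus the outlet pressure (used for the
demonstration circuit). The matrix is stored sparse and factorized with
SuperLU; solutions are audited against Ohm/KCL residuals at 1e-8 relative
(measured residuals are at machine precision, ~1e-16). Equivalence with
recursive series/parallel reduction is tested on 100 random mirrored
tree–SL–tree networks to 1e-10 relative; mirrored outlet trees are used
because gluing two *unrelated* trees at their leaves is generally not
series-parallel reducible.

R_SL calibration is plain bisection on the monotone map R_SL ↦ Q_in at
fixed pressures: feasibility is pre-checked at R_SL = 0 (the vessel-only
network must pass more than the target flow, else no non-negative R_SL
exists and an error names the achievable operating point), the upper bound
doubles from `bisect_upper` (default 1) until bracketed, and halving stops
when |Q_in − Q_target| ≤ 1e-8 expressed in mL/min — the tolerance is
applied in the reporting unit so it is scale-stable.

## CPA loading

Each element is a well-mixed compartment updated by
C ← (V_in·C_in + (V − V_in)·C)/V with V_in = Q·dt and C_in the
flow-weighted mix of the inflow parents' concentrations; elements are
oriented along solved flows and processed inlet-to-outlet. Two readings of
"parent concentration" exist and both are implemented:

- `scheme="previous"` (default): parents' previous-step values — the
  standard explicit upwind update. It is *exactly* mass-conservative:
  per step every element expels V_in at its old concentration and each
  child receives precisely that, so injected CPA = stored + cumulative
  outflow to machine precision (the suite asserts ≤ 0.5% and observes
  ~1e-14).
- `scheme="updated"`: parents' current-step values (ordered Gauss–Seidel
  sweep). This anticipates the advancing front by one step per element and
  therefore *creates* Σ_e Q_e·dt·ΔC_e of CPA per step — a few percent of
  the injected volume at early times for dt = 0.01 s — which is why it is
  not the default. Both schemes converge to the same loading curves as
  dt → 0 (asserted in the suite).

Stability demands V_in ≤ V for every element; violations raise an error
naming the element and the maximum stable dt = min V/Q (the terminal-edge
l_min rule above keeps this comfortably above the default dt = 0.01 s).
Iteration uses a constant sparse linear map (one matvec, or one
pre-factorized triangular solve for the updated scheme) per step.
Times-to-threshold are linearly interpolated between bracketing steps; the
outlet is a pure sink whose efflux concentration is the last element's
pre-update value (the quantity that makes the conservation audit exact).
The default dt = 0.01 s is validated by the convergence protocol: on a
100-SL model, times to 50/90/98% change by ~0.01% between dt = 0.01 and
0.005 (threshold 1%).

## Boundary-condition sweeps

The sweep recalibrates R_SL per (ΔP, Q) cell — infeasible cells are
flagged, not fatal — and reports max WSS over vessels and the total /
last-SL 90% loading times. Directional behaviour asserted by the suite:
R_SL increases with ΔP and decreases with Q; max WSS increases with Q and
decreases with ΔP (higher R_SL evens out SL flows, shaving the extreme
vessel flows); the last-SL time decreases with ΔP; the total-concentration
time depends only on Q. Whether a given (ΔP, Q) corner is infeasible
depends on the organ surface and attractor cloud: the vessel-only
resistance of the default ellipsoid models is low enough that the whole
3–12 mmHg × 100–1000 mL/min grid is feasible, so the infeasibility path is
exercised on a constructed high-resistance circuit instead.

## Synthetic geometry, and what the tests do not show

The built-in triaxial ellipsoid (2 : 1.2 : 0.8, scaled to 1.6 L) has the
bulk proportions of a liver but none of its lobed, concave anatomy; SL
partitions and tree topologies on it are smoother and more symmetric than
on a real segmentation, and vessel-path resistances are somewhat lower.
Green tests therefore establish the *mechanisms* — target reachability,
calibration exactness, conservation laws, trend directions — not
anatomical fidelity of any particular tree. Quantities tied to one
specific mesh/cloud/seed (per-model R_SL values, per-SL pressure drops)
are validated through their defining identities (R_SL,eq = R_SL/n_SL,
ΔP_SL = R_SL·Q_SL, mean Q_SL = Q_in/n_SL) rather than against any single
model instance.

## Problem sizes

The suite and the acceptance script run coarse models chosen for
turnaround: 10-SL / 3000-point and 100-SL / 8000-point clouds (the default
floor is 5000 points, 200 per SL), giving ~250–1600 vessels and linear
systems of ~500–3300 unknowns; the demonstration circuit has 6 elements.
All machinery is size-independent; denser clouds and larger k simply cost
more colonization iterations and larger (still sparse) factorizations.

## Known limitations

Single inlet tree (no hepatic artery co-perfusion); rigid vessels, no
capacitance or vasomotion; Newtonian constant-viscosity fluid; advective
transport only (no diffusion or Taylor dispersion); no heat transfer; the
shared R_SL is a calibration parameter, not a physiological constant — at
low prescribed pressures it becomes small and flow distributes less
evenly, which is a known artifact of treating it as free.
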