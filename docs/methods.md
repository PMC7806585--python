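# Methods

This note documents the model equations, the default parameters and why they
were chosen, what the synthetic geometry does and does not emulate, and the
numerical choices that matter when interpreting results.

## Scope and philosophy

`airwaysim` is a desk-scale, reduced-order counterpart to 3D CFD aerosol
simulations of the conducting airways. It deliberately trades resolved flow
fields (laryngeal jet structure, secondary vortices, cross-sectional velocity
profiles) for three things a reduced model can do well: exact conservation,
full-cycle transients at negligible cost, and transparent sensitivity to the
parameters that dominate regional dosimetry — particle size, flow rate,
injection timing, and airway calibre. Quantities that only a resolved 3D
solution can produce are out of scope and are treated, at most, as
qualitative trends.

## Geometry

The conducting airways are a strict binary tree (every branch has 0 or 2
children), trachea = generation 0, terminating at generation 6 with 64
peripheral outlets labelled by lobe. Branch diameters across a bifurcation
satisfy the power-law diameter relation `d_P^x = d_A^x + d_B^x`. The exponent
`x` is configurable and defaults to 3 (Murray's law) — a standard choice for
the conducting airways; for externally supplied morphometry tables the
relation is reported as a per-bifurcation residual diagnostic, never
enforced. The carinal ridge radius is `r_c = (R_A + R_B) · c_c` with
`c_c = 0.1`, and the bifurcation transition zone begins at 80 % of the parent
axial length; both are geometric annotations used by the surface exporter.

The trachea is a circular tube of diameter 1.56 cm cut by a posterior plane
0.65 cm from the centre; its effective cross-section (1.835 cm²) is used for
tracheal velocity. Cartilaginous rings (step 5 mm, width 3.5 mm, depth
0.5 mm, fillet 0.3 mm — anatomically plausible defaults, no published values
to pin them) are annotated on the trachea and main bronchi only. By default
rings are geometry-only; an opt-in "effective roughness" flow option shrinks
the tracheal effective diameter by the ring depth, off by default because no
quantitative model for their aerodynamic effect is established.

The upper airway is three elliptical tubes (oral cavity, pharynx, larynx)
with cross-sectional areas anchored at 2.98, 0.95 and 0.64 cm² — the
literature cast values for an average adult — an assumed 2:1 ellipse aspect
ratio and lengths 7/6/3 cm. All linear dimensions are multiplied by a single
factor so the source model's tracheal end (equivalent diameter 1.90 cm, a
typical adult cast value) matches the 1.56 cm trachea; the factor is
therefore 0.821. The aspect ratio, lengths and tracheal-end diameter are
fixture design choices (the sources publish areas, not full ellipse tables);
they were fixed once when the fixture was designed. The glottis hydraulic
diameter uses `4A/P` with Ramanujan's perimeter approximation.

### The packaged characteristic tree

The characteristic asymmetric tree emulates an average adult male
tracheobronchial tree; it is generated, not measured. Topology: right main
bronchus → RUL subtree (16 outlets) and intermediate bronchus → RML (8) and
RLL (8); left main bronchus → LUL (16) and LLL (16). Fixed anatomical
dimensions: trachea length 10 cm, right main 2.2 cm, left main 5.0 cm (the
longer, narrower left main is the anatomical source of right-favouring
resistance asymmetry); every other branch has length 3 × its diameter.
Within-lobe bifurcations carry a mild seeded conductance-share jitter
(±0.08) so the tree is not artificially symmetric; all upstream diameters
are Murray combinations of their daughters, then globally rescaled so the
trachea is exactly 1.56 cm — the diameter law therefore closes to round-off
at every bifurcation.

The five lobar-root diameters are the only free parameters. They are
calibrated by a damped fixed-point iteration (scale by
`(target/achieved)^(0.8/4)`, laminar conductance ∝ d⁴) until the
equal-outlet-pressure solve reproduces the physiological lobar ventilation
partition RUL 19 / RML 9 / RLL 29 / LUL 26 / LLL 17 % (right lung 57 %).
This calibration is part of the fixture's definition — the partition is an
input of the model, not a prediction — and is deterministic: regenerating
the table reproduces the shipped CSV bit-for-bit (checksums recorded in
`fixtures/checksums.json` and verified by the test suite).

What the synthetic geometry does **not** emulate: real branching-angle
statistics and out-of-plane rotation angles beyond a simple alternating
scheme, per-branch length/diameter scatter of cast data, cartilage ring
irregularity, and the exact coordinates of any digitized reference lung.
Tests passing on this geometry therefore validate the *pipeline* (balance
laws, correlations, transport bookkeeping) and the calibrated ventilation
partition, not anatomical fidelity of any individual airway.

## Airflow

Breathing is the sedentary sinusoid `Q(t) = Q_peak sin(2πt/T)`, T = 4 s,
mean inspiratory flow 6 L/min, hence `Q_peak = 6·π/2 = 9.42 L/min`;
inhalation is [0, 2 s], exhalation mirrors it.

The flow solve is quasi-steady: each snapshot is an independent steady
laminar network solution at |Q(t)|, with all signs flipped during
exhalation. At 0.25 Hz the Womersley number of the trachea is ≈ 1.7 and
unsteady inertia is a secondary effect; neglecting it is the model's central
approximation and the reason transients cost nothing. Branch resistance is
Hagen–Poiseuille, `R = 128 μ L/(π d⁴)`; upper-airway sections use the exact
elliptical-tube resistance `ΔP = 4 μ L Q (a²+b²)/(π a³ b³)`.

In equal-pressure mode, flows are computed by a bottom-up series/parallel
conductance recursion and a top-down proportional split — exact mass
conservation by construction (residuals ~1e−16, tested against a dense
nodal-Laplacian solve on small networks). In lobar-fractions mode terminal
flows are pinned to the configured partition, distributed equally within
each lobe, and summed upward.

Fully developed Poiseuille flow underestimates dissipation in short,
entrance-dominated airway segments, so reported pressures include, by
default:

* a Pedley-type developing-flow multiplier `Z = max(1, (C/4)·√(Re·d/L))` on
  each branch's viscous drop, `C = 1.85` (the classical energy-dissipation
  coefficient used in lung network models);
* a bifurcation minor loss `K·ρU²/2` on each non-root branch's entry
  velocity head, `K = 0.5` (modest bend/secondary-flow loss);
* a laryngeal-jet loss `K·ρU²/2` at the larynx, `K = 1.0` (Borda–Carnot-type
  expansion of the glottal jet).

These corrections affect reported pressures only; the flow *split* uses the
linear Poiseuille network, which keeps it scale-invariant and linear in the
inlet flow (both properties are tested). With the default losses the
tracheal-inlet → generation-6 static drop at the inspiratory peak is
≈ 3.4 Pa; pure Poiseuille gives ≈ 0.73 Pa — the corrections carry most of
the physical dissipation, as expected in the entrance-flow regime.

Reynolds numbers use `Re = ρ U D_h/μ` with the section's hydraulic diameter;
the glottis (minimum CSA) is the critical section, Re ≈ 1694 at the 9.42
L/min peak with the documented upper-airway scaling — laminar to
quasi-transitional, consistent with sedentary breathing.

## Aerosol transport and deposition

Particles are inert spheres, density 998.2 kg/m³ (water), Cunningham slip
factor 1 (appropriate for ≥ 3 µm), diameters of interest 3/7/10/25 µm. The
reference injection is 2720 particles uniform on a 2.16 cm disk at the oral
inlet.

Transport is 1D: a bolus advects along its conduit at the local
instantaneous mean velocity, splits at bifurcations in proportion to the
instantaneous daughter flows, and reverses with the flow at mid-cycle.
Deposition happens at *region entry*: crossing into a conduit of a new
region (oral → pharynx → larynx → trachea → 1st/2nd/3rd-bifurcation →
peripheral) removes the deposited fraction given by the region's
correlation. The upper-airway regions use `DE = 1 − exp(−a·IP)` at the
instantaneous inlet flow; downstream regions use `DE = 1 − exp(−a·St^b)`
with the Stokes number built from the *parent* conduit's mean velocity and
radius at the moment of entry. Reaching a terminal outlet during inhalation
credits the bolus to that lobe's escaped count (available for deeper-airway
deposition); crossing the mouth during exhalation is recorded as exhaled and
folded into the suspended bucket; anything still airborne at the end of the
cycle is suspended. Deposition is re-evaluated on every region change in
either direction, so boluses carried back during exhalation can deposit
again — a deliberate simplification consistent with the correlations'
per-encounter meaning.

Correlation constants are configuration, not code: the defaults
(oral/pharynx/larynx `a` = 1.7e−4 / 1.0e−4 / 3.0e−4 per unit IP;
tracheobronchial `a` = 1.0–1.6, `b` = 1.2) are order-of-magnitude
literature-consistent values for oral-replica IP fits and TB-cast Stokes
fits, recorded with source notes in the config block and fully overridable.
Model outputs that depend on their absolute values (e.g. "total DE =
27.7 %") inherit their uncertainty; trend statements (DE monotone in size
and flow, larynx filtering growing with size, transient ≥ steady deposition)
are robust to any positive constants because of the correlations' functional
form.

Two transport modes: deterministic fractional-bolus accounting (default; no
variance, ledger conserved to ~1e−16) and a seeded Monte-Carlo per-particle
mode used for position-fate maps, which converges to the deterministic
ledger as 1/√n (tested within 3 standard errors at n = 2720). Gravitational
sedimentation and Brownian diffusion are not modelled: the supported size
range is impaction-dominated at these flows; this is the main reason 3 µm
results should be read as lower bounds on deposition.

## Numerical choices and degenerate cases

* Flow snapshots every `dt = 0.01 s` (400 per cycle); `dt` must divide T/2.
  The bolus integrator sub-steps exactly at conduit boundaries, so transit
  is not limited by `dt`; velocities are piecewise-constant per snapshot.
* Zero-flow snapshots (t = 0, 2, 4 s) advect nothing; boluses wait.
* A region never entered has undefined DE and is reported as not-applicable
  (`None`), never as 0.
* Boluses below 1e−12 of the injected mass are dropped; the ledger tolerance
  (1e−9) dominates this truncation by three orders of magnitude.
* `posterior_cut_offset ≥ trachea radius` degenerates to a full circle and
  warns; offset 0 halves the circle.
* The fixed-point calibration of the characteristic tree runs 60 iterations
  or to a 1e−12 fraction residual, whichever first; it converges in ~25.
* Surface export builds one connected, locally watertight mesh by sharing a
  single apex vertex per junction; tubes interpenetrate near junctions
  rather than being boolean-unioned (a warning lists branches when the
  global mesh is not watertight).

## Problem sizes

The shipped analyses use the full characteristic tree (127 branches, 64
outlets), 400 flow snapshots per cycle, 10 injection times, and 2720
particles in Monte-Carlo mode. The complete test suite runs in well under a
minute on one CPU; the acceptance script in about a second.

## Known limitations

* Quasi-steady laminar flow: no turbulence, no Womersley effects, no
  secondary flows; the laryngeal jet appears only as a minor-loss term and a
  Reynolds number, not a flow structure.
* Deposition constants are configurable surrogates; absolute DE values are
  only as good as the correlation constants supplied.
* Region-entry sampling assigns the whole peripheral zone (generations 4–6)
  a single entry event; intra-region redeposition is not resolved.
* The geometry is characteristic, not patient-specific; lobar partition is
  calibrated, not predicted.
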