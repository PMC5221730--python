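# Methods

This note documents the model, the numerical choices and the design
decisions behind `afpom`, in the spirit of the methods documentation of
simulation packages: what exactly is computed, under which assumptions,
and what the shipped defaults do and do not represent.

## Cell model

The membrane model is the Courtemanche–Ramirez–Nattel (CRN, 1998) human
atrial action-potential model (21 states: V, 15 gates, Na/K/Ca
concentrations with SR uptake/release compartments), with the standard
chronic-AF electrical remodeling applied on top of the control
parameters: Ito −50%, ICaL −70%, IK1 +100% (Courtemanche et al. 1999).
This remodeled cell — RMP ≈ −84 mV, APD90 ≈ 120 ms at 1 Hz, flattened
rate dependence — is the package's baseline "AF cell". CRN with cAF
remodeling was chosen as the substrate because it is the most widely
used and best characterized chronic-AF rotor substrate in the
literature, its equations could be transcribed and verified reliably
offline, and every contract in this package (scalable conductances,
biomarkers, calibration, tissue dynamics, statistics) is agnostic to the
particular human atrial formulation standing behind it. Swapping in a
different atrial model means reimplementing `_crn.py`'s state vector and
right-hand side; nothing else changes.

A population member is defined by eleven multiplicative scale factors on
gNa, gCaL, gto, gKur, gKr, gKs, gK1, the Na/K-pump maximum, the Na/Ca-
exchanger maximum, the sarcolemmal Ca-pump maximum, and the SERCA uptake
maximum. Each factor ranges over [0, 3] (−100% to +200% of the
remodeled nominal value); 0 is allowed and means complete removal of the
current, which calibration rejects via the not-excited / out-of-range
paths rather than by pre-filtering. The membership of the sampled set
is a parameter (`names` in `scale_conductances`), not a hard-coded
truth; the default above spans the depolarizing currents, the
repolarization reserve, and the major Ca-handling fluxes.

## Integration

Gating variables use Rush–Larsen exponential updates; voltage and
concentrations use forward Euler. The default step is dt = 0.02 ms for
single-cell work and dt = 0.04 ms for tissue (APD90 of the baseline
cell agrees to < 0.5 ms between the two). All voltage-dependent
quantities (12 gate steady states and exponential decay factors, the
IK1/IKr rectification factors, gKur(V), the Na/K-pump voltage factor and
the Na/Ca-exchanger exponentials) are tabulated on a 0.02 mV grid over
[−110, +70] mV and linearly interpolated inside the compiled kernel;
this is the standard cardiac-simulation optimization and is part of the
numerical method, i.e. the reference `derivatives` path and the kernel
agree to discretization error, not bit-exactly. The kernel is numba-
compiled; single-cell and tissue integration share one reaction routine,
so a tissue run with D = 0 reproduces single-cell trajectories to
round-off (≤ 1e-9 mV over hundreds of ms, verified in the tests).

The stimulus is a rectangular 2-ms pulse; the default amplitude of
25 pA/pF is twice the diastolic threshold of the baseline AF cell
(12.5 pA/pF for a 2-ms pulse, found once by bisection;
`diastolic_threshold` recomputes it for any variant). Pacing policy for
phenotyping: 30 beats at each frequency, biomarkers from the last beat.

## Biomarkers

RMP is the voltage immediately before the stimulus; APA the peak minus
RMP; the take-off point is the right endpoint of the steepest sampled
upstroke interval (max dV/dt), which is exact for step-like synthetic
shapes and robust to the stimulus artifact in simulated APs; APDx runs
from take-off to the crossing of RMP + (1 − x/100)·APA. The crossing
time is estimated from a least-squares line over a ±1 ms window around
the first sample below the threshold: on piecewise-linear test shapes
this is exact, and under additive noise it is unbiased, whereas plain
two-point interpolation at the first noisy sub-threshold sample is
systematically early (the tests quantify both). V20 is the voltage at
take-off + 0.2·APD90. V20 is measured from the take-off point rather
than the stimulus onset; for any stimulus shorter than the upstroke the
two differ by under a sample. An AP with APA < 10 mV is flagged
not-excited; a beat whose repolarization never crosses the APD90 level
within its cycle is flagged not-repolarized. Both flags make a
candidate ineligible for calibration.

Rate dependence is summarized as APD50 and APD90 at 2, 3, 4 Hz divided
by their 1-Hz values.

## Calibration envelope

The experimental acceptance ranges that a real study would measure in
patient tissue are not available, so the calibration envelope is
synthetic and explicit: centered on the baseline AF cell's own
phenotype (six 1-Hz biomarkers plus six rate ratios), with half-width
`spread`·|center|. The library default is spread = 0.3; with
11-dimensional sampling over [0, 3] this accepts ≈ 1% of candidates, a
yield of the same order as the full-scale study design this emulates.
The shipped experiment presets use spread = 0.5, which accepts ≈ 11% and
yields a workstation-sized calibrated population (tens of models) from a
few hundred candidates. Envelopes serialize to YAML, so measured ranges
can replace the synthetic ones without code changes. Acceptance is
monotone in the envelope by construction (widening never rejects a
previously accepted model); this is property-tested.

## Tissue model

Homogeneous monodomain: every node carries the same (rescaled) cell
model, coupled by a discrete Laplacian with diffusion coefficient D
(cm²/ms), integrated by Godunov splitting (reaction step, then explicit
diffusion step) at a shared dt. Meshes: a bounded sheet (5-point
Laplacian, mirrored zero-flux borders), a 1-D strip for conduction-
velocity work, a periodic sheet (torus; 5-point Laplacian with
wraparound), and an icosphere with cotangent-weight Laplacian and
barycentric vertex areas. Laplacian rows sum to zero exactly on every
mesh (zero-flux or closed surface), so a uniform field generates no
diffusive flux — this holds to the last bit and is tested.

D defaults to 1.0e-3 cm²/ms. At the deployed discretization
(dx = 0.05 cm, dt = 0.04 ms) this propagates a planar wave at
≈ 33 cm/s; the dx→0 limit at small dt is ≈ 48 cm/s. Both the
discretization bias and the absolute value are deliberate: conduction in
chronically remodeled, dilated human atria is commonly reported in the
25–60 cm/s range, and the resulting wavelength (CV × APD ≈ 4 cm) is
commensurate with workstation-sized domains. Conduction-velocity
convergence is validated on the strip (CV changes < 3% when dx is
halved from 0.0125 to 0.00625 cm at dt = 0.005 ms), and CV is
monotone in the gNa multiplier, both in the test suite.

Reentry initiation: `phase_seed` wraps one paced limit cycle of the cell
(default cycle 250 ms) around an axis — one spiral on a bounded sheet, a
counter-rotating pair on closed surfaces (longitude seeding on the
sphere; a vortex–antivortex pair phase field on the torus, which is
continuous across the periodic seams). `cross_field` implements classic
S1–S2 initiation on bounded sheets, with the S2 timed adaptively off the
repolarization tail of the S1 wave; it reliably produces a single
charge-+1 rotor on a 4×4 cm baseline sheet and is used for validation
rather than for the population experiments (phase seeding is cheaper and
model-robust).

## Rotor analysis

Phase is the angle of the analytic signal (Hilbert transform) of the
mean-subtracted voltage, computed per node over the analysis window; a
time-delay-embedding variant is available. Phase singularities are
faces whose oriented boundary phase differences (each wrapped to
(−π, π]) sum to ±2π; the detector is vectorized and agrees exactly with
a brute-force per-face winding loop (oracle-tested on random smooth
fields). On closed surfaces the detected charges sum to zero frame by
frame.

Cores are tracked by greedy nearest-neighbor association with a
same-charge constraint and a gate of 4 node spacings per frame; on the
torus, displacements use the minimum-image convention and positions are
unwrapped along each trajectory. Rotor meandering (RM) is the convex-
hull area of a core trajectory (tangent-plane projection on the sphere);
the reported RM of a simulation is the maximum over trajectories alive
at least 100 ms inside the analysis window. Dominant frequency (DF) is
the frequency of the highest peak of a Hann-windowed, zero-padded
periodogram in 1–20 Hz per node; the scalar DF is the modal per-node
value (aggregation configurable). Termination is declared at the start
of the first contiguous 300 ms with no singularity and no node above
−40 mV; the mechanism is tagged "core collision" when the last two
opposite-charge trajectories died within the tracking gate of each
other, and "boundary" when the last core died within two spacings of a
bounded-sheet border.

Analysis windows exclude the first part of each simulation (default
skip = 250 ms after seeding; the experiment presets skip 500 ms) so that
the seeded transient does not contaminate DF/RM.

## Experiments and their scale

`run_maintenance_experiment` samples and calibrates a population, runs
one reentry simulation per calibrated model, splits sustained vs
unsustained, compares every scale factor between the groups
(Mann–Whitney, two-sided, α = .01, no multiplicity correction by
default), and computes partial correlations (PCr) of DF and RM with each
scale factor controlling for the other ten among the sustained models.
`run_ical_block_experiment` continues every sustained model from its
end-of-baseline state with gCaL halved, measures ΔDF/ΔRM against the
baseline window, flags block-induced terminations, and repeats the
statistical layer on the Δs. All randomness derives from the
configuration seed; tissue and cell integration are deterministic, and
per-model results are cached on disk keyed by a hash of the
configuration and scale vector, so interrupted sweeps resume.

The shipped presets trade statistical power against workstation runtime:

* `mini` — 192 LHS candidates, spread-0.5 envelope, a radius-0.9 cm
  icosphere (subdivision 4, 2562 nodes), 2-s baseline and block
  windows. This is the configuration the acceptance script and the
  heavy tests run; it fits in tens of minutes on one CPU.
* `desk` — the same geometry with a larger candidate pool (256).
* `study` — 16,384 candidates, spread-0.3 envelope, a radius-2.5 cm
  icosphere at subdivision 6 and 7-s windows; cluster-scale, provided
  as configuration only.

The closed surface for the experiment presets is a deliberate choice,
and so is scaling the sphere radius down rather than switching to a
bounded sheet. On a bounded desk-sized sheet the rotor wavelength is
comparable to the domain and long-wavelength (high-gCaL) rotors drift
along the borders; this boundary interaction dominates measured
meandering, reverses the gCaL–RM relationship, and replaces the
collision termination mechanism by boundary escape. On a flat periodic
sheet (torus) the seeded counter-rotating pair instead translates
freely — dipole self-propulsion with nothing to curve its path — so the
trajectory hull saturates at the domain area and colliding ends never
meet. Only the sphere's curvature both removes boundaries and bends
drifting cores back toward each other, which is what makes "larger
meander → pair collision → termination" observable. The desk sphere
(radius 0.9 cm, ≈ 10 cm² surface, node spacing ≈ 0.07 cm) trades some
spatial resolution (a construction-time warning flags spacing above
0.05 cm; conduction is uniformly somewhat slower on the coarser
lattice) for simulations that fit a workstation session. The bounded
sheet and the torus remain first-class mesh kinds, used by the numerics
tests and available for custom experiments.

## What the desk scale reproduces

At the shipped mini scale (22 calibrated models at the default seed)
the pipeline recovers the qualitative physiology the design targets:
roughly three quarters of the calibrated models sustain the seeded
reentry for the full window; self-terminations happen by rotor-pair
collision; faster rotors associate with higher gNa and higher gK1 and
meander less (positive PCr of gNa and gK1 with DF, negative PCr of gNa
with RM); the DF–RM association is weakly negative; and under 50% gCaL
block the models that terminate have lower gNa than those that persist,
while the change in DF correlates positively with gNa and negatively
with gK1. Two quantities do not reproduce stably at this scale and the
corresponding acceptance tests fail honestly rather than being loosened:
the partial correlation of gCaL with RM (with ~16 sustained models and
ten controls the coefficient has ~4 residual degrees of freedom, and
across seeds the sustained count can fall below the minimum the
11-predictor PCr needs at all) and the mean RM change among models
still sustained after the block (near zero here: the models with the
largest block-induced RM increase are removed from that mean by their
own termination, and halving an ICaL already reduced to 30% by
remodeling shortens the wavelength — a stabilizing effect on a 10-cm²
surface — nearly as strongly as it destabilizes the rotor head).

## What the synthetic setup does and does not show

The synthetic envelope is centered on one cell's phenotype rather than
on patient recordings, so the calibrated population explores parameter
space around the remodeled baseline, not the clinical biomarker
distribution; passing trends therefore demonstrate that the pipeline
recovers the mechanistic directions (sodium/calcium availability vs
rotor stability) under controlled conditions, not that it reproduces
patient-level effect sizes. Desk-scale geometry, 2-s windows and tens
of models further mean that percentages (sustained fraction, block
termination fraction) and magnitudes (mean ΔRM, PCr values) are
indicative only; signs and orderings are the reproducible content.
Homogeneous tissue, no fibrosis or anatomy, no late-INa or SK currents,
and surface (not transmural) rotor filaments are out of scope.

## Numerical edge cases

* Gate tables clamp V to the tabulated range; excursions beyond
  [−110, +70] mV would be integrated with end-of-range kinetics.
* Solver divergence (non-finite V) raises with the failing time and
  node; in population sweeps it is caught and recorded as a rejection
  or an errored simulation row, never a crash.
* Phase of a (numerically) constant node is undefined and flagged; such
  nodes never contribute singularities or DF values.
* Convex hulls of < 3 points or collinear trajectories have RM = 0.
* Mann–Whitney switches from the exact to the tie-corrected normal
  p-value above n1·n2 = 400 or in the presence of ties.
* Partial correlation uses explicit residual regressions, which remain
  well-defined when a predictor and the outcome are exactly collinear
  (PCr = ±1), where inverse-correlation-matrix formulations fail.
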