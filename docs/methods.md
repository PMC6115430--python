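# Methods

`neovent` is a reduced-order (0D network / 1D transport) model of
high-frequency oscillatory ventilation (HFOV) in an extremely preterm
infant.  It reproduces, at desk scale, the gas-exchange phenomenology that
full 3D computational models of the infant bronchial tree exhibit:
steady-state onset of the ventilator–lung interaction, tube leak, pendelluft
between lung regions of unequal compliance, direct versus delayed oxygen
delivery to distal regions, and the localisation of turbulence-prone versus
laminar flow along the airway generations.  This note records the model, its
assumptions, the parameter choices, and what the reduction can and cannot
show.

## The patient and the synthetic inputs

The modelled patient is an extremely preterm infant (27.3 weeks
postmenstrual age, birth weight 0.76 kg) with severe (grade 3)
bronchopulmonary dysplasia (BPD) and a total respiratory compliance of
C_rs = 20.93 ml/kPa determined by infant lung function testing.  No
individual-level imaging or lung-function traces of such patients are
publicly deposited, so every input is synthesised:

* **Single-occlusion technique (SOT) maneuvers.**  The clinical measurement
  is modelled as single-compartment passive expiration: after a brief
  occlusion holding volume `V0` above relaxation volume, flow decays as
  `V0/tau * exp(-t/tau)` with `tau = R * C_rs`, against a plateau pressure
  `V0 / C_rs`.  Gaussian noise (default sd 4 ml/s in the analysis scripts,
  ~5% of peak flow) is added to the flow channel; volume is the trapezoidal
  integral of the noisy flow, as a pneumotachograph-based system integrates.
  The default generator resistance, 0.005 kPa·s/ml (5 kPa·s/L), is a typical
  total respiratory resistance for an intubated preterm infant and gives a
  textbook expiratory time constant of ~105 ms.
* **Estimator.**  C_rs is exhaled volume over plateau pressure, with the
  exhaled volume taken as the volume-axis intercept of the least-squares
  flow–volume line (`V0 = intercept * tau`), the standard SOT extrapolation;
  a finite recording otherwise biases C_rs low by `exp(-T/tau)`.  The time
  constant is the negative inverse slope of that line and
  `R = tau / C_rs`.
* **Regional compliance heterogeneity.**  BPD mechanics are patchy.  The
  generator down-weights a seeded, contiguous block of 25% of the terminal
  outlets (roughly one lobe) by a severity factor (default 0.5, i.e. the
  affected region is half as compliant) and renormalises.  The patient-scale
  truth — a regional compliance map of a real BPD lung — is unavailable;
  contiguity and the 25% extent are modelling choices.

All generators are pure functions of their parameters and an explicit seed;
a single global seed fans out to per-stage seeds through
`numpy.random.SeedSequence`.

## Airway tree

The resolved domain is a dichotomous bifurcating tree, generations 0
(trachea) through 7 (255 segments, 128 terminal outlets).  Child dimensions
scale by per-generation homothety ratios (default 0.79 ≈ 2^(-1/3) for both
length and diameter, the classic self-similar value), split between the two
children by an asymmetry factor a (child ratios ×(1+a) and ×(1−a), default
a = 0.1) so that root-to-leaf path lengths are heterogeneous as in a real
lung; optional log-normal jitter adds irregularity.  Pre-calibration trachea
dimensions (30 mm × 3.5 mm) are plausible for a ~0.76 kg infant.

The binding anatomical calibration is the **anatomical dead space**: all
linear dimensions are rescaled by the single global factor (the cube root of
the volume ratio) that makes the summed cylinder volume equal 2.2 ml/kg of
body weight, the value reported for this patient's airway tree and
consistent with clinical measurements (2.51 ± 0.61 ml/kg).  Per-generation
mean dimensions of the reference anatomy are published only graphically and
are not reproduced numerically.

Lobe labels (RUL, RML, RLL, LUL, LLL) are assigned from the generation-2
subtrees purely for reporting.

## Mechanics: terminal closure

Airways beyond generation 7 are not resolved.  Behind every terminal outlet
`i` sits a lumped unit with

* an **equivalent resistance** `R_eq^i`: a virtual symmetric dichotomous
  subtree continues the homothety ratios for 9 further generations (8–16)
  and is reduced by series/parallel composition of laminar
  (Hagen–Poiseuille, `R = 128 μ L / (π d^4)`, `μ = ρν`) segment resistances;
* a **regional compliance** `C_eq^i = w_i · C_rs`, a weight-vector share of
  the measured total (parallel compliances add, so the partition conserves
  C_rs exactly).  Weights are uniform or the BPD-patchy map.

The closure pressure at the end of the resolved tree is

    P^i = R_eq^i · Q^i + ΔV^i / C_eq^i ,

with `ΔV^i` the time integral of the regional flow.  Pressures are stored
relative to the PEEP baseline, so `ΔV^i` is volume above the
PEEP-equilibrated FRC and the closure needs no offset.  There is no
inertance in the closure and no tissue viscoelasticity.  Air properties:
ν = 17 mm²/s, ρ = 1.27 kg/m³.

## Ventilator and leak

Defaults are the clinical prescription: f = 10 Hz, V_T = 2.0 ml/kg,
I:E = 1:2 (period 100 ms, inspiration 33.3 ms), PEEP = 8 cmH2O
(0.7845 kPa; 1 cmH2O = 0.0980665 kPa, converted once at the configuration
boundary), FiO2 = 0.35.  Inspiratory flow is a half-sine,
`Q(t) = Q_peak sin(π t/t_insp)` with `Q_peak = π V_T/(2 t_insp)` so the
inspiratory integral is exactly V_T; the expiratory source is zero — during
expiration the Y-piece is held at PEEP and flow develops freely from the
regional mechanics.  The ventilator never applies active (negative) flow.

The endotracheal tube is uncuffed, 3.0 mm inner diameter; the 100 mm length
is a declared default (a typical neonatal oral tube) and its resistance is
laminar.  The leak between pharynx and tube wall is modelled as a branch
from the Y-piece to ambient, by default a **linear resistance calibrated by
bisection** so that the per-cycle leak volume is 16% of the supplied tidal
volume — the observed clinical leak fraction is used as a calibration
anchor because the image-derived leak area of the patient is unpublished.
An orifice law (`Q = sign(p) A sqrt(2|p|/ρ)`) is available for sensitivity
studies.  Since PEEP keeps the opening pressure positive, leak flows in both
phases.  Calibration measures the fraction on the same cycle horizon as the
production run.

## Network flow solver

The tree is an electrical-analogue network: nodes at the Y-piece, the
tube/trachea junction and every segment's distal end; resistive branches
(tube, segments; optional per-branch inertance ρL/A, off by default since
the terminal closure has none); terminal Thevenin branches from the closure;
the leak branch.  Each time step solves one sparse nodal-conservation system
(LU-prefactored per phase) for all pressures and flows simultaneously.

Terminal capacitors advance by the trapezoidal (Crank–Nicolson) rule,
consistent with the trapezoidal `ΔV` integration of the standalone closure
operator; the first step after each phase switch uses implicit Euler because
the boundary-condition change makes branch flows discontinuous there.  Both
rules are A-stable on this stiff R-C network.  Default step: dt =
t_insp/200 (167 µs), with step counts snapped so steps land exactly on the
phase boundaries; a warning is raised above t_insp/50.  Initial condition:
all `ΔV^i = 0` (lung at the PEEP-equilibrated FRC).  Volume bookkeeping uses
quadrature matching the capacitor update, so the closure
`cumulative inlet − cumulative leak − Σ ΔV^i = 0` holds to round-off at
every step.  Against the closed-form single-compartment response the solver
is accurate to < 1e-3 (max error relative to peak volume) at the default
step.

**Diagnostics on the solution.**  Steady state is the first cycle k ≥ 2 with
`|EEV_k − EEV_{k−1}| < 0.02 V_T` (EEV = end-expiratory volume).  Pendelluft
events are time samples where two sibling segments carry opposite-signed
flows, both exceeding 2% of the peak recorded inlet flow (a threshold above
numerical noise and below the physiological signal).  A perfectly symmetric
homogeneous lung produces none; the patchy-compliance default produces them
predominantly in the last third of inspiration, when the prescribed inflow
wanes and regions of unequal time constant exchange gas directly.

## Oxygen transport

Oxygen volume fraction Φ obeys `∂Φ/∂t + u ∂Φ/∂x − D ∂²Φ/∂x² = 0` on every
segment with the per-segment plug velocity `u = Q/A` from the flow solution
(one-way coupling) and molecular diffusivity D = 0.219 cm²/s.  A Taylor-type
dispersion multiplier exists but defaults to 1 (the printed equation is
solved with the molecular coefficient).  Discretisation: explicit
first-order upwind finite volumes (20 cells per segment), central
within-segment diffusion, sub-cycled to CFL 0.9 inside each flow step.

* **Inlet** (top of the trachea): Φ = FiO2 = 0.35 on distal-ward inlet flow,
  free outflow otherwise.  The tube and Y-piece are outside the transport
  domain: at cycling steady state the tube lumen is flushed with fresh gas,
  and including its volume would double-count circuit dead space that the
  reference model resolves separately.
* **Junctions**: perfect instantaneous mixing in a zero-volume node with
  fluxes apportioned by volumetric flow — the declared 1D surrogate for 3D
  radial mixing.  No diffusive flux crosses a node.
* **Outlets** (generation 7): zero-gradient.  Oxygen leaving an outlet is
  consumed (never re-enters with a different composition); gas re-entering
  during expiration carries the boundary-cell concentration, the discrete
  reading of ∂Φ/∂n = 0.

The scheme is locally conservative; the per-cycle budget (inlet influx −
proximal return − outlet efflux − storage change) closes to round-off and is
reported as an audit.  The proximal return is labelled "leak efflux": with
the tube outside the domain, gas returned toward the circuit and gas lost
through the leak cannot be separated.  The initial field is room air
(Φ = 0.21, configurable); under upwind/CFL the discrete field respects the
maximum principle between 0.21 and 0.35.

**Delivery classification.**  Per terminal, the first time its distal cell
exceeds Φ = 0.25: *direct* within the first inflation, *delayed* within a
later recorded cycle, *unreached* otherwise.  Because V_T (1.52 ml) is below
the dead space (1.67 ml), bulk convection alone cannot reach the outlets in
one breath; terminals on short root-to-leaf paths (asymmetry) plus axial
diffusion and junction mixing produce the direct group, reproducing the
observation that regions close to the major airways are ventilated directly
while distal regions are supplied over subsequent cycles.

## Flow-regime localisation

A 0D model resolves no turbulence.  Each segment is classified by its
peak-cycle Reynolds number `Re = 4|Q|/(π d ν)` against declared thresholds
(laminar < 500, transitional 500–2000, turbulent-prone ≥ 2000 — classical
pipe-flow values, configurable and echoed in every report), alongside the
Womersley number `α = (d/2)√(2πf/ν)` of the oscillatory regime.  At the
clinical settings the trachea and main bronchi are transitional
(Re ≈ 1.5·10³) while every segment of generation ≥ 6 is laminar
(Re ≲ 10²), matching the reported localisation of turbulence to the large
airways and laminar flow beyond roughly generation six.

## Known limitations

* **Steady-state onset.**  With the calibrated morphometry and Poiseuille
  resistances, the model's total resistance is ≈ 5.5·10⁻³ kPa·s/ml
  (≈ 56 cmH2O·s/L — clinically realistic for a ventilated BPD preterm),
  giving τ = R·C_rs ≈ 115 ms.  Under the strict 2%-of-V_T criterion the
  end-expiratory volume therefore settles around cycle 9, not after the
  fourth inflation as the reference 3D anatomy does; reaching cycle 4 at
  10 Hz would require τ ≈ 60 ms.  The reference model's regional R_eq/C_eq
  values are unpublished, so the reduced model keeps its physiologically
  defensible defaults rather than tuning resistance to the reported onset.
  The volume trajectory is qualitatively identical (rising over the first
  inflations, then visually stationary).
* The exact timing of specific pendelluft sites (e.g. 32 ms into
  inspiration at particular branches) and 3D-only mechanisms (λ2 vortex
  structures, asymmetric velocity profiles, true radial mixing) are
  geometry-specific and out of numeric scope; the reduction reproduces their
  existence, location class, and end-inspiratory character only.
* Resolved airways are rigid; no CO2 transport, no alveolar gas exchange or
  blood-side uptake, no collateral ventilation or alveolar-scale diffusion.
* The synthetic tree is regular (one asymmetry factor, optional jitter);
  real infant airways are irregular per branch.  Passing tests show the
  pipeline's behaviour under the stated statistical structure, not
  performance on real MRI-derived anatomy.

## Problem sizes and runtimes

Default runs used throughout: 6 cycles × 600 flow steps (dt = 167 µs) on
the 255-segment network (~1 s), oxygen transport on 5 100 finite-volume
cells with 1–4 CFL sub-steps per flow step (~1 s), leak calibration ≈ 12
bisection simulations (~8 s).  The full analysis sequence completes in well
under a minute on one CPU.
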