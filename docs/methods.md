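# Methods

## Model and assumptions

`csfna` models sodium exchange between four compartments of the rat brain:
blood (an infinite reservoir at fixed concentration), ventricular CSF and
subarachnoid CSF (each well-mixed), and brain tissue (a spherical shell
supporting radial diffusion). The geometry is idealized as three concentric
spheres whose radii follow from the compartment volumes; with the nominal
volumes (0.1, 1.1, 0.2 cm³) the tissue–CSF contact areas come out at
1.04 cm² (ventricular) and 5.47 cm² (subarachnoid), consistent with
anatomical estimates once rounded.

Assumptions worth keeping in mind:

- **Lumped barrier kinetics.** Each barrier's net transporter activity is a
  single influx and a single efflux permeability coefficient (cm/s).
  Transporter identity, saturation and regulation are outside the model.
- **Instant tissue–CSF equilibration.** The ependymal and pial surfaces are
  given contact permeabilities of 10⁶ cm/s, so ISF sodium at the interfaces
  tracks the adjacent CSF concentration on a sub-second timescale. This is
  a modelling statement ("no rate-limiting resistance"), not a measurement.
- **Constant distribution factor.** Tissue sodium content (mol/g) converts
  to ISF concentration by a fixed factor f_d = 0.34 ml/g; intracellular and
  extracellular sodium stay in their baseline proportion throughout.
- **No convective ISF flow** (glymphatic transport), no water fluxes or
  volume changes, no potassium/chloride coupling, constant CSF production
  Q_csf routed ventricles → subarachnoid space → blood.

## Steady-state calibration

The two efflux permeabilities are *dependent* parameters. At t = 0 the CSF
and tissue are equilibrated (C_v = C_s = C_csf0, C_br = f_d·C_csf0), the
contact-surface exchanges and diffusion vanish, and zeroing the ventricular
and tissue balances gives

    P'_BCSFB = (P_BCSFB·A_BCSFB·C_blood − Q_csf·C_csf0) / (A_BCSFB·C_csf0)
    P'_BBB   = P_BBB·C_blood / C_csf0

(6.897×10⁻⁷ and 1.352×10⁻⁷ cm/s at nominal values). The feasibility margin
of the first expression is razor-thin at nominal physiology: the influx
term exceeds the bulk-flow drainage by only 1.9%. Consequences of this are
discussed under "Sampling" below. The public `calibrate_effluxes` raises on
a negative implied efflux by default; `strict=False` returns the signed
value, which still makes the initial state an exact stationary point (the
total ventricular loss coefficient P'A + Q = P·A·C_blood/C_csf0 stays
positive, so stability is unaffected).

A consistency check on the calibration: the implied first-order rate
constant for tissue-to-blood sodium loss is P'_BBB·A_BBB/f_d (the division
by f_d is the dimensionally consistent form, 1/s). With the distribution
factor at its unrounded derivation 50/145 ml/g this is 5.49×10⁻⁵ s⁻¹, the
right order against tracer-efflux measurements.

## Discretization and solver

The radial domain [r_i, r_o] carries n_r uniformly spaced nodes. The
diffusion operator is discretized in conservative finite-volume form: node j
owns the shell between the midpoint faces, and the diffusive exchange across
a face is 4π·λ·D·r_face²/(f_d·h)·ΔC (mol/s). The boundary exchange rates
Q_v, Q_s (mol/s, positive = CSF → tissue) are deposited into the half-cell
shell masses adjacent to each interface. With this choice the
mass-weighted row sum of the system matrix telescopes exactly, and the
tests assert discrete global sodium balance at every step to 10⁻⁸ of total
content.

Time stepping is backward Euler on the FULL coupled unknown vector
(C_v, all C_br nodes, C_s) — one LU-factored dense solve per step, with the
factorization reused because the system is linear and time-invariant.
Operator splitting is deliberately avoided: the contact-surface terms have
rate constants up to ~10⁸ s⁻¹, and any scheme that updates the CSF and
tissue blocks separately destroys the calibrated steady state.

Two numerical details matter at this stiffness:

- **Deviation form.** The state is integrated as u = u0 + δ with the source
  term M·u0 + b evaluated analytically (at the uniform equilibrated state
  the exchange and diffusion terms vanish identically, leaving only the
  barrier/bulk-flow imbalance). Assembled naively, the ~10⁸-magnitude
  coefficients leave a rounding residual that moves the state by ~10⁻⁸ of
  itself per step; in deviation form a correctly calibrated baseline is a
  fixed point to machine precision.
- **Iterative refinement.** cond(I − dt·M) ≈ 10⁹, so each solve gets one
  refinement pass; perturbed trajectories are then accurate to ~10⁻⁵
  relative at dt = 1 s against exact exponential integration.

Defaults: n_r = 61, dt = 1 s for single experiments; n_r = 31, dt = 10 s
for sensitivity sweeps. The sweep grid was checked by refinement (n_r 31→61,
dt 10→2): the Sobol indices move by less than 0.001, far below estimator
noise. Observed convergence orders are ~1.0 in time and ~2.0–2.3 in space,
estimated from successive-solution differences (three-grid Richardson);
comparing against a single fine reference would bias a first-order scheme's
apparent order to log₂(7/3) ≈ 1.22 and is avoided.

Verification uses two independent oracles on the same semi-discrete system:
an adaptive stiff method-of-lines integration (BDF; tolerances chosen so it
completes in seconds — at rtol ≤ 1e-9 the error controller thrashes against
the stiff boundary modes) and an exact matrix-exponential integrator,
cross-validated against an eigendecomposition route to 3×10⁻⁷. All four
canonical ±20% experiments agree with the oracles within 0.1% at all saved
times.

## Output functionals

Three scalars summarize a run over a horizon T: the percent change of the
time-averaged ventricular or subarachnoid concentration (trapezoid in
time), and the percent change of volume-integrated brain sodium at t = T
(trapezoid in radius, weighted by 4πr²). The brain baseline C_br(0)·V_b is
evaluated under the *same* radial quadrature as the endpoint integral so
that the ratio is exactly 1 at steady state; mixing an analytic volume with
a trapezoid integral would inject an O(h²) ≈ 10⁻⁴ spurious "change", larger
than genuine 1-minute responses.

The interface flux study uses the per-unit-area flux deviations
P_vb·λ·(C_v − C_br(r_i)/f_d) and the analogous subarachnoid expression;
q_v and q_s are their time-averaged absolute values and the reported
quantity is the ratio q_v/q_s. Per-area is the form in which the
ventricular interface dominates (the subarachnoid interface has ~5.5× the
area, so *total* flux ordering is reversed); `interface_fluxes` exposes
both conventions.

## Global sensitivity analysis

**Input space (18 dimensions).** Twelve independent physiological
parameters uniform within ±25% of nominal; C_blood and the shared initial
CSF concentration C_csf0 uniform within ±5%; and four pathophysiological
multipliers uniform in [0.5, 1.5]. The multipliers act on each sampled
subject's *own* recalibrated permeabilities — every subject is first placed
at its own steady state, then disturbed. With identity multipliers every
output is therefore exactly zero: physiological spread alone carries no
signal, and the analysis isolates the pathophysiology.

**Signed calibration during sampling.** Because the nominal feasibility
margin of the BCSFB efflux calibration is 1.9%, roughly half of the sampled
subjects imply a (slightly) negative efflux permeability. Redrawing or
excluding them would truncate the input distribution, correlate the inputs
and invalidate the Saltelli estimators, so the signed value is kept (the
subject remains stationary and stable; the term simply reverses direction)
and the count is reported in the run metadata (~48% of draws, as expected
from the margin). This is a structural feature of the published parameter
ranges, not a numerical artifact.

**Absolute-value outputs.** Each percent-change output is a deviation from
the subject's own baseline and takes either sign (e.g. the brain response
is, to leading order, proportional to the *difference* of the two BBB
multipliers). Sensitivity indices are computed on |percent change|: the
question asked of the variance decomposition is which barrier controls the
*magnitude* of the disturbance. For a signed output the four multiplier
total-effects would be forced to sum to exactly 1 (the model is linear in
the multiplier deviations with zero baseline), which contradicts the
strongly interactive landscape this analysis is designed to resolve; the
absolute value is what makes the two symmetric BBB multipliers each carry a
total effect near 0.8 at short horizons.

**Estimators.** Scrambled Sobol' base points in 2k dimensions split into
the A/B matrices of a Saltelli radial design (N(k+2) model runs);
first-order indices by the Saltelli-2010 estimator, total effects by
Jansen; 95% confidence intervals by bootstrap over the base sample (the
variance is re-estimated per replicate). Inputs with total effect below
0.01 are screened as non-influential, optionally using the upper bootstrap
bound. The estimators are validated against closed-form decompositions
(single-input passthrough, additive linear functions, and the Ishigami
function at a = 7, b = 0.1, whose analytic indices S₁ = 0.3139,
S₂ = 0.4424, S_T3 = 0.2437 fall inside the bootstrap intervals at
n_base = 4096).

**Problem sizes.** Reported sensitivity runs use n_base = 2048
(40,960 simulations, ~2 min); at n_base = 1024 the Monte-Carlo error on a
total-effect index is about ±0.01 and doubles the base sample halves it.
The landscape (three outputs × seven horizons from 1 min to 3 h) comes from
a single simulation per subject to the longest horizon. The flux-ratio
survey uses 2,000 plain uniform draws over the same input space; the
fraction of subjects with q_v/q_s > 1 is the reported majority statistic
(~0.95 at 2 h).

## What the generator does and does not emulate

The sampled "subjects" emulate inter-animal variability and measurement
uncertainty as independent uniform ranges around one nominal rat, plus a
migraine-like barrier disturbance as a step change held constant for the
experiment. Real physiological parameters co-vary (e.g. volumes scale
together), barrier disturbances evolve in time, and CSF production itself
responds to choroid-plexus sodium transport — none of which is represented.
Passing tests therefore certify the transport model, calibration, solver
and estimator machinery under the stated study conditions; they do not
certify predictions for any individual animal or for triggers that violate
the constant-disturbance assumption.

## Known limitations

- Spherical-shell geometry; no realistic ventricular anatomy.
- The percent-change outputs make the analysis insensitive to physiological
  parameters *by construction* (each subject is its own control); questions
  about absolute concentration variability need a different output.
- Sobol indices computed on |output| cannot be compared directly against
  indices computed on signed outputs.
- Total-effect indices are Monte-Carlo estimates; at n_base = 2048 the
  seed-to-seed spread is roughly ±0.01–0.02 on indices near 0.9 (heavier
  for the strongly skewed absolute-value outputs than Gaussian intuition
  suggests), and the bootstrap intervals reported with every run are the
  honest measure of that noise.
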