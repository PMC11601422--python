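# Methods

This note documents the models implemented in `nmskit`, the assumptions
behind them, the defaults that matter, what the synthetic-data generator
does and does not emulate, and the numerical choices made where the design
was genuinely open.

## Mechanics core

Models are trees of rigid segments rooted at a fixed `ground` segment.
Mechanics are planar (sagittal): a segment pose is an angle about z plus a
2-D origin; joints are pins (optionally "oblique" — the stored 3-D axis is
projected onto z, scaling the effective rotation) and a 3-DOF planar root
joint (two translations in ground axes plus a rotation). A 6-DOF root type
is reserved in the data model but has no dynamics implementation.
Translational coordinates are restricted to ground-attached root joints so
that their world directions are configuration-independent; this covers
every model the toolset constructs (planar root + pin chains), including
the extracted foot models.

Pose kinematics are propagated with first and second time derivatives in
closed form (chain rule on the planar pose composition), so accelerations
of any segment-fixed point are exact. Inverse dynamics projects the
Newton–Euler body forces onto coordinate directions with geometric
Jacobians (d'Alembert):

    tau_j = sum_b [ m_b (a_b - g) . J_bj + I_b phidd_b jphi_bj ] - Q_ext,j

The Jacobians come from central differences of the exact pose map
(eps = 1e-6; error ~1e-10 — verified against the closed-form pendulum).
The joint-space mass matrix is assembled from the *same* Jacobians
(M = Σ m JᵀJ + I jφᵀjφ), so the inverse-dynamics / forward-dynamics round
trip is consistent by construction; the measured duality error on random
trajectories is ~1e-8, dominated by the linear solve.

Generalized forces at a ground-attached root are the residual loads; they
vanish exactly when motion and external loads are dynamically consistent.

### Muscle geometry

Muscle paths are not modeled geometrically. Each muscle declares a
polynomial moment arm r_j(q_j) per spanned coordinate, and its
muscle-tendon length follows as
l_mt(q) = l_ref − Σ_j ∫₀^{q_j} r_j(s) ds (closed form for polynomials),
which keeps moment arms and lengths analytically consistent
(r_j = −∂l_mt/∂q_j — checked by finite differences in the suite). This is
a differentiable stand-in for a muscle-analysis preprocessing step;
via-point or wrapping-surface paths are out of scope.

## Signal processing

Motion and ground-reaction channels: zero-phase (forward–backward)
4th-order Butterworth low-pass at 7/tf Hz, where tf is the cycle period.
EMG: 40 Hz high-pass, demean, rectify, low-pass at 3.5/tf Hz, then
normalization. The normalization divides by the channel maximum over all
provided cycles, offsets the minimum to zero, and rescales to a unit peak —
i.e. min–max normalization, so every non-constant envelope spans exactly
[0, 1]. Cycles are resampled to 101 points; envelopes carry a 0.2 s pad
before the cycle start (≈18 samples on the standard grid) to leave room
for electromechanical delay. Whether the normalization maximum is per
trial or across trials is not settled usage; here it is across all cycles
passed to one `process_emg` call.

## Muscle-tendon model

Rigid tendon: tendon length is fixed at slack length, so fiber kinematics
are algebraic, with constant-thickness pennation
(fiber = sqrt((l_mt − l_ts)² + (l_opt sin φ_opt)²)). A guard at
l_mt = l_ts − 0.5 l_opt clamps and flags pathological samples.

Activation dynamics are first-order bilinear, backward-Euler discretized:
ȧ = (e − a)/τ with τ = τ_act when e > a else τ_deact
(defaults 0.015 s / 0.060 s, both calibratable). The activation
nonlinearity is a_nl = (e^{A a} − 1)/(e^A − 1) with A ∈ [−3, 0]
(A → 0 is the identity). The generator uses the exact algebraic inverses
of both maps, so synthetic EMG is consistent with its activations by
construction.

Curve shapes are fixed; only length/force parameters are calibrated:

* active force–length: Gaussian, peak 1 at normalized length 1, width 0.45;
* force–velocity: Hill hyperbola on the concentric side
  (f(0) = 1, f(−1) = 0, curvature a_f = 0.25) and a slope-matched
  exponential saturation to the eccentric plateau 1.4;
* passive: exponential, zero at or below optimal length, equal to F_max at
  normalized length 1.6;
* maximum contraction velocity fixed at 10 optimal fiber lengths/s.

## The four personalization tools

All tools minimize sums of standardized terms
((value − center)/max_allowable)², time-varying terms normalized by trial
duration, using scipy least-squares/SLSQP (gradient-based local descent,
mirroring standard practice in this literature).

**JMP** nests per-frame damped-least-squares IK (seeded from the previous
frame) inside a trust-region nonlinear least-squares outer problem over
joint-frame offsets, uniform segment scale factors (which consistently
rescale COM offsets, marker positions and joint frames), and marker
offsets (±30 mm default). Each frame carries its Δt quadrature weight, so
concatenated trials of different lengths weight time, not frames. A
warning (not an error) fires when a personalized coordinate moves through
less than ~25° of motion.

**MTP** design variables per muscle: electromechanical delay, activation
and deactivation time constants, nonlinearity A, EMG scale, and fractional
deviations of l_opt and l_ts from their initialized values (fractional for
conditioning; ±30% bounds). F_max is set once by initialization and held
constant. Terms: moment tracking per coordinate, parameter deviations from
initial values, normalized passive force above zero (allowable 0.02 F_max
by default), and grouped similarity (deviation from the group mean) of
normalized fiber-length trajectories, EMG scales and delays. Because the
problem has genuine local minima (an antagonist pair can trade length
changes), the optimizer supports seeded multistart (`n_restarts`, jitter
0.3 of the half bound range, best final cost wins); the recovery suites
use 4 starts. SynX factorizes the measured envelopes (NMF, or PCA with
signed weights and reconstruction clamped at zero; component count
defaults to the smallest reaching 95% VAF) and adds the unmeasured
muscles' component weights to the design vector.

**NCP** exploits that rigid-tendon muscle force is *linear* in activation
at fixed kinematics, so all terms are least-squares forms in the bilinear
product H·W and analytic gradients are available. The optimization (SLSQP)
runs over non-negative H and W with per-synergy equality constraints
Σ_m W[k,m] = C·M (C = 1; the value is observationally irrelevant because
outputs are re-normalized so each vector's largest weight is 1, with H
rescaled inversely — H·W invariant). Initial guesses come from NMF of the
MTP activations; in no-MTP mode a per-frame ridge moment fit provides the
prior and an activation-minimization term (allowable = the expected
activation magnitude, per tool usage guidance) makes the solution unique.
Shared bilateral vectors are implemented by aliasing one W block across
groups. Recovery comparisons are made on the reconstruction H·W (VAF),
which is invariant to the inherent NMF permutation/scale ambiguity.

**GCP** extracts a standalone two-segment foot model whose planar root
coordinates exactly reproduce the full-body hindfoot pose, re-expresses
experimental ground-reaction moments about the per-frame ground projection
of a midfoot superior marker, and runs staged nonlinear least squares
(vertical GRF → + horizontal GRF → + moments, each stage warm-starting the
next). Contact force per spring: penetration d = resting_length − height;
C¹ compact-support deflection smoothing s(d) = 0 below −h,
(d + h)²/4h inside the band, exactly d above +h (h = 1 mm default; chosen
over a softplus form because a calibration and collocation model needs
differentiability *and* an airborne foot must produce exactly zero
wrench); normal force k·s(d)·(1 + c·v_pen) clamped at zero (multiplicative
velocity damping, c default 1 s/m — the exact nonlinear damping law of
lab practice varies, this form is the documented choice here); tangential
force −f_n(μ_d tanh(v_slip/0.05) + μ_v v_slip), with dynamic friction off
by default and viscous friction calibratable. B-spline kinematic
deviations use n = max(5, ceil(duration·cutoff) + 4) uniformly spaced
cubic nodes (a stand-in rule; the node-count heuristic is this package's
own). A symmetry option shares one contact model across feet. Stiffness
smoothness is a 4-connected-neighbor difference penalty.

Identifiability note: with planar mechanics, springs in the same
across-width row are statically indistinguishable, so recovery studies use
single-row grids; the default grid remains 5×11.

## Treatment optimization

Hermite–Simpson direct collocation on a fixed mesh (default N = 25
intervals/cycle). The implicit-dynamics formulation (states q, v; controls
include accelerations a) makes the state derivative linear, so defect
constraints are exact linear constraints for fixed final time (nonlinear
only via h = T/N when the final time is free). Cost quadrature is
composite Simpson over nodes and Hermite-interpolated midpoints, which is
why the double-integrator benchmark reproduces the analytic cost 12 to
machine precision. Model nonlinearity enters through node-local path
constraints (kinetic consistency |ID_j − (τ_j + muscle moment_j)| ≤
0.01 N·m; root residuals ≤ 1 N / 0.1 N·m) and cost quantities; their
Jacobians are assembled from one finite-difference sweep over the per-node
inputs (n_states + n_controls + n_params evaluations regardless of mesh
size), and objective gradients are exact given those local sensitivities.
The NLP is solved by scipy's interior-point method (trust-constr) with
sparse constraint Jacobians. Iteration counts reported are its outer
iterations.

Variable bounds come from range scale factors: each state/control family
is bounded by its initial-guess range extended by rsf×(range width) on
each side (default 0.8; degenerate ranges get a 0.1-unit floor). Synergy
commands are additionally non-negative. Periodicity is enforced as bounds
on final-minus-initial states (0.05 rad positions, 10× for velocities),
excluding designated coordinates (e.g. forward root translation in
locomotion).

Tool variations: TO tracks coordinates, velocities, loads, ground
reactions and activations against experimental tables; VO tracks the
TO-found synergy controls plus the positions of torque-controlled and
uncontrolled coordinates (synergy-driven motion is *not* tracked — that is
the verification); DO starts from VO, keeps the VO-style tracking with
looser allowables, and adds goal terms, static parameters (plain NLP
variables passed to a user model-modification hook each evaluation, e.g. a
synergy-amplitude scale), user cost terms, and optionally a free final
time (tracked control tables are interpreted on normalized time τ = t/T).

Built-in design quantities: braking/propulsive impulses (∫ of the
negative/positive anteroposterior GRF), whole-body angular momentum about
the COM, joint mechanical energy generation/absorption, and a
two-coefficient activation/work metabolic model

    P = Σ_m [ α_act F_max l_opt a + α_work max(0, −v_fiber F_fiber) ] + basal

with α_act = 40 s⁻¹, α_work = 1 and basal = 1.2 W/kg body mass. This is a
deliberately simple, replaceable metabolic model; its absolute values are
not physiological predictions, but relative targets (e.g. "reduce the rate
by 10%") are well defined, which is how the design tool uses it.

## Synthetic data generator

`fixtures.make_demo_model` builds a planar two-legged model (pelvis root;
thigh, shank, hindfoot, toes per leg; 6 Hill muscles per leg with linear
moment-arm polynomials; 3+ markers per segment; spring-grid feet) with a
seeded ground-truth parameter set. `generate_trial` produces one cycle of
mutually consistent data:

* joint trajectories are finite harmonic series with exact derivatives —
  a rhythmic double-support motion (hip ~38°, knee ~49° excursions, ankle
  compensating so the feet stay nearly flat and the springs engaged);
* ground reactions come from the truth contact model along the motion;
* the pelvis trajectory is adjusted by Gauss–Newton over Fourier
  coefficients (8 harmonics; the Jacobian factorizes into frame-local
  sensitivities times analytic basis derivatives because inverse dynamics
  is frame-local) until root residuals are ~0.1 N / 0.003 N·m RMS;
* activations are H·W of truth synergies; EMG inverts the
  nonlinearity/dynamics/delay/scale chain exactly (up to ~3e-4
  resampling error from the delay shift — the reason "start at truth"
  tests assert 0.5% rather than 0);
* markers are forward kinematics plus optional Gaussian noise; the loads
  table for muscle-level tools is the truth muscle moments.

A separate single-foot stance generator produces a heel-to-toe rolling
loading for contact calibration, and a single-joint antagonist-pair
fixture (co-contraction gives the joint intrinsic stiffness) serves the
optimal-control tools.

What the generator does *not* emulate — and therefore what passing
recovery tests do not establish about real data: swing phases and impact
transients; soft-tissue artifact and systematic marker placement error;
EMG crosstalk and amplitude nonstationarity; 3-D (frontal/transverse)
mechanics; trial-to-trial variability. Recovery results certify the
estimation machinery, not field robustness.

Problem sizes used by the test and acceptance suites: 101-point single
cycles (51 for the contact-consistent trial), one leg for muscle-level
recovery, 7-spring single-row contact grids, 20–25 collocation intervals.
These are the package's desk-scale study conditions.

## Known limitations

* Planar mechanics only; the 6-DOF root is a data-model placeholder.
* No muscle path geometry (polynomial moment arms only), no compliant
  tendon, no fiber-type or fatigue models.
* One phase per optimal-control problem; no closed kinematic chains; no
  user-defined external loads as state functions.
* The metabolic model is intentionally minimal (see above).
* The XML settings and overlay dialects are this package's own; they
  follow the field's tool/term vocabulary but are not file-compatible with
  other software.
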