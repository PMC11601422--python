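# nmskit

Personalization of neuromusculoskeletal gait models and predictive
treatment simulation, in pure scientific Python on a built-in planar
multibody dynamics core.

Subject-specific ("personalized") neuromusculoskeletal models are the basis
of computational treatment design for movement impairments such as stroke
gait: generic musculoskeletal models calibrated to an individual's motion
capture, ground reaction and EMG data can predict how that individual's
movement would change under a candidate intervention. `nmskit` implements
the two halves of that workflow for researchers who want a self-contained,
testable implementation:

**Model personalization** — four optimizers that calibrate a model from
gait-lab-style data:

* **JMP** (joint model personalization): joint frame locations/orientations,
  uniform body scale factors and marker offsets, minimizing IK marker
  distance error `J = (1/(T·M)) Σ_f Δt_f Σ_m ‖p_model − p_exp‖²`.
* **MTP** (muscle-tendon personalization): EMG-driven calibration of
  Hill-model parameters. Each muscle follows the rigid-tendon Hill model —
  excitation `e(t) = s·EMG(t − d)` with scale `s` and electromechanical
  delay `d`, first-order activation dynamics
  `ȧ = (e − a)/τ(e, a)`, activation nonlinearity
  `a_nl = (e^{A a} − 1)/(e^A − 1)`, and tendon force
  `F = F_max (a_nl f_L(ℓ̃) f_V(ṽ) + f_P(ℓ̃)) cos φ` — and the optimizer
  adjusts delays, time constants, nonlinearity, EMG scales, and optimal
  fiber / tendon slack lengths so that `Σ_i r_ij(q) F_i` matches the
  inverse-dynamics joint moments. Muscle-Tendon Length Initialization
  places normalized fiber lengths on the ascending limb and fixes
  `F_max = σV/ℓ_opt` (σ = 60 kPa, volume from a height–mass regression).
  Synergy Extrapolation (SynX) estimates excitations of muscles without
  EMG from the PCA/NMF components of the measured channels.
* **NCP** (neural control personalization): muscle synergies `A = H·W`
  (non-negative synergy activations H and vectors W) fitted to joint
  moments and MTP activations under per-synergy vector-sum constraints,
  with output normalization (max weight of each vector = 1) and optional
  shared bilateral vectors.
* **GCP** (ground contact personalization): an elastic-foundation foot
  model — a grid of point springs under a two-segment (hindfoot + toes)
  foot with per-spring stiffness and shared damping, friction and resting
  length — calibrated in stages against vertical GRF, then horizontal GRF,
  then ground reaction moments (expressed about the ground projection of a
  midfoot marker).

**Treatment optimization** — a three-stage direct-collocation optimal
control layer (Hermite–Simpson transcription, implicit dynamics: states are
coordinate positions/velocities, controls include coordinate accelerations,
so defect constraints are linear):

* **TO** (tracking) finds a dynamically consistent motion reproducing
  experimental coordinates, loads, ground reactions and activations, under
  kinetic-consistency path constraints (|ID_j − controller moment_j| ≤
  0.01 N·m), root residual bounds (1 N / 0.1 N·m) and periodicity bounds.
* **VO** (verification) restarts from the TO solution tracking only the
  synergy controls (plus torque-driven joint positions) and should
  reproduce the motion without tracking it — confirming the problem is
  well posed.
* **DO** (design) adds treatment terms (e.g. a metabolic-rate target),
  static parameters with model-modification hooks, user cost terms and
  optionally a free final time, and predicts the modified movement.

All cost terms share one standardized form
`((value − center)/max_allowable)²`, so a deviation equal to its maximum
allowable error always contributes 1 (e.g. 1.1² = 1.21, 0.9² = 0.81) and
heterogeneous quantities can be summed meaningfully.

Every tool is testable end to end by **parameter recovery**: the
`nmskit.fixtures` module generates a planar two-legged demo model and fully
self-consistent synthetic trials (markers, EMG consistent with known
synergies and activation dynamics, ground reactions from the true contact
model, root trajectory adjusted so residual loads vanish) from known ground
truth.

## Worked example: muscle-tendon calibration by recovery

```python
import numpy as np
from nmskit.fixtures import FixtureConfig, make_demo_model, generate_trial
from nmskit.mtp import MtpSettings, MtpTrial, MuscleTendonPersonalizer

cfg = FixtureConfig(seed=0, with_contact=False, legs=("r",))
model, truth = make_demo_model(cfg)
trial = generate_trial(model, truth, cfg)

muscles = model.muscle_groups["leg_r"]
data = MtpTrial(coordinates=trial["coordinates"], loads=trial["loads"],
                emg=trial["emg_all"], cycle_duration=cfg.cycle_duration)

rng = np.random.default_rng(1)     # start ±10% away from the truth
guess = {m: truth["muscles"][m].replace(
    optimal_fiber_length=truth["muscles"][m].optimal_fiber_length
    * (1 + rng.uniform(-0.1, 0.1)),
    tendon_slack_length=truth["muscles"][m].tendon_slack_length
    * (1 + rng.uniform(-0.1, 0.1))) for m in muscles}

settings = MtpSettings(muscles=muscles,
                       tracked_coordinates=["hip_r", "knee_r", "ankle_r"],
                       free=("lengths",), passive_allowable=1e3,
                       deviation_allowable={"delay": 0.05, "tau": 0.02,
                                            "nonlinearity": 2.0,
                                            "scale": 0.5,
                                            "length_fraction": 10.0},
                       similarity_groups=[], n_restarts=4)
fit = MuscleTendonPersonalizer(settings).fit(model, [data], initial=guess)

for c, rmse in fit.diagnostics_["moment_rmse"].items():
    print(f"{c}: moment RMSE {rmse[0]*1000:.2f} mN*m")
for m in muscles:
    p, q = fit.params_[m], truth["muscles"][m]
    print(f"{m}: l_opt {p.optimal_fiber_length*1000:.2f} mm "
          f"(truth {q.optimal_fiber_length*1000:.2f}), "
          f"l_ts {p.tendon_slack_length*1000:.2f} mm "
          f"(truth {q.tendon_slack_length*1000:.2f})")
```

Output:

```
hip_r: moment RMSE 2.29 mN*m
knee_r: moment RMSE 3.11 mN*m
ankle_r: moment RMSE 2.31 mN*m
hip_flexor_r: l_opt 110.01 mm (truth 110.00), l_ts 140.00 mm (truth 140.00)
hip_extensor_r: l_opt 130.01 mm (truth 130.00), l_ts 149.98 mm (truth 150.00)
vasti_r: l_opt 99.91 mm (truth 100.00), l_ts 180.09 mm (truth 180.00)
hamstring_r: l_opt 109.97 mm (truth 110.00), l_ts 300.04 mm (truth 300.00)
gastroc_r: l_opt 60.00 mm (truth 60.00), l_ts 360.01 mm (truth 360.00)
tibialis_r: l_opt 69.90 mm (truth 70.00), l_ts 220.10 mm (truth 220.00)
```

The calibration reproduces the joint moments to a few mN·m and recovers the
length parameters of all six muscles to well under 1 mm from a ±10%
perturbed start — the EMG-driven moment data identify both Hill lengths.

## Command line

Each tool also runs from a single XML settings file
(`nmskit {jmp|mtp|ncp|gcp|to|vo|do} settings.xml`), reading models from the
declarative YAML model format, motion data from TRC/MOT/STO files, and
writing personalized properties into an osimx-style XML overlay with
independent `<MTPMuscleSet>`, `<RCNLSynergySet>` and
`<GCPContactSurfaceSet>` blocks.

## Layout

```
src/nmskit/
  tables.py       TRC / MOT / STO containers and readers/writers
  model.py        declarative planar model, exact pose kinematics, YAML I/O
  dynamics.py     inverse/forward dynamics (d'Alembert projection)
  kinematics.py   marker inverse kinematics
  signal.py       variable-cutoff filtering, cycle resampling
  muscle.py       EMG processing, activation dynamics, Hill model
  jmp.py / mtp.py / ncp.py / gcp.py     the four personalization tools
  collocation.py  Hermite–Simpson transcription (scipy trust-constr)
  treatment.py    TO / VO / DO, built-in design terms, metabolic model
  fixtures.py     demo model + self-consistent synthetic trial generator
  settings.py / overlay.py / runner.py / cli.py     XML interface + CLI
```

See `docs/methods.md` for the models, assumptions, parameter defaults and
known limitations.
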