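# emgelbow

EMG-driven modelling of elbow motion and a comparative evaluation of seven
muscle activation models — the candidate nonlinearities and first-order
dynamics that map neural drive u(t) (the processed surface-EMG envelope)
to mechanical muscle activation a(t).

The package is aimed at researchers in neuromusculoskeletal modelling and
wearable-device control who want to study, at desk scale, how the choice of
activation model trades estimation accuracy against optimization cost. It
contains the full modelling chain of a two-muscle (elbow flexor/extensor)
motion model, the inverse/forward optimization used to calibrate and compare
the activation models, and a synthetic cohort generator that emulates the
data-collection protocol so that every stage is testable with known ground
truth — no human data required.

## The model

**Signal chain.** Raw surface EMG (4000 Hz) is band-pass filtered
(Butterworth, order 2, 20–300 Hz, zero-phase), rectified, normalized by the
maximum-voluntary-contraction (MVC) extremes,
e_norm = (e − EMG_min)/(EMG_max − EMG_min), and low-pass filtered
(order 4, 3 Hz, zero-phase) to give the neural activation u(t) ∈ [0, 1].
Joint angle (100 Hz encoder) is upsampled, smoothed, and differentiated.

**Activation models.** Seven candidates map u(t) to a(t) ∈ [0, 1]:

| id | form | parameters |
|----|------|------------|
| 1 | a = (e^{A₁u} − 1)/(e^{A₁} − 1) | A₁ ∈ [−3, 0) |
| 2 | a = (A₁ᵘ − 1)/(A₁ − 1) | A₁ ∈ [0.05, 1) |
| 3 | piecewise ln/linear through a knot (u₀, a₀) | A₁ ∈ [10⁻⁴, 0.12], A₂ ∈ [10⁻², 10¹¹] |
| 4 | ȧ = (u/A₁ + (1−u)/A₂)(u − a) | A₁, A₂ ∈ [1, 70] ms |
| 5 | ȧ = (u − a)/A₁ if u ≥ a, else (u − a)/A₂ | A₁, A₂ ∈ [1, 70] ms |
| 6 | ȧ = (A₁u + A₂)(u − a) | A₁, A₂ ∈ [0.001, 0.070] |
| 7 | ȧ = (u − a)/Tₐ, state-dependent Tₐ | A₁, A₂ ∈ [1, 70] ms |

**Muscle contraction.** A Hill-type model with a rigid tendon:
F = (a·F_max·F_fl(L_M)·F_fv(L̇_M) + F_MEE(L_M))·cos φ, with a Gaussian
force–length curve, a Hill force–velocity curve whose eccentric branch is
blended for a continuous first derivative at zero velocity, a nonlinear
parallel-elastic spring, and constant-volume pennation
sin φ = L_Mo sin φ_o / L_M. Pooled flexor/extensor constants
(F_max = 2874.67 / 2397.12 N, etc.) ship in a defaults file.

**Skeletal dynamics.** One degree of freedom:
M_joint = I·θ̈ + M_p + M_g + Σᵢ rᵢ·Fᵢ, with damping-only passive torque
M_p = −b·θ̇ (b = 1 N·m·s/rad), gravity from Winter anthropometric
proportions, cylindrical forearm inertia, and tendon-excursion moment arms
r = −dL_MT/dθ.

**Optimization.** Per trial, the inverse stage finds the total muscle
torque that zeroes the equation of motion (free motion) and inverts it
through a single flexor-equivalent unit into the control activation
a_TI(t) ∈ [−1, 1]. The forward stage fits each activation model's bounded
parameters (shared by both channels) to minimize Σ(a_TI − a_TF)², where
a_TF = model(u_flexor) − model(u_extensor), by multi-start bounded
L-BFGS-B. Each fit reports the activation RMSE e_a, the muscle-torque RMSE
e_T (N·m), and the optimization time per data point T_dp (µs); summaries
and pairwise Kruskal–Wallis H tests compare models, motions, and parameter
counts.

**Synthetic cohort.** Virtual subjects perform the 13-trial protocol
(flexion–extension FE ×1; reversed-start EF120, 1-kg-loaded FEM,
random-pause FEP, and varied-start FES ×3 each) as minimum-jerk
trajectories. Ground truth is built by running the estimation chain in
reverse — trajectory → required torque → control activation → antagonist
split with baseline co-contraction → per-muscle inverse of the subject's
true activation model → neural drive — and raw EMG is band-limited Gaussian
noise amplitude-modulated by that drive.

## Worked example

`examples/05_fit_one_trial.py` generates one noiseless FE trial whose
ground truth is Model 6 with A₁ = 0.0260, A₂ = 0.0538, runs the inverse
stage, and fits all seven models:

```
trial FE, 1001 samples at 100 Hz; ground truth: Model 6, A1=0.0260, A2=0.0538
control torque range: -0.13 .. 3.64 N*m
model      ea        eT (N*m)   Tdp (us)   A1        A2
  1      1.90e-01    14.118       2.3      -0.01     -
  2      1.90e-01    14.118       2.5       0.99     -
  3      1.89e-01    14.083      37.4     0.0001  1e+11
  4      1.88e-01    14.031     165.2       0.07  0.07
  5      1.83e-01    13.665       8.1       0.07  0.001
  6      1.17e-09     3.342      20.9    0.02604  0.05377
  7      1.83e-01    13.667      10.5       0.07  0.001
```

The generating model recovers its own parameters to four decimals and
drives the activation error to numerical zero, while every other family is
orders of magnitude worse — on known-truth data the pipeline identifies the
true activation dynamics. The torque range (a few N·m) is what gravity and
damping demand of a slow unloaded elbow movement; Model 6's residual torque
error reflects the antagonist co-contraction that the single-unit inversion
cannot see. The one-parameter models (1, 2) show the smallest per-point
optimization times — the accuracy/cost trade-off the study quantifies.

The other examples walk through the signal chain (`01`), the activation
model zoo (`02`), the Hill-model landmarks (`03`), inverse dynamics (`04`)
and a scaled-down full study (`06`). A command-line interface wraps the
batch workflow:

```bash
elbow synth --subjects 6 --seed 42 --out cohort/
elbow run --cohort-dir cohort/ --out results/
elbow report --results results/
```

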