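# Methods

This note documents the models implemented in `emgelbow`, the choices made
where the design was genuinely open, and what the synthetic data can and
cannot show.

## Signal processing

All filters are bilinear-transform Butterworth designs applied forward and
backward (`scipy.signal.sosfiltfilt`), giving zero net phase at the cost of
squaring the magnitude response; stop-band attenuation therefore doubles in
dB relative to the nominal order. The chain is: band-pass 20–300 Hz
(order 2) on raw EMG, rectification, MVC normalization, low-pass 3 Hz
(order 4) to form the neural activation u(t); encoder angles are linearly
upsampled then low-passed at 3 Hz (order 4) before central-difference
differentiation.

Two consequences deserve mention. First, the MVC calibration extremes are
read from the **rectified, 3-Hz-smoothed** MVC recording (not from raw
peaks): single-sample spikes would otherwise set the scale. Because trial
and calibration recordings pass through the same filters, any filter gain
cancels in the normalization. Second, normalization is applied to the
rectified signal *before* envelope smoothing and is clipped to [0, 1];
instantaneous rectified samples routinely exceed the envelope-level MVC
maximum, so the recovered drive is systematically compressed at high effort
(about 20–30 % near u = 1). This is a property of MVC-normalized processing
itself, not of the synthetic data, and it is why envelope-recovery checks
are stated in terms of correlation rather than amplitude.

After synchronization, model computation runs at a configurable processing
rate (default 100 Hz, decimated from the 4000-Hz EMG grid). Every retained
signal is 3-Hz band-limited, so decimation to 100 Hz is alias-free, and the
optimization cost per trial drops by a factor of 40 relative to running at
the acquisition rate.

## Activation models

Models 1–3 are static maps evaluated sample-wise; all fix a(0) = 0 and
a(1) = 1 for every in-bounds parameter and are monotone in u. Model 3's
second parameter spans thirteen decades ([10⁻², 10¹¹]); it is represented
and optimized on a log₁₀ scale, and its curve is evaluated with
`expm1`/`log1p` so the near-linear limit (huge A₂) stays exact.

Models 4–7 are first-order ODEs integrated by fixed-step explicit Euler at
the processing rate. The drive sample uᵢ is held constant (zero-order hold)
over the step landing on sample i; a is clipped to [0, 1] after every
substep. When the macro step dt exceeds 20 % of the smallest time constant,
the step is automatically divided into 10 substeps (at 100 Hz and the 1-ms
lower parameter bound this keeps the stability number λ·dt ≤ 1). The
initial condition defaults to a(0) = u(0) — the fixed point shared by all
four ODEs — so short trials that begin at rest carry no startup transient.

Two structural facts about the model set matter for interpretation:

* Model 2 is Model 1 reparametrised (base A₁ = e^{Model-1 A₁}), and their
  parameter boxes map onto each other almost exactly. Fits of the two are
  numerically identical, and ranking tests must expect exact ties.
* Model 6's coefficients enter the relaxation rate directly
  (λ = A₁u + A₂) yet share the numeric box [0.001, 0.070] used for the
  time constants of models 4, 5 and 7. Its rate is therefore at most
  0.14 s⁻¹ — relaxation times of 7 s and up — making it dynamically very
  different from the genuinely fast models 4/5/7 (τ ≤ 70 ms), whose
  responses at 100 Hz are nearly quasi-static. This asymmetry is preserved
  deliberately: the parameter ranges are part of the study conditions.

**Euler-consistent inversion.** The synthetic generator needs the drive
that makes a model reproduce a target activation trajectory. Solving the
continuous relation u = f(a, ȧ) per sample leaves O(dt) residuals that a
slow model never forgets (errors decay at rate λ), so the generator instead
inverts the *discrete* integrator: for each step, a scalar solve (coarse
scan for a bracket, then bisection — the end state is not guaranteed
monotone in the drive for models 4 and 6) finds the drive that lands the
Euler macro-step exactly on the next target sample. Unreachable targets
saturate at u ∈ {0, 1} and the achieved state carries forward, so errors do
not accumulate. Integrating the returned drive reproduces the achieved
trajectory to solver precision.

## Musculotendon model

Rigid-tendon Hill model. The eccentric force–velocity branch uses the blend
constant c_d = V_max·A·(g_max − 1)/(A + 1); for the first derivative to be
continuous at zero velocity — the purpose of c_d — the concentric branch
must be (V_max + v)/(V_max − v/A), and that is the form implemented (the
alternative (V_max − v·A) denominator also passes through 1 at rest but has
a four-fold slope mismatch at v = 0 for A = 0.25). Velocities at or beyond
−V_max clamp the factor to zero with a warning. V_max scales with optimal
fibre length as 10·L_Mo per second.

Pennation uses the constant-volume relation sin φ = L_Mo·sin φ_o/L_M with
the argument clamped to [0, 1] and an explicit arcsin. The parallel-elastic
element is k₁(L_M − L_S) below slack and adds k₂(L_M − L_S)² above; k₁ =
10 N/m and k₂ = 1000 N/m² are soft defaults — no published values exist for
this two-muscle reduction — and the slack length policy L_S = L_Mo keeps
passive forces small near the optimum, so results are insensitive to them.

Length–angle geometry ships as cubic polynomials: fibre length L_M(θ)
stays within ±20 % of L_Mo over the 0–150° joint range (the force–length
factor then stays above 0.88), and the musculotendon path L_MT(θ) shortens
with flexion for the flexor and lengthens for the extensor. Moment arms are
the analytic tendon-excursion derivatives r = −dL_MT/dθ (flexor ≈ +2.5 to
+4 cm, extensor ≈ −2 to −3 cm), so positive muscle force yields a flexion
moment for the flexor; the sign lives in the moment arm, and forces stay
non-negative.

## Skeletal model

θ = 0 is full extension, flexion positive, radians internally and degrees
at file boundaries. The default posture is vertical (upper arm fixed,
forearm hanging at θ = 0), giving M_g = −g·sin θ·(m_fh·d_com +
m_held·L); a horizontal-plane mode zeroes gravity entirely. Forearm+hand
mass is 0.022 of body mass with its centre of mass at 0.682 of forearm
length (Winter's proportionality tables); inertia is a solid cylinder about
its end (radius 0.04 m) plus, for loaded trials, the held mass as a point
mass at the hand — the equation of motion's inertia term is the total
rotating inertia, so the held mass appears in both gravity and inertia.
Passive joint torque is damping only, M_p = −b·θ̇ with b = 1 N·m·s/rad.

## Optimization

The inverse stage exploits that the free-motion equation of motion is
linear in the total muscle torque: the closed form
M_TM = −(I·θ̈ + M_p + M_g) is exact, and a bounded per-sample scalar
minimization of the squared residual is kept as an independent cross-check
(the two agree to 10⁻⁶ N·m). Torque demands beyond both muscles' combined
capacity (F_max times peak moment arm) are clipped with a warning. The
control activation a_TI inverts that torque through a single
flexor-equivalent unit — with one net torque and two coupled antagonists
the per-muscle split is indeterminate, and the flexor-unit convention
resolves it; a_TI is clipped to [−1, 1], and samples with a vanishing
moment arm (never reached by the shipped geometry) are masked.

The forward stage minimizes the summed squared activation error with
L-BFGS-B on a unit-box parametrisation (linear per parameter, log₁₀ for
Model 3's A₂, so finite-difference steps are comparable across scales).
Five starts: the box centre, then four uniform draws from a seeded
generator; ties resolve to the lowest start index; tolerances are
ftol = 10⁻¹⁰, 200 iterations per start. Wall time is accumulated around
objective evaluations only, so T_dp measures optimization cost, not I/O.
T_dp is the one quantity that cannot be bit-reproducible; determinism
checks on results therefore exclude timing columns.

## Synthetic cohort

The generator manufactures data whose statistical structure matches what
the analysis assumes: six subjects (sampled anthropometry 55–90 kg,
1.55–1.90 m; forearm 0.146 of height; per-subject optimal fibre lengths
inside the shipped ranges), each performing FE ×1 and EF120/FEM/FEP/FES ×3
(13 trials; 78 datasets for 6 subjects). Trajectories are concatenated
minimum-jerk segments with 1-s dwells at the 120° turn-around and 0.5-s
subject-chosen pauses for FEP, at a nominal 30 °/s (8 s of movement per
240° repetition) — a deliberately slow speed at which the required
activations stay a few percent of maximum.

Ground truth runs the estimation chain in reverse, ending at the neural
drive. The antagonist split happens in activation space on top of a
constant per-subject baseline co-contraction c ∈ [0.05, 0.15] (typical
antagonist co-activation at the elbow): a_f − a_e = a_TI identically, so a
noiseless pipeline run can close the loop exactly. For slow ODE truth
models the agonist cannot shed activation as fast as the net demand falls;
the generator then moves the surplus to the antagonist instead (iterated
pair-tracking), mirroring the co-contraction bursts real subjects produce
at direction changes. Residual closure error is ~10⁻⁴ in activation.

Raw EMG is band-limited (20–300 Hz) Gaussian noise amplitude-modulated by
the drive, scaled so the rectified-and-smoothed envelope spans the MVC
calibration range (E|N(0, σ)| = σ√(2/π)), with a 2 % resting noise floor.
Only the 3-Hz envelope ever reaches the motion model, so no motor-unit
structure is simulated. MVC recordings (rest–ramp–4-s hold–release) are
synthesized per subject and the pipeline measures its calibration from
them, exactly as it would from real recordings.

What the synthetic data does **not** emulate: electrode placement
variability and shift, power-line interference, motion artefact, fatigue
and time-varying electromechanical delay, variable (rather than constant
baseline) co-contraction strategies, tremor, and the torque contribution of
muscles outside the two pooled groups. Passing tests therefore demonstrate
internal consistency of the estimation machinery and its statistical
pipeline under the study's design — not accuracy on real human data.

## Known limitations

* With a Model 6 ground truth, its required drive is jagged and often
  saturated (a consequence of its slow admissible rates), so the 3-Hz
  envelope cannot fully recover it; noisy-pipeline activation errors for
  the generating model are then of order 10⁻² rather than the noiseless
  10⁻⁴, and competitor models fare much worse. This separation is larger
  than one would expect between fast models fitted to slow human motions.
* The per-muscle forward torque estimate differs from the single-unit
  control torque by the co-contraction asymmetry term (the flexor and
  extensor gains differ by ~30 %); that gap, a few N·m at c ≈ 0.1, is
  precisely what the torque-error metric e_T measures and is irreducible
  within this architecture.
* Explicit Euler with zero-order-hold drive is first-order accurate;
  halving the substep roughly halves trajectory error. The Richardson
  check in the test suite pins this behaviour.
* Processor-usage and program-space metrics are hardware- and OS-dependent
  and are not implemented; T_dp is the portable cost metric.
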