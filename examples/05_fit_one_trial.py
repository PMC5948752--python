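"""Inverse-forward optimization of one synthetic trial.

Generates a single noiseless trial whose ground truth comes from Model 6,
runs the inverse stage (control torque and activation), then fits all seven
activation models and prints the study's three metrics for each.
"""

import emgelbow as eg
from emgelbow.config import RunConfig
from emgelbow.pipeline import evaluate_trial, process_trial

cfg = RunConfig(n_subjects=1, seed=1, emg_noise=False)
cohort = eg.generate_cohort(1, seed=1, emg_noise=False)
subj = cohort.subjects[0]
trial = cohort.trials[0]  # the FE repetition

ds = process_trial(trial, subj.cal_flexor, subj.cal_extensor, cfg)
inv, forward, _ = evaluate_trial(ds, subj, cfg)

print(f"trial {trial.motion_id}, {ds.n} samples at {ds.rate:.0f} Hz; "
      f"ground truth: Model {subj.truth.model_id}, "
      f"A1={subj.truth.A1:.4f}, A2={subj.truth.A2:.4f}")
print(f"control torque range: {inv.m_tm.values.min():.2f} .. "
      f"{inv.m_tm.values.max():.2f} N*m")
print("model      ea        eT (N*m)   Tdp (us)   A1        A2")
for model_id, fr in forward.items():
    a2 = f"{fr.spec.A2:.4g}" if fr.spec.n_params == 2 else "   -"
    print(f"  {model_id}     {fr.ea:9.2e}  {fr.et:8.3f}  {fr.t_dp_us:8.1f}"
          f"   {fr.spec.A1:8.4g}  {a2}")
# the generating model reaches an activation error orders of magnitude below
# the others and the lowest torque error: on self-generated data the fitting
# pipeline identifies the true activation dynamics
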