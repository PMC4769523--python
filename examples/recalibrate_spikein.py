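"""Train SEGREG on a spiked-in control and measure calibration accuracy.

Simulates a control library whose emitted qualities are systematically
miscalibrated (floor-score pessimism plus an underestimated background),
trains the per-group segmented regression on it, and compares the
frequency-weighted squared error (FWSE) of raw vs recalibrated scores on a
held-out library from the same run.  A lower FWSE means the scores track
the true error rates more closely.
"""

from segreg.evaluate import calibration_table, fwse
from segreg.recalibrate import combine_error_rates, train_model
from segreg.simulate import ErrorProfile, generate_templates, simulate_reads

control_seq, _ = generate_templates(0, 5000, 0.0, seed=42)
profile = ErrorProfile.legacy_basecaller()

print("Background-error arithmetic: a raw Q40 base over a 1e-3 background")
print(f"  has true quality {combine_error_rates(40, 1e-3):.2f} "
      "(the correction SEGREG should learn for such a run)\n")

training = simulate_reads(control_seq, profile, coverage=3000,
                          read_length=100, paired=True, seed=1)
model = train_model(training.observation_batch(control_seq), control_seq)
print(f"Trained {model.n_fitted} groups ({model.n_fallback} without enough "
      "well-populated quality bins fall back to raw scores)")

held_out = simulate_reads(control_seq, profile, coverage=800,
                          read_length=100, paired=True, seed=2)
batch = held_out.observation_batch(control_seq)
raw_fwse = fwse(calibration_table(batch))
recal = batch.with_qualities(model.recalibrate_batch(batch))
recal_fwse = fwse(calibration_table(recal))

print(f"\nHeld-out FWSE, raw qualities:          {raw_fwse:8.2f}")
print(f"Held-out FWSE, SEGREG-recalibrated:    {recal_fwse:8.2f}")
print("\nThe raw score miscalibration (dominated by accurate bases emitted "
      "at the\nfloor score) disappears once each (mate, cycle, base, "
      "context) group is\nmapped through its fitted segmented regression.")
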