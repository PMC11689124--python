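"""Estimate coherence, phase, gain and nGain for one synthetic recording.

Injects a known transfer (gain 0.79 cm/s/mmHg, phase +0.47 rad for the
mean-velocity component, plus component-specific values for the systolic and
diastolic series), runs the full beat -> spline -> Welch chain and compares
the point estimates at the 0.05 Hz pacing frequency with the injected truth.
"""

import cardiotfa as ct

bp = ct.simulate_bp_waveform(
    hr=90, forcing_freq=0.05, forcing_amp=10, duration=240, seed=11
)
truths = ct.default_transfer_truths("eucapnia", 0.05)
rec, truth = ct.apply_transfer(bp, truths, forcing_freq=0.05, noise_sd=0.0, seed=12)

points, _ = ct.analyze_recording(rec)
merged = points.merge(truth, on=["vessel", "component"])
cols = ["vessel", "component", "coherence", "phase_rad", "phase_true",
        "gain_cms_mmhg", "gain_true", "ngain_pct_mmhg"]
print(merged[cols].round(3).to_string(index=False))
print(
    "\nWith noiseless data, coherence sits at ~1.0 at the forcing bin and the\n"
    "estimated phase (rad) and gain (cm/s/mmHg) match the injected transfer to\n"
    "well under 1%; nGain is the gain re-expressed per 100 cm/s of that\n"
    "component's own mean velocity (%/mmHg)."
)
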