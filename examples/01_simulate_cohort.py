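"""Simulate a small squat-stand cohort and inspect its ground truth.

Builds four participants' recordings at one pacing frequency across the three
CO2 stages, then prints the per-beat BP levels of one recording and the
transfer parameters that were injected into its velocity channels.
"""

import cardiotfa as ct

spec = ct.CohortSpec(
    n_female=2, n_male=2, ssm_frequencies=(0.05,), duration=120, seed=7
)
recordings, truth = ct.generate_cohort(spec)

rec = recordings[0]
print(f"{len(recordings)} recordings "
      f"({spec.n_female + spec.n_male} participants x {len(spec.stages)} stages)")
print(f"first: {rec.participant} ({rec.sex}), {rec.stage}, "
      f"{rec.ssm_frequency} Hz pacing, {rec.duration:.0f} s at {rec.sample_rate:.0f} Hz")
print("\nsimulated per-beat BP levels (first beats):")
print(rec.truth_beats.head(5).round(2).to_string(index=False))
print("\ninjected transfer truths for this participant/stage:")
sel = truth.query(
    "participant == @rec.participant and stage == @rec.stage"
)
print(sel[["vessel", "component", "gain_true", "phase_true", "baseline_velocity"]]
      .round(3).to_string(index=False))
print(
    "\nEach velocity channel's per-beat systolic/diastolic/mean series equals\n"
    "baseline + gain x (BP component oscillation advanced by phase): these are\n"
    "the parameters the TFA pipeline is expected to recover."
)
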