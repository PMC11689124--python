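"""Detect beats and decompose a pulsatile recording into cardiac-cycle series.

Simulates one forced recording, detects pressure feet, decomposes every beat
into systolic/diastolic/mean values, screens for systolic artifacts and
summarizes the PETCO2 clamp quality.
"""

import cardiotfa as ct

rec = ct.simulate_bp_waveform(
    hr=90, sbp=120, dbp=80, forcing_freq=0.05, forcing_amp=10, duration=240, seed=3
)
rec.petco2 = ct.simulate_petco2(40.0, duration=240, sample_rate=rec.sample_rate, seed=3)

onsets = ct.detect_beats(rec.bp, rec.sample_rate)
table = ct.decompose_beats(rec.bp, onsets, rec.sample_rate)
table, corrected = ct.flag_and_correct_artifacts(table)
breaths = ct.extract_breath_peaks(rec.petco2, rec.sample_rate)

print(f"{len(table)} beats over {rec.duration:.0f} s "
      f"(mean HR {table['heart_rate'].mean():.1f} beats/min)")
print(f"systolic {table['systolic'].mean():.1f} mmHg, "
      f"diastolic {table['diastolic'].mean():.1f} mmHg, "
      f"mean {table['mean'].mean():.1f} mmHg")
print(f"artifact-corrected fraction: {corrected:.3%}")
print(f"{len(breaths)} breaths; PETCO2 peaks "
      f"{breaths.attrs['mean_peak']:.1f} +- {breaths.attrs['sd_peak']:.1f} mmHg")
print(
    "\nThe squat-stand forcing shows up as a +-10 mmHg swing of the beat-to-beat\n"
    "levels around their means; the breath peaks sit within ~1 mmHg of the\n"
    "40 mmHg eucapnic clamp target."
)
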