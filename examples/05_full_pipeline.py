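"""End-to-end pipeline on a reduced cohort, with artefacts written to disk.

Simulates 2 + 2 participants at 0.05 Hz pacing across the three CO2 stages,
runs beats -> TFA -> mixed models and prints the manifest reconciliation and
the phase results per vessel for the mean-velocity component.
"""

import tempfile
from pathlib import Path

import cardiotfa as ct

out = Path(tempfile.mkdtemp()) / "run"
cfg = ct.PipelineConfig(
    cohort=ct.CohortSpec(n_female=2, n_male=2, ssm_frequencies=(0.05,), seed=1),
    out_dir=str(out),
)
result = ct.run_pipeline(cfg)

man = result.manifest
print(f"config hash {man['config_hash']}, seed {man['seed']}")
print(f"{man['n_recordings']} recordings -> {man['n_beat_tables']} beat tables "
      f"-> {man['n_tfa_rows']} TFA rows -> {man['n_lme_cells']} model cells")

phase = result.lme_results.query("metric_name == 'phase' and component == 'mean'")
cols = ["vessel", "beta_hypocapnia", "beta_hypercapnia", "beta_sex_male", "lr_p"]
print("\nstage effects on mean-velocity phase (rad, vs eucapnia):")
print(phase[cols].round(3).to_string(index=False))
print(f"\nartefacts written under {out}")
print(
    "\nPhase rises under hypocapnia and falls under hypercapnia, mirroring the\n"
    "CO2 dependence built into the simulator's stage truths; with only 4\n"
    "participants the confidence intervals are wide, so treat this as a smoke\n"
    "run, not an inference."
)
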