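"""Fast-mode end-to-end replication run.

Generates a parameter-level cohort and decisive evidence stubs, pools family
evidence, runs both family comparisons, selects the winning model and runs
the permutation statistics — persisting each stage's artifact under
``replication_out/``.
"""

import dcmnet as d

report = d.run_replication(d.RunConfig(seed=1, outdir="replication_out"))

print(f"winning model: {report.winning_model}")
print(f"S1 families:   winner {report.s1_bms.winner}, "
      f"expected {report.s1_bms.expected_p.max():.3f}, "
      f"exceedance {report.s1_bms.exceedance_p.max():.3f}")
print(f"stim families: winner {report.stim_bms.winner}, "
      f"expected {report.stim_bms.expected_p.max():.3f}, "
      f"exceedance {report.stim_bms.exceedance_p.max():.3f}")
print(f"raw-significant couplings: {report.stats.significant()}")
print("artifacts in replication_out/ (space.json, parameters.csv, evidence_*.csv, ")
print("bms_*.json, stats.csv, report.json)")
# A "full" mode run replaces the evidence stubs with real inversions of every
# candidate model on simulated BOLD sessions (see RunConfig(mode="full")).
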