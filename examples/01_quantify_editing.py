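"""Quantify indel editing on a small simulated amplicon panel.

Simulates three Cas9 targets with 2,000 reads each, half carrying modeled
repair events, writes FASTQ + ground truth to a temp directory, runs the
full pipeline and prints the per-target report.  Reported percent indels
should sit within a fraction of a point of the 50% ground truth; the
quality/merge/assignment accounting shows where every read went.
"""

import tempfile

from crispamp import RunConfig, generate_specificity_dataset, run_pipeline

ds = generate_specificity_dataset(n_targets=3, reads_per_target=2000,
                                  n_insertions=50, n_deletions=50, seed=7)
with tempfile.TemporaryDirectory() as tmp:
    paths = ds.write(tmp, gzip_fastq=False)
    report = run_pipeline(RunConfig(r1=paths["r1"], r2=paths["r2"],
                                    targets=ds.targets))

print(report.per_target_frame()[
    ["target_id", "total_reads", "pct_indels", "pct_frameshift",
     "pct_templated_of_insertions", "pct_mmej_of_deletions"]
].to_string(index=False))
print()
acct = report.accounting.as_dict()
print(f"reads: {acct['input_reads']} in, {acct['pct_merged']}% merged, "
      f"{acct['pct_dimers']}% dimers, {acct['ambiguous']} ambiguous")
print("pct_indels = edited reads / analyzed reads per target; the "
      "mechanistic columns are percentages within insertions/deletions.")
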