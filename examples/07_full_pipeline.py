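"""One-call pipeline: simulate -> DE -> set tests -> enrichment -> TE -> report.

Equivalent to `ovage run --out pipeline_out --seed 7 --n-perm 2000` with a
smaller simulated gene count for speed.
"""

import json

from ovage import pipeline

cfg = pipeline.RunConfig(
    outdir="pipeline_out",
    seed=7,
    n_perm=2_000,
    sim_overrides={"n_genes": 2_000, "n_te_families": 50, "dot_gene_count": 30},
)
summary = pipeline.run_pipeline(cfg)

print(f"DE: {summary['differential']['n_significant']} significant "
      f"({summary['differential']['n_up']} up / {summary['differential']['n_down']} down)")
print(f"piRNA permutation p = {summary['gene_set_tests']['pirna']['permutation_p']:.4f}")
het = summary["positional_enrichment"]["heterochromatin"]
print(f"heterochromatin 2x2 {het['table']} -> chi2 = {het.get('chi2', float('nan')):.2f}")
print(f"TE global paired-t p: "
      f"{ {s: round(v['p'], 3) for s, v in summary['te']['global_paired_t'].items()} }")
print("\nfull machine-readable summary: pipeline_out/summary.json")
print("per-stage tables: de_results.tsv, te_family_results.tsv, ...")
print(json.dumps(summary["parameters"], indent=2))
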