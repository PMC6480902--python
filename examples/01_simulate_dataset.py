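"""Generate a synthetic egg-chamber aging dataset and write it to disk.

The generator draws negative-binomial counts for a two-strain, two-age
design with known injected effects: the piRNA set shifts up with age, the
mitochondrial / electron-transport-chain and eggshell sets shift down.
"""

from pathlib import Path

from ovage import synthetic_data as sd

cfg = sd.SimulationConfig(n_genes=2_000, n_te_families=50, seed=1)
result = sd.simulate_counts(cfg)
paths = sd.write_dataset(result, Path("example_data"))

print(f"samples: {list(result.counts.samples)}")
print(f"features: {result.counts.counts.shape[0]} "
      f"({(result.counts.feature_kind == 'te_family').sum()} TE families, "
      f"{(result.counts.feature_kind == 'mito').sum()} mitochondrial)")
print(f"heterochromatic genes: {int(result.truth['het'].sum())}, "
      f"dot-chromosome genes: {int(result.truth['dot'].sum())}")
for gs in result.gene_sets:
    print(f"gene set {gs.name!r}: {len(gs.members)} members")
print("\nwritten files:")
for name, path in paths.items():
    print(f"  {name}: {path}")
# The truth table (truth.tsv) holds the injected per-strain log2 age effect
# for every feature, so downstream estimates can be scored against it.
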