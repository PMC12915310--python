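"""Generate a complete synthetic strain set and look at its ground truth.

The generator emits every table the analysis consumes — a Yule tree, GCF
presence/absence with tree-structured signal, a pan-genome occurrence matrix,
gene-call/BGC coordinate tables and an LC-MS-style feature table whose
variance is split between medium, phylogeny, source and noise.
"""

from micromulti.simulate import EffectSizes, SimConfig, simulate_dataset

cfg = SimConfig(
    n_strains=15,
    n_features=300,
    effect_sizes=EffectSizes(sigma_medium=1.0, sigma_phylo=0.3, sigma_source=0.0, sigma_noise=0.3),
    seed=7,
)
truth = simulate_dataset(cfg)

print(f"strains:            {truth.gcf_presence.shape[0]}")
print(f"GCF presence:       {truth.gcf_presence.shape} (mean occupancy "
      f"{truth.gcf_presence.to_numpy().mean():.2f})")
print(f"occurrence matrix:  {truth.occurrence.shape} gene clusters x genomes")
print(f"gene calls / BGCs:  {len(truth.gene_calls)} / {len(truth.bgcs)}")
print(f"feature table:      {truth.feature_table.data.shape} samples x features")
print(f"ground-truth BGs:   {int(truth.bg_labels['is_bg'].sum())} genes inside BGC intervals")
# Occupancy near 0.5 reflects the symmetric gain/loss chain's stationary
# frequency; the BG count is what the coordinate join must recover exactly.
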