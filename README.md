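# micromulti

Integrative pan-genome / metabolome concordance analysis for bacterial strain
sets, built around the question natural-product researchers keep running
into: **when a collection of strains is fermented and profiled, is the
metabolome shaped by phylogeny, by where the strains were isolated, or by the
culture medium?**

The package implements the full analysis chain as a reusable, tested library:

- **Pan-genome partitioning and BG mapping** — classify gene clusters of an
  occurrence matrix as *core* (present in every genome), *accessory*, or
  *singleton* (exactly one genome); join antiSMASH-style BGC intervals onto
  gene calls to label biosynthetic genes (a gene is a BG iff it lies fully
  within a BGC's boundaries); summarize BGC novelty from percent similarity
  to known clusters; apply the ANI < 95% / dDDH < 70% species-delineation
  rule.
- **Profiles** — strain × GCF presence/absence from BGC family membership,
  MS2 filtering and TIC/log normalization of MZmine-style feature tables,
  pathway-category composition.
- **Distances and trees** — Jaccard and Bray-Curtis dissimilarities, UPGMA
  dendrograms with cophenetic matrices (scaled so a two-leaf tree reproduces
  its input distance), patristic distances from Newick phylograms.
- **Tree concordance** — cophenetic Pearson correlation and Baker's Gamma
  (Spearman rank correlation of per-pair merge levels) between two
  leaf-labeled trees, with leaf-permutation null models; Mantel tests between
  distance matrices. p = (1 + #{null ≥ obs}) / (n_perm + 1).
- **Ordination** — PCoA (Gower double-centering, negative eigenvalues
  reported and dropped) and one-way PERMANOVA,
  pseudo-F = (SS_B/(g−1)) / (SS_W/(n−g)) with label-permutation p-values.
- **Random-forest attribution** — bagged regression trees with out-of-bag
  R² = 1 − MSE_oob/Var(y) and %IncMSE permutation importance, one forest per
  grouping criterion (medium, clade, source), ranked by R².
- **Synthetic data** — a generator with known effect sizes: a Yule tree, GCF
  presence evolving as a two-state Markov chain down the tree, and a
  log-normal metabolome whose variance splits into orthogonal medium,
  phylogeny (Brownian trait × feature loading), source and noise components.
  Every stage of the pipeline is testable against this ground truth.

## Worked example

```python
from micromulti.distances import bray_curtis_matrix
from micromulti.ordination import pcoa, permanova
from micromulti.profiles import filter_ms2, normalize
from micromulti.simulate import SimConfig, simulate_dataset

truth = simulate_dataset(SimConfig(seed=5, n_features=300))
metab = normalize(filter_ms2(truth.feature_table), "log1p_tic")
d = bray_curtis_matrix(metab.data)
for grouping in ("medium", "clade", "source"):
    pm = permanova(d, metab.sample_meta[grouping], n_perm=999, seed=2)
    print(f"PERMANOVA {grouping:7s} pseudo-F={pm.pseudo_F:7.2f}  "
          f"R2={pm.r_squared:.3f}  p={pm.p_value:.3f}")
```

prints

```
PERMANOVA medium  pseudo-F=  62.29  R2=0.690  p=0.001
PERMANOVA clade   pseudo-F=   1.46  R2=0.144  p=0.176
PERMANOVA source  pseudo-F=   0.62  R2=0.022  p=0.485
```

Only the culture-medium grouping is significant: under the generator's
default effect sizes (σ_medium = 1.0 ≫ σ_phylo = 0.3, σ_source = 0) the
fermentation condition dominates the metabolome, while phylogeny and
isolation source do not reach significance — the qualitative verdict the
full pipeline condenses into its report.

The `examples/` directory holds one short script per capability
(`simulate_bundle.py`, `pangenome_partition.py`, `tree_concordance.py`,
`permanova_pcoa.py`, `forest_attribution.py`, `full_pipeline.py`); each
builds a small input, runs the method and explains its printout.

A thin CLI wraps the pipeline:

```bash
micromulti simulate --seed 7 -o bundle/        # write a synthetic input bundle
micromulti validate config.yaml                # fail-fast schema check
micromulti run config.yaml -o out/             # full run, TSV outputs + verdict
```

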