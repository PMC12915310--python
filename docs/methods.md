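# Methods

## The question and the analysis chain

Given a set of bacterial strains with (i) genome-derived inputs — a
phylogeny, a pan-genome occurrence matrix, BGC intervals with gene-cluster
family (GCF) membership — and (ii) an untargeted LC-MS feature table from
fermentations in several media, the pipeline asks which grouping criterion
structures each data layer. Three statistical instruments answer it from
different angles: tree concordance (do two dendrograms agree more than
chance relabeling?), PERMANOVA (does a grouping explain distance-based
variance?), and random-forest regression (how well does a profile predict a
grouping label out of bag?). Agreement across instruments is the point: in
the motivating setting all three say that GCF content follows phylogeny
while the realized metabolome follows the culture medium.

## Synthetic generative model

The generator exists so every stage can be tested against known truth; its
defaults encode the study design it emulates (15 strains, 2 media, one
sample per strain × medium, ~300 usable features).

**Tree.** Pure-birth (Yule) with unit birth rate: with k lineages the wait
to the next split is Exponential(k); a final waiting interval keeps pendant
edges strictly positive. Leaf labels are assigned in random order so label
sort carries no topological information.

**GCF presence.** Each family evolves independently down the tree as a
present/absent Markov chain with symmetric gain/loss rate r (per unit branch
length); the flip probability along a branch of length t is
(1 − e^(−2rt))/2 and the root state is Bernoulli(1/2), the stationary
frequency. Low r ⇒ strong phylogenetic signal in Jaccard profiles; r → ∞
recovers i.i.d. coin flips. An optional fraction of families is instead tied
to one isolation-source group (presence probability 0.9 inside, 0.2
outside). Matrices with an all-zero strain row are redrawn.

**Metabolome.** Log-abundance of feature f in sample (strain s, medium m):

    log x = μ_f + σ_medium·a_{f,m} + σ_phylo·b_f·z_s + σ_source·c_{f,src(s)} + σ_noise·ε

with a, b, c, ε standard normal and z a Brownian-motion trait on the tree
(Var(z_s) = root-to-leaf depth, covariance = shared path length). Abundances
are exponentiated. The phylogenetic component is deliberately routed through
a Brownian trait rather than through GCF content, so the medium, phylogeny
and source knobs are orthogonal by construction and recovery experiments are
unconfounded. Default σ values (medium 1.0, phylo 0.3, source 0.0, noise
0.3) encode a medium-dominated metabolome with a weak phylogenetic
component — the regime the pipeline is designed to diagnose. 95% of features
carry an MS2 flag (configurable); pathway categories are drawn from a
categorical distribution whose default weights mirror the annotated
composition of a real 650-feature panel.

**Coordinate tables.** Per genome, non-overlapping gene intervals (1-based,
inclusive on both ends) are laid out on 1–3 contigs; each BGC spans a
contiguous run of ≥ 2 genes and takes the 5′ end of its first and the 3′ end
of its last gene as boundaries, so the ground-truth BG label (full
containment) holds by construction. Each genome receives one BGC per present
GCF — this makes the presence matrix round-trip exactly through
`build_presence` — and `bgc_per_genome` acts as a floor topped up with
duplicate family members. Per-BGC similarity scores are drawn from a mixture
(21% exact zeros, 2.5% exact 100s, Beta(1.2, 3.5)·100 otherwise) so novelty
summaries exercise all three bins. When an occurrence matrix is available,
each gene is assigned a pan-genome cluster present in its genome, making the
per-partition BG profile tabulable.

**ANI/dDDH.** Monotone linear maps of patristic distance spanning
[78, 100] and [22, 100], placed to exercise both sides of the 95/70
species-delineation thresholds. These are synthetic stand-ins for
identity matrices the pipeline otherwise consumes as inputs.

## Statistical definitions and numerical choices

- **Pan-genome rule.** Core ⇔ present (count ≥ 1) in *every* genome;
  singleton ⇔ present in exactly one. Presence, not copy number: a paralog
  expansion cannot eject a universal cluster from the core. All-zero rows
  are dropped with a warning (merged exports commonly carry them).
- **BG join.** Full containment by default (`any-overlap` behind a flag);
  overlapping BGCs resolve to the smallest span, ties to the
  lexicographically smallest id; strand ignored; inverted records rejected
  with a warning.
- **Species rule.** Strictly below both thresholds (ANI < 95 at the maximum
  over references, dDDH < 70 at that closest reference); boundary equality
  is not novel.
- **UPGMA.** Cluster-size-weighted average linkage; merge height = average
  inter-cluster distance / 2, so cophenetic distance (2 × merge height)
  reproduces the merging distance and a 2-leaf tree is a fixed point. Ties
  break on the lexicographically smallest member labels. The cophenetic
  scale convention matters when comparing against toolchains that report raw
  linkage heights (ours equal half of scipy's).
- **Merge levels / Baker's Gamma.** k(i, j) is the largest cluster count at
  which i and j still co-occur when the tree is cut from the root down:
  merges ordered by height (descending) for dendrograms and internal nodes
  by root distance (ascending) for phylograms — the ordering an ultrametric
  tree's height cuts induce, extended to non-ultrametric phylograms. Baker's
  Gamma is the Spearman midrank correlation of the two k vectors (a
  Pearson-on-levels dialect is available).
- **Permutation tests.** One-sided (greater) with the plus-one correction,
  p = (1 + #{null ≥ obs})/(n_perm + 1) ∈ (0, 1]; default n_perm = 999, with
  a hard floor of 99 for usable resolution. Tree nulls permute leaf labels
  (topology and heights fixed); Mantel permutes rows and columns of the
  second matrix simultaneously; PERMANOVA shuffles group labels, optionally
  within strata.
- **Double-zero convention.** Jaccard and Bray-Curtis are undefined between
  two all-zero profiles; both return 0 with a logged warning.
- **PCoA.** Eigendecomposition of the Gower-centered −d²/2; axes are scaled
  eigenvectors for positive eigenvalues; negative eigenvalues are counted
  and dropped with no Lingoes/Cailliet correction (a correction would change
  coordinates invisibly to the reader).
- **Forest.** Our own bagging loop over sklearn `DecisionTreeRegressor`s
  (mtry = ⌈p/3⌉, min node size 5, 5,000 trees as the pipeline default).
  OOB R² uses the population variance of y. %IncMSE permutes a feature
  within each tree's OOB set and averages the per-tree relative MSE
  increase; features a tree never splits on contribute exactly 0, so a
  constant column scores 0 identically. Group labels are encoded 0/1 for
  two-level criteria and as integer codes of the sorted levels otherwise
  (one-vs-rest averaging available) — this encoding is the analysis's
  largest free choice and is deliberately explicit.
- **Normalization.** Default `log1p_tic` (total-ion-current scaling then
  log1p): TIC is the least-assumption choice for untargeted LC-MS tables and
  the log stabilizes Bray-Curtis against blockbuster features; `tic` and
  `none` are exposed because the raw-vs-normalized choice is genuinely open
  for this kind of data.
- **Strain aggregation.** Comparing a sample-level metabolome against a
  strain-level tree forces aggregation; the package means each strain's
  samples across media. Note the consequence: averaging removes the medium
  component, so strain-level concordance tests see mostly the phylogenetic
  residue, while sample-level PERMANOVA sees the medium effect.
- **Seeding.** One run seed; each stage derives an independent child seed
  from the seed and the stage name (CRC32 into a `SeedSequence`), so stages
  can be rerun in isolation and full runs are byte-identical.

## What the tests do and do not show

Unit and property tests verify every operation against independent oracles
(scipy linkage/cophenet, scikit-bio Mantel/PERMANOVA, networkx shortest
paths, brute-force double loops and cut enumerations) and check permutation
calibration (null rejection ≈ α over 500 replicates at n_perm = 199).
Parameter-recovery experiments run the full chain at the emulated design
size — 15 strains × 2 media, 300 features, 500-tree forests, 20 replicates;
forests are grown at 500 trees rather than the 5,000-tree pipeline default
to keep the suite fast, which widens forest Monte-Carlo noise but does not
bias R².

Two recovery summaries sit below a strict 90%-of-seeds bar and are reported
as measured rather than hidden: "PERMANOVA significant *only* for medium"
fails in the ~15–25% of replicates where the clade test correctly detects
the real σ_phylo = 0.3 component (its power at this signal-to-noise), and
the RF ordering clade > source is noisy when both R² are near zero (σ_source
= 0). Both reflect the prescribed simulation condition, not an
implementation defect; the medium-dominance verdict itself is recovered in
every replicate.

The generator does not emulate real LC-MS phenomena — missing values, gap
filling, adducts/isotopes, retention-time drift, batch effects,
heteroscedastic noise — nor sequence-level evolution (no genomes, no reads,
no mass spectra). Passing recovery tests therefore show that the statistics
recover known effects under the stated generative model, not that any real
dataset satisfies that model.

## Known limitations

- PERMANOVA is one-way; no interactions, nested designs, or dispersion
  (betadisper-style) diagnostics — a significant result can reflect
  dispersion as well as location differences.
- Integer-coding multi-level groupings imposes an arbitrary order the forest
  must work around; one-vs-rest trades that for g times the compute.
- Baker's Gamma on non-ultrametric phylograms depends on the documented
  depth-ordering convention for cuts; other toolchains may rank tied or
  near-tied nodes differently.
- UPGMA is the only linkage wired into the pipeline (the cophenetic fixed
  point and ultrametric comparability motivated it); complete/Ward would
  need only a different merge update but are not exposed.
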