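"""Synthetic multi-omics data generator with known effect sizes.

Emulates every input the concordance pipeline consumes — a strain phylogeny,
gene-cluster-family (GCF) presence/absence with tunable phylogenetic signal, a
pan-genome occurrence matrix, gene-call and BGC coordinate tables with
ground-truth biosynthetic-gene labels, an LC-MS-style metabolite feature table
whose variance is split between medium, phylogeny, source and noise, and
ANI/dDDH matrices — so every stage of the analysis is testable against known
truth without any external download.

The generative model for the metabolome puts the three grouping effects on
orthogonal axes by construction: the phylogenetic component enters through a
Brownian-motion trait simulated on the tree (per-strain value times a
per-feature loading), the medium component through an i.i.d. per-(feature,
medium) shift, and the source component through a per-(feature, source) shift.
Setting exactly one sigma above zero therefore makes exactly one grouping
recoverable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .phylo import leaf_labels, patristic
from .profiles import FeatureTable

__all__ = [
    "EffectSizes",
    "SimConfig",
    "SyntheticTruth",
    "simulate_tree",
    "simulate_gcf_matrix",
    "simulate_metabolome",
    "emit_coordinate_tables",
    "simulate_occurrence",
    "simulate_ani_ddh",
    "assign_clades",
    "simulate_dataset",
    "write_dataset",
    "BGC_CLASSES",
    "DEFAULT_CATEGORY_WEIGHTS",
]

BGC_CLASSES = (
    "Terpene",
    "NRPS",
    "RiPPs",
    "Type I PKS",
    "Other PKSs",
    "PKS-NRP_Hybrids",
    "NI-siderophore",
    "NAGGN",
    "Others",
)

# class frequencies loosely following the genus-wide BGC class proportions
_CLASS_WEIGHTS = np.array([0.22, 0.12, 0.12, 0.09, 0.11, 0.09, 0.03, 0.02, 0.20])

# pathway-category frequencies mirroring the annotated MS2 feature composition
DEFAULT_CATEGORY_WEIGHTS: dict[str, float] = {
    "alkaloids": 233 / 650,
    "amino acids and peptides": 164 / 650,
    "fatty acids": 117 / 650,
    "carbohydrates": 25 / 650,
    "terpenoids": 11 / 650,
    "polyketides": 10 / 650,
    "shikimates and phenylpropanoids": 6 / 650,
    "unknown": 84 / 650,
}


@dataclass(frozen=True)
class EffectSizes:
    """Standard deviations of the metabolome variance components (log scale)."""

    sigma_phylo: float = 0.3
    sigma_medium: float = 1.0
    sigma_source: float = 0.0
    sigma_noise: float = 0.3

    def __post_init__(self) -> None:
        for name in ("sigma_phylo", "sigma_medium", "sigma_source", "sigma_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for a full synthetic dataset.

    Defaults mirror the design of the real strain set: 15 strains fermented in
    two media (one sample per strain x medium), grouped by two isolation
    sources and a handful of phylogenetic clades.
    """

    n_strains: int = 15
    n_gcfs: int = 60
    n_features: int = 300
    n_media: int = 2
    n_sources: int = 2
    n_clades: int = 4
    tree_model: str = "yule"
    gain_loss_rate: float = 0.3
    effect_sizes: EffectSizes = field(default_factory=EffectSizes)
    genes_per_genome: int = 400
    bgc_per_genome: int = 20
    n_replicates: int = 1
    source_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains < 3:
            raise ValueError("n_strains must be >= 3")
        for name in ("n_media", "n_sources", "n_clades"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if self.tree_model != "yule":
            raise ValueError("only the pure-birth ('yule') tree model is supported")
        if self.gain_loss_rate < 0:
            raise ValueError("gain_loss_rate must be >= 0")
        if not 0 <= self.source_fraction <= 1:
            raise ValueError("source_fraction must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth plus every emitted table for one synthetic dataset."""

    tree: dendropy.Tree
    gcf_presence: pd.DataFrame
    group_assignments: dict
    effect_sizes: EffectSizes
    bg_labels: pd.DataFrame | None = None
    gene_calls: pd.DataFrame | None = None
    bgcs: pd.DataFrame | None = None
    occurrence: pd.DataFrame | None = None
    feature_table: FeatureTable | None = None
    ani: pd.DataFrame | None = None
    ddh: pd.DataFrame | None = None


def simulate_tree(n_strains: int, seed: int, birth_rate: float = 1.0) -> dendropy.Tree:
    """Simulate a rooted binary tree under a pure-birth (Yule) process.

    Waiting times between speciation events are Exponential(k * birth_rate)
    with k the current number of lineages; a final waiting interval is added
    after the n-th lineage appears so pendant edges are strictly positive.
    """
    if n_strains < 3:
        raise ValueError("n_strains must be >= 3")
    rng = np.random.default_rng(seed)
    tree = dendropy.Tree()
    tree.is_rooted = True
    root = tree.seed_node
    active = [root.new_child(edge_length=0.0), root.new_child(edge_length=0.0)]
    while True:
        k = len(active)
        dt = rng.exponential(1.0 / (birth_rate * k))
        for node in active:
            node.edge.length += dt
        if k == n_strains:
            break
        node = active.pop(int(rng.integers(k)))
        active.append(node.new_child(edge_length=0.0))
        active.append(node.new_child(edge_length=0.0))
    labels = [f"S{i + 1:03d}" for i in range(n_strains)]
    order = rng.permutation(n_strains)
    for node, j in zip(active, order):
        node.taxon = tree.taxon_namespace.new_taxon(labels[int(j)])
    tree.seed_node.edge.length = 0.0
    return tree


def _simulate_ctmc_presence(
    tree: dendropy.Tree, n_traits: int, rate: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Two-state symmetric CTMC down the tree; stationary frequency 1/2.

    Flip probability along a branch of length t is (1 - exp(-2 r t)) / 2; a
    rate of zero freezes the root state everywhere.
    """
    states: dict[int, np.ndarray] = {}
    labels = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            states[id(node)] = rng.integers(0, 2, size=n_traits)
        else:
            t = node.edge.length or 0.0
            p_flip = 0.5 * (1.0 - np.exp(-2.0 * rate * t))
            flips = rng.random(n_traits) < p_flip
            states[id(node)] = np.where(flips, 1 - states[id(node.parent_node)], states[id(node.parent_node)])
        if node.is_leaf():
            labels[node.taxon.label] = states[id(node)]
    strains = sorted(labels)
    return pd.DataFrame(
        np.vstack([labels[s] for s in strains]).astype(np.int64), index=strains
    )


def simulate_gcf_matrix(
    tree: dendropy.Tree,
    n_gcfs: int,
    gain_loss_rate: float,
    source_fraction: float = 0.0,
    group_assignments: dict[str, str] | None = None,
    seed: int = 0,
    p_in: float = 0.9,
    p_out: float = 0.2,
    max_resample: int = 100,
) -> tuple[pd.DataFrame, dict]:
    """Strain x GCF presence/absence with tree-structured signal.

    Each GCF evolves as a present/absent Markov chain down the tree with
    symmetric gain/loss rate; low rates give strong phylogenetic signal in the
    resulting profiles, very high rates approach independent Bernoulli(1/2)
    draws. A ``source_fraction`` of GCFs is instead tied to one randomly
    chosen isolation-source group (presence probability ``p_in`` inside it,
    ``p_out`` outside). Matrices with an all-zero strain row are redrawn.
    """
    if gain_loss_rate < 0:
        raise ValueError("gain_loss_rate must be >= 0")
    if not 0 <= source_fraction <= 1:
        raise ValueError("source_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    strains = leaf_labels(tree)
    n_source = int(round(source_fraction * n_gcfs))
    if n_source > 0 and not group_assignments:
        raise ValueError("source_fraction > 0 requires group_assignments")

    gcf_ids = [f"GCF{i + 1:04d}" for i in range(n_gcfs)]
    for _ in range(max_resample):
        mat = _simulate_ctmc_presence(tree, n_gcfs, gain_loss_rate, rng)
        mat.index = mat.index.astype(str)
        mat = mat.loc[strains]
        mat.columns = gcf_ids
        source_linked: dict[str, str] = {}
        if n_source > 0:
            chosen = rng.choice(n_gcfs, size=n_source, replace=False)
            groups = sorted(set(group_assignments.values()))
            src_vec = np.array([group_assignments[s] for s in strains])
            for j in chosen:
                g = groups[int(rng.integers(len(groups)))]
                p = np.where(src_vec == g, p_in, p_out)
                mat.iloc[:, int(j)] = (rng.random(len(strains)) < p).astype(np.int64)
                source_linked[gcf_ids[int(j)]] = g
        if (mat.sum(axis=1) > 0).all():
            return mat, {"source_linked": source_linked}
    raise RuntimeError(
        f"could not draw a matrix without all-zero strain rows in {max_resample} attempts"
    )


def _brownian_trait(tree: dendropy.Tree, rng: np.random.Generator) -> pd.Series:
    """One Brownian-motion trait on the tree; Var(leaf) = root-to-leaf depth."""
    D = patristic(tree)
    strains = list(D.ids)
    d = D.data
    # leaf depths from root
    depth = {}
    node_depth = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            node_depth[id(node)] = node_depth[id(node.parent_node)] + (node.edge.length or 0.0)
        if node.is_leaf():
            depth[node.taxon.label] = node_depth[id(node)]
    h = np.array([depth[s] for s in strains])
    cov = (h[:, None] + h[None, :] - d) / 2.0
    cov[np.diag_indices_from(cov)] = h
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(len(strains)))
    z = chol @ rng.standard_normal(len(strains))
    return pd.Series(z, index=strains)


def simulate_metabolome(
    truth: SyntheticTruth,
    effect_sizes: EffectSizes,
    n_features: int,
    seed: int,
    n_replicates: int = 1,
    has_ms2_rate: float = 0.95,
    category_weights: dict[str, float] | None = None,
) -> FeatureTable:
    """LC-MS-style feature table under an additive log-normal variance model.

    log-abundance of feature f in sample (strain s, medium m) =
    mu_f + sigma_medium * a_{f,m} + sigma_phylo * b_f * z_s
        + sigma_source * c_{f,src(s)} + sigma_noise * eps,
    with z a Brownian trait on the tree and a, b, c, eps standard normal.
    Abundances are exponentiated, so they are strictly positive.
    """
    rng = np.random.default_rng(seed)
    strains = leaf_labels(truth.tree)
    media = truth.group_assignments["media"]
    source_of = truth.group_assignments["source"]
    clade_of = truth.group_assignments["clade"]
    missing = [s for s in strains if s not in source_of or s not in clade_of]
    if missing:
        raise ValueError(f"strains missing group assignments: {missing}")
    if not media:
        raise ValueError("no media defined in group assignments")

    sources = sorted(set(source_of.values()))
    es = effect_sizes

    z = _brownian_trait(truth.tree, rng)
    mu = rng.standard_normal(n_features)
    a = rng.standard_normal((n_features, len(media)))
    b = rng.standard_normal(n_features)
    c = rng.standard_normal((n_features, len(sources)))

    rows, sample_ids, meta_rows = [], [], []
    for s in strains:
        for mi, m in enumerate(media):
            for rep in range(n_replicates):
                sid = f"{s}.{m}" + (f".r{rep + 1}" if n_replicates > 1 else "")
                eps = rng.standard_normal(n_features)
                si = sources.index(source_of[s])
                log_ab = (
                    mu
                    + es.sigma_medium * a[:, mi]
                    + es.sigma_phylo * b * z[s]
                    + es.sigma_source * c[:, si]
                    + es.sigma_noise * eps
                )
                rows.append(np.exp(log_ab))
                sample_ids.append(sid)
                meta_rows.append(
                    {"strain": s, "medium": m, "source": source_of[s], "clade": clade_of[s]}
                )

    feature_ids = [f"F{i + 1:05d}" for i in range(n_features)]
    data = pd.DataFrame(np.vstack(rows), index=sample_ids, columns=feature_ids)
    sample_meta = pd.DataFrame(meta_rows, index=sample_ids)

    weights = dict(category_weights or DEFAULT_CATEGORY_WEIGHTS)
    cats = list(weights)
    p = np.array([weights[k] for k in cats], dtype=float)
    p = p / p.sum()
    feature_meta = pd.DataFrame(
        {
            "mz": np.round(rng.uniform(100, 1200, n_features), 4),
            "rt": np.round(rng.uniform(0.5, 18.0, n_features), 3),
            "has_ms2": rng.random(n_features) < has_ms2_rate,
            "category": rng.choice(cats, size=n_features, p=p),
        },
        index=feature_ids,
    )
    return FeatureTable(data=data, feature_meta=feature_meta, sample_meta=sample_meta)


def emit_coordinate_tables(
    truth: SyntheticTruth,
    genes_per_genome: int,
    bgc_per_genome: int,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-genome gene-call and BGC interval tables with ground-truth labels.

    Coordinates are 1-based inclusive on both ends. Every BGC spans a
    contiguous run of >= 2 genes; its boundary is the 5' end of the first and
    the 3' end of the last gene of the run, so the ground-truth biosynthetic
    label (gene fully contained in a BGC) holds by construction. Each genome
    receives one BGC per GCF present in the truth matrix (so family presence
    round-trips exactly); ``bgc_per_genome`` acts as a floor, topped up with
    duplicate members of already-present families. When the truth carries an
    occurrence matrix, each gene is also assigned a pan-genome ``cluster_id``
    drawn from the clusters present in its genome, so the per-partition BG
    profile is tabulable downstream.
    """
    if genes_per_genome < 1 or bgc_per_genome < 0:
        raise ValueError("counts must be >= 1 (genes) / >= 0 (BGCs)")
    rng = np.random.default_rng(seed)
    strains = list(truth.gcf_presence.index)
    gcf_ids = list(truth.gcf_presence.columns)
    class_of_gcf = {g: BGC_CLASSES[int(i)] for g, i in
                    zip(gcf_ids, rng.choice(len(BGC_CLASSES), size=len(gcf_ids), p=_CLASS_WEIGHTS))}

    occurrence = truth.occurrence
    gene_rows, bgc_rows, label_rows = [], [], []
    for genome in strains:
        if occurrence is not None and genome in occurrence.columns:
            present_clusters = occurrence.index[occurrence[genome] > 0].to_numpy()
        else:
            present_clusters = None
        present = [g for g in gcf_ids if truth.gcf_presence.loc[genome, g] == 1]
        n_extra = max(0, bgc_per_genome - len(present))
        fams = list(present)
        if n_extra and present:
            fams += list(rng.choice(present, size=n_extra, replace=True))
        run_lengths = rng.integers(2, 5, size=len(fams))
        # margin covers inter-run skips and contig-boundary fragmentation
        margin = len(fams) + 8
        if run_lengths.sum() + margin > genes_per_genome:
            run_lengths = np.full(len(fams), 2)
            if run_lengths.sum() + margin > genes_per_genome:
                raise ValueError(
                    f"genes_per_genome={genes_per_genome} too small for "
                    f"{len(fams)} BGCs in genome {genome}"
                )

        n_contigs = int(rng.integers(1, 4))
        contig_sizes = np.full(n_contigs, genes_per_genome // n_contigs)
        contig_sizes[: genes_per_genome % n_contigs] += 1

        # lay out genes, then place BGC runs greedily contig by contig
        gene_counter = 0
        genes_by_contig: list[list[dict]] = []
        for ci, size in enumerate(contig_sizes):
            pos = 1
            contig = f"{genome}_c{ci + 1}"
            genes = []
            for _ in range(int(size)):
                start = pos + int(rng.integers(50, 400))
                stop = start + int(rng.integers(300, 3000))
                gene_counter += 1
                genes.append(
                    {
                        "genome_id": genome,
                        "contig_id": contig,
                        "gene_id": f"{genome}_g{gene_counter:04d}",
                        "start": start,
                        "stop": stop,
                        "strand": "+" if rng.random() < 0.5 else "-",
                    }
                )
                pos = stop
            genes_by_contig.append(genes)

        bg_genes: set[str] = set()
        ci, cursor = 0, 0
        for k, (fam, run) in enumerate(zip(fams, run_lengths)):
            run = int(run)
            while ci < n_contigs and cursor + run > len(genes_by_contig[ci]):
                ci, cursor = ci + 1, 0
            if ci >= n_contigs:
                raise RuntimeError("internal error: BGC placement overflow")
            members = genes_by_contig[ci][cursor : cursor + run]
            cursor += run + int(rng.integers(0, 2))
            u = rng.random()
            if u < 0.21:
                sim = 0.0
            elif u < 0.235:
                sim = 100.0
            else:
                sim = float(rng.beta(1.2, 3.5) * 100.0)
            bgc_rows.append(
                {
                    "genome_id": genome,
                    "contig_id": members[0]["contig_id"],
                    "bgc_id": f"{genome}_bgc{k + 1:03d}",
                    "start": members[0]["start"],
                    "stop": members[-1]["stop"],
                    "bgc_class": class_of_gcf[fam],
                    "similarity_pct": sim,
                    "gcf_id": fam,
                }
            )
            bg_genes.update(g["gene_id"] for g in members)

        for genes in genes_by_contig:
            for g in genes:
                if present_clusters is not None:
                    g["cluster_id"] = str(present_clusters[int(rng.integers(len(present_clusters)))])
                gene_rows.append(g)
                label_rows.append(
                    {
                        "genome_id": genome,
                        "contig_id": g["contig_id"],
                        "gene_id": g["gene_id"],
                        "is_bg": g["gene_id"] in bg_genes,
                    }
                )

    gene_calls = pd.DataFrame(gene_rows)
    bgcs = pd.DataFrame(bgc_rows)
    bg_labels = pd.DataFrame(label_rows)
    return gene_calls, bgcs, bg_labels


def simulate_occurrence(
    tree: dendropy.Tree,
    n_clusters: int,
    gain_loss_rate: float,
    core_fraction: float = 0.25,
    singleton_fraction: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene-cluster occurrence matrix (clusters x genomes, copy counts).

    A ``core_fraction`` of clusters is present in every genome, a
    ``singleton_fraction`` in exactly one, and the remainder evolves under the
    same present/absent chain as the GCF matrix. Copy counts are 1 plus a
    small Poisson excess, emulating occasional paralog expansions.
    """
    rng = np.random.default_rng(seed)
    strains = leaf_labels(tree)
    n = len(strains)
    n_core = int(round(core_fraction * n_clusters))
    n_single = int(round(singleton_fraction * n_clusters))
    n_ctmc = n_clusters - n_core - n_single

    blocks = []
    presence_core = np.ones((n_core, n), dtype=np.int64)
    blocks.append(presence_core)
    if n_ctmc > 0:
        acc = _simulate_ctmc_presence(tree, n_ctmc, gain_loss_rate, rng)
        blocks.append(acc.loc[strains].to_numpy().T)
    single = np.zeros((n_single, n), dtype=np.int64)
    for i in range(n_single):
        single[i, int(rng.integers(n))] = 1
    blocks.append(single)
    presence = np.vstack(blocks)
    counts = presence * (1 + rng.poisson(0.1, size=presence.shape))
    ids = [f"CL{i + 1:05d}" for i in range(presence.shape[0])]
    return pd.DataFrame(counts, index=ids, columns=strains)


def simulate_ani_ddh(tree: dendropy.Tree) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ANI and dDDH matrices derived monotonically from patristic distance.

    Identity mappings place the most distant pair at ANI 78 / dDDH 22 and any
    identical pair at 100 / 100, spanning the species-delineation thresholds
    (95 and 70) so the classification rule is exercised on both sides.
    """
    D = patristic(tree)
    d = D.data
    dmax = d.max() or 1.0
    ani = 100.0 - 22.0 * d / dmax
    ddh = 100.0 - 78.0 * d / dmax
    ids = list(D.ids)
    return (
        pd.DataFrame(ani, index=ids, columns=ids),
        pd.DataFrame(ddh, index=ids, columns=ids),
    )


def assign_clades(tree: dendropy.Tree, n_clades: int) -> dict[str, str]:
    """Partition leaves into the tree's ``n_clades`` highest-level clusters.

    Internal nodes are ordered by root distance; removing the shallowest
    n_clades - 1 of them leaves exactly n_clades subtrees, each a clade.
    """
    strains = leaf_labels(tree)
    if n_clades < 2 or n_clades > len(strains):
        raise ValueError("n_clades must be in [2, n_leaves]")
    depth = {id(tree.seed_node): 0.0}
    internals = []
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)
        if not node.is_leaf():
            internals.append(node)
    internals.sort(key=lambda nd: (depth[id(nd)], min(lf.taxon.label for lf in nd.leaf_iter())))
    cut = {id(nd) for nd in internals[: n_clades - 1]}
    assignment: dict[str, str] = {}
    roots = [
        nd
        for nd in tree.preorder_node_iter()
        if id(nd) not in cut and (nd.parent_node is None or id(nd.parent_node) in cut)
    ]
    roots.sort(key=lambda nd: min(lf.taxon.label for lf in nd.leaf_iter()))
    for i, nd in enumerate(roots):
        for lf in nd.leaf_iter():
            assignment[lf.taxon.label] = f"clade{i + 1}"
    return assignment


def simulate_dataset(config: SimConfig) -> SyntheticTruth:
    """Generate the complete, mutually consistent synthetic input bundle."""
    from ._seeds import derive_seed

    seed = config.seed
    tree = simulate_tree(config.n_strains, derive_seed(seed, "tree"))
    strains = leaf_labels(tree)

    rng = np.random.default_rng(derive_seed(seed, "groups"))
    order = rng.permutation(len(strains))
    sources = [f"source{i + 1}" for i in range(config.n_sources)]
    source_of = {strains[int(j)]: sources[k % config.n_sources] for k, j in enumerate(order)}
    clade_of = assign_clades(tree, config.n_clades)
    media = ["GYM", "V22"] if config.n_media == 2 else [f"M{i + 1}" for i in range(config.n_media)]
    groups = {"source": source_of, "clade": clade_of, "media": media}

    presence, _info = simulate_gcf_matrix(
        tree,
        config.n_gcfs,
        config.gain_loss_rate,
        source_fraction=config.source_fraction,
        group_assignments=source_of,
        seed=derive_seed(seed, "gcf"),
    )
    truth = SyntheticTruth(
        tree=tree,
        gcf_presence=presence,
        group_assignments=groups,
        effect_sizes=config.effect_sizes,
    )
    truth.occurrence = simulate_occurrence(
        tree, 5 * config.n_gcfs, config.gain_loss_rate, seed=derive_seed(seed, "occurrence")
    )
    truth.gene_calls, truth.bgcs, truth.bg_labels = emit_coordinate_tables(
        truth, config.genes_per_genome, config.bgc_per_genome, derive_seed(seed, "coords")
    )
    truth.feature_table = simulate_metabolome(
        truth,
        config.effect_sizes,
        config.n_features,
        derive_seed(seed, "metabolome"),
        n_replicates=config.n_replicates,
    )
    truth.ani, truth.ddh = simulate_ani_ddh(tree)
    return truth


def write_dataset(truth: SyntheticTruth, outdir: str) -> dict[str, str]:
    """Write every table of a synthetic bundle as plain text; returns paths."""
    import os

    from .phylo import write_newick

    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def _tsv(name: str, df: pd.DataFrame, index: bool = True) -> None:
        p = os.path.join(outdir, name)
        df.to_csv(p, sep="\t", index=index)
        paths[name] = p

    write_newick(truth.tree, os.path.join(outdir, "tree.nwk"))
    paths["tree.nwk"] = os.path.join(outdir, "tree.nwk")
    _tsv("gcf_presence.tsv", truth.gcf_presence)
    if truth.gene_calls is not None:
        _tsv("gene_calls.tsv", truth.gene_calls, index=False)
        _tsv("bgcs.tsv", truth.bgcs, index=False)
        _tsv("bg_labels.tsv", truth.bg_labels, index=False)
    if truth.occurrence is not None:
        _tsv("occurrence.tsv", truth.occurrence)
    if truth.ani is not None:
        _tsv("ani.tsv", truth.ani)
        _tsv("ddh.tsv", truth.ddh)
    if truth.feature_table is not None:
        ft = truth.feature_table
        ft.data.to_csv(os.path.join(outdir, "features.csv"))
        paths["features.csv"] = os.path.join(outdir, "features.csv")
        _tsv("feature_meta.tsv", ft.feature_meta)
        _tsv("sample_meta.tsv", ft.sample_meta)
    meta = pd.DataFrame(
        {
            "strain": leaf_labels(truth.tree),
            "source": [truth.group_assignments["source"][s] for s in leaf_labels(truth.tree)],
            "clade": [truth.group_assignments["clade"][s] for s in leaf_labels(truth.tree)],
        }
    ).set_index("strain")
    _tsv("strain_meta.tsv", meta)
    return paths
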