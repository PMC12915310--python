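"""End-to-end orchestration: simulate/load -> pan-genome -> profiles ->
distances -> concordance -> ordination -> forests, with one global seed.

Every stage derives its own seed from the run seed and its stage name, so a
rerun with the same config reproduces every output bit for bit and any stage
can be rerun in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import concordance as cc
from . import distances as dist
from . import forest as rf
from . import ordination as ordn
from . import pangenome as pg
from . import profiles as pr
from ._seeds import derive_seed
from .phylo import leaf_labels, patristic, read_newick
from .simulate import EffectSizes, SimConfig, simulate_dataset, write_dataset

log = logging.getLogger("micromulti")

__all__ = ["RunConfig", "RunReport", "load_config", "validate", "run"]

_STAGES = ("pangenome", "profiles", "distances", "concordance", "ordination", "forest")


@dataclass
class RunConfig:
    seed: int
    simulate: SimConfig | None = None
    inputs: dict | None = None
    n_perm: int = 999
    n_trees: int = 5000
    normalize: str = "log1p_tic"
    stages: dict = field(default_factory=lambda: {s: True for s in _STAGES})

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("config must set exactly one of 'simulate' or 'inputs'")
        for s in self.stages:
            if s not in _STAGES:
                raise ValueError(f"unknown stage {s!r}")
        self.stages = {s: self.stages.get(s, True) for s in _STAGES}


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "seed" not in raw:
        raise ValueError("config must set a seed")
    sim = None
    if "simulate" in raw and raw["simulate"] is not None:
        block = dict(raw["simulate"])
        if "effect_sizes" in block:
            block["effect_sizes"] = EffectSizes(**block["effect_sizes"])
        block.setdefault("seed", raw["seed"])
        sim = SimConfig(**block)
    return RunConfig(
        seed=int(raw["seed"]),
        simulate=sim,
        inputs=raw.get("inputs"),
        n_perm=int(raw.get("n_perm", 999)),
        n_trees=int(raw.get("n_trees", 5000)),
        normalize=raw.get("normalize", "log1p_tic"),
        stages=raw.get("stages", {s: True for s in _STAGES}),
    )


@dataclass
class RunReport:
    output_paths: dict
    partition_counts: pd.Series | None = None
    novelty: pg.NoveltySummary | None = None
    concordance_table: pd.DataFrame | None = None
    mantel_table: pd.DataFrame | None = None
    permanova_table: pd.DataFrame | None = None
    rf_table: pd.DataFrame | None = None
    verdict: list[str] | None = None


def _load_inputs(config: RunConfig):
    """Materialize the input bundle, from disk or the generator."""
    if config.simulate is not None:
        truth = simulate_dataset(config.simulate)
        meta = pd.DataFrame(
            {
                "source": pd.Series(truth.group_assignments["source"]),
                "clade": pd.Series(truth.group_assignments["clade"]),
            }
        )
        return {
            "tree": truth.tree,
            "occurrence": truth.occurrence,
            "gene_calls": truth.gene_calls,
            "bgcs": truth.bgcs,
            "feature_table": truth.feature_table,
            "strain_meta": meta,
            "ani": truth.ani,
            "ddh": truth.ddh,
            "_truth": truth,
        }
    paths = config.inputs
    bundle = {}
    bundle["tree"] = read_newick(paths["tree"])
    bundle["occurrence"] = pd.read_csv(paths["occurrence"], sep="\t", index_col=0)
    bundle["gene_calls"] = pd.read_csv(paths["gene_calls"], sep="\t")
    bundle["bgcs"] = pd.read_csv(paths["bgcs"], sep="\t")
    bundle["feature_table"] = pr.read_feature_table(
        paths["features"], paths["feature_meta"], paths["sample_meta"]
    )
    bundle["strain_meta"] = pd.read_csv(paths["strain_meta"], sep="\t", index_col=0)
    bundle["ani"] = pd.read_csv(paths["ani"], sep="\t", index_col=0) if "ani" in paths else None
    bundle["ddh"] = pd.read_csv(paths["ddh"], sep="\t", index_col=0) if "ddh" in paths else None
    return bundle


def validate(config: RunConfig) -> list[str]:
    """Fail-fast schema and cross-consistency check; returns problems."""
    problems: list[str] = []
    if config.inputs is not None:
        for key in ("tree", "occurrence", "gene_calls", "bgcs", "features",
                    "feature_meta", "sample_meta", "strain_meta"):
            if key not in config.inputs:
                problems.append(f"missing input path: {key}")
            elif not os.path.exists(config.inputs[key]):
                problems.append(f"input file not found: {config.inputs[key]}")
        if problems:
            return problems
    try:
        bundle = _load_inputs(config)
    except Exception as exc:  # noqa: BLE001 - reported, not raised
        return [f"inputs could not be loaded: {exc}"]

    strains = set(leaf_labels(bundle["tree"]))
    meta = bundle["strain_meta"]
    if meta.index.duplicated().any():
        problems.append("duplicated strain id(s) in strain metadata")
    for leaf in sorted(strains - set(meta.index)):
        problems.append(f"tree leaf {leaf!r} missing from strain metadata")
    occ_cols = set(bundle["occurrence"].columns)
    if occ_cols != strains:
        problems.append(
            f"occurrence matrix genomes differ from tree leaves: {sorted(occ_cols ^ strains)[:5]}"
        )
    for col in ("genome_id", "contig_id", "gene_id", "start", "stop"):
        if col not in bundle["gene_calls"].columns:
            problems.append(f"gene calls missing column {col!r}")
    for col in ("genome_id", "contig_id", "bgc_id", "start", "stop", "bgc_class"):
        if col not in bundle["bgcs"].columns:
            problems.append(f"BGC table missing column {col!r}")
    ft = bundle["feature_table"]
    if ft.sample_meta.index.duplicated().any():
        problems.append("duplicated sample id(s) in sample metadata")
    for s in sorted(set(ft.sample_meta["strain"]) - strains):
        problems.append(f"sample strain {s!r} missing from tree")
    return problems


def run(config: RunConfig, outdir: str) -> RunReport:
    """Execute the enabled stages in dependency order and write TSV outputs."""
    problems = validate(config)
    if problems:
        raise ValueError("invalid configuration:\n" + "\n".join(problems))
    os.makedirs(outdir, exist_ok=True)
    bundle = _load_inputs(config)
    paths: dict[str, str] = {}

    def _save(name: str, df: pd.DataFrame, index: bool = True) -> None:
        p = os.path.join(outdir, name)
        df.to_csv(p, sep="\t", index=index)
        paths[name] = p
        log.info("wrote %s (seed=%s)", p, config.seed)

    if config.simulate is not None:
        sim_paths = write_dataset(bundle["_truth"], os.path.join(outdir, "simulated"))
        paths.update({f"simulated/{k}": v for k, v in sim_paths.items()})

    report = RunReport(output_paths=paths)
    stages = config.stages

    if stages["pangenome"]:
        partitions = pg.partition_occurrence(bundle["occurrence"])
        report.partition_counts = partitions.value_counts()
        _save("partition_table.tsv", partitions.to_frame())
        joined = pg.bgc_gene_join(bundle["gene_calls"], bundle["bgcs"])
        _save("bg_labels.tsv", joined, index=False)
        if "cluster_id" in bundle["gene_calls"].columns:
            labeled = joined.merge(
                bundle["gene_calls"][["genome_id", "contig_id", "gene_id", "cluster_id"]],
                on=["genome_id", "contig_id", "gene_id"],
            )
            profile = pg.bg_partition_profile(partitions, labeled)
            _save("bg_partition_profile.tsv", profile)
        report.novelty = pg.summarize_novelty(bundle["bgcs"]["similarity_pct"])
        if bundle.get("ani") is not None and bundle.get("ddh") is not None:
            ids = sorted(bundle["ani"].index)
            refs = ids[: max(2, len(ids) // 3)]
            queries = [i for i in ids if i not in refs]
            species = pg.classify_species_novelty(bundle["ani"], bundle["ddh"], queries, refs)
            _save("species_novelty.tsv", species)

    presence = metab = metab_strain = None
    if stages["profiles"] or stages["distances"] or stages["concordance"] or \
            stages["ordination"] or stages["forest"]:
        presence = pr.build_presence(bundle["bgcs"])
        metab = pr.normalize(pr.filter_ms2(bundle["feature_table"]), config.normalize)
        metab_strain = pr.aggregate_by_strain(metab)
    if stages["profiles"]:
        _save("gcf_presence.tsv", presence)
        _save("metabolome_normalized.tsv", metab.data)
        _save("category_composition.tsv", pr.category_composition(metab.feature_meta))

    d_jac = d_bc_strain = dendro_bg = dendro_met = d_patristic = None
    if stages["distances"] or stages["concordance"] or stages["ordination"]:
        d_patristic = patristic(bundle["tree"])
        d_jac = dist.jaccard_matrix(presence)
        d_bc_strain = dist.bray_curtis_matrix(metab_strain.data)
        dendro_bg = dist.upgma(d_jac)
        dendro_met = dist.upgma(d_bc_strain)
    if stages["distances"]:
        dist.write_distance_tsv(d_jac, os.path.join(outdir, "jaccard_gcf.tsv"))
        dist.write_distance_tsv(d_bc_strain, os.path.join(outdir, "braycurtis_metabolome.tsv"))
        dist.write_distance_tsv(d_patristic, os.path.join(outdir, "patristic.tsv"))
        for name, dd in (("bg_dendrogram.nwk", dendro_bg), ("metabolome_dendrogram.nwk", dendro_met)):
            with open(os.path.join(outdir, name), "w") as fh:
                fh.write(dd.to_newick())
            paths[name] = os.path.join(outdir, name)

    if stages["concordance"]:
        pairs = [
            ("phylogeny_vs_bg", bundle["tree"], dendro_bg),
            ("phylogeny_vs_metabolome", bundle["tree"], dendro_met),
            ("bg_vs_metabolome", dendro_bg, dendro_met),
        ]
        rows = []
        for i, (name, a, b) in enumerate(pairs):
            for stat in ("cophenetic_pearson", "bakers_gamma"):
                res = cc.permutation_null(
                    stat, a, b, n_perm=config.n_perm,
                    seed=derive_seed(config.seed, f"concordance/{name}/{stat}"),
                )
                rows.append({"pair": name, "statistic": stat, "observed": res.observed,
                             "p_value": res.p_value, "n_perm": res.n_permutations})
        report.concordance_table = pd.DataFrame(rows)
        _save("concordance.tsv", report.concordance_table, index=False)

        mrows = []
        for name, a, b in (
            ("patristic_vs_gcf_jaccard", d_patristic, d_jac),
            ("patristic_vs_metabolome_braycurtis", d_patristic, d_bc_strain),
            ("gcf_jaccard_vs_metabolome_braycurtis", d_jac, d_bc_strain),
        ):
            res = cc.mantel(a, b, n_perm=config.n_perm,
                            seed=derive_seed(config.seed, f"mantel/{name}"))
            mrows.append({"pair": name, "r": res.observed, "r_squared": res.r_squared,
                          "p_value": res.p_value, "n_perm": res.n_permutations})
        report.mantel_table = pd.DataFrame(mrows)
        _save("mantel.tsv", report.mantel_table, index=False)

    groupings = ("medium", "clade", "source")
    if stages["ordination"]:
        d_bc_samples = dist.bray_curtis_matrix(metab.data)
        pcoa_res = ordn.pcoa(d_bc_samples)
        _save("pcoa_coordinates.tsv", pcoa_res.coordinates)
        prow = []
        for grouping in groupings:
            res = ordn.permanova(
                d_bc_samples, metab.sample_meta[grouping],
                n_perm=config.n_perm, seed=derive_seed(config.seed, f"permanova/{grouping}"),
            )
            prow.append({"grouping": grouping, "pseudo_F": res.pseudo_F,
                         "r_squared": res.r_squared, "p_value": res.p_value})
        report.permanova_table = pd.DataFrame(prow).set_index("grouping")
        _save("permanova.tsv", report.permanova_table)

    if stages["forest"]:
        fc = rf.ForestConfig(n_trees=config.n_trees, seed=derive_seed(config.seed, "forest"))
        summary, results = rf.compare_groupings(
            metab.data, metab.sample_meta, list(groupings), fc
        )
        report.rf_table = summary
        _save("rf_metabolome.tsv", summary)
        imp = pd.DataFrame(
            {g: results[g].importance for g in groupings if results[g].importance is not None}
        )
        _save("rf_importance.tsv", imp)

    verdict: list[str] = []
    if report.rf_table is not None:
        verdict.append("rf_r2_ranking: " + " > ".join(report.rf_table.index))
    if report.permanova_table is not None:
        sig = report.permanova_table[report.permanova_table["p_value"] <= 0.05]
        verdict.append("permanova_significant: " + (",".join(sig.index) if len(sig) else "none"))
    report.verdict = verdict
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(
            {
                "seed": config.seed,
                "verdict": verdict,
                "outputs": sorted(paths),
                "partition_counts": (
                    report.partition_counts.to_dict() if report.partition_counts is not None else None
                ),
                "novelty": dataclasses.asdict(report.novelty) if report.novelty else None,
            },
            fh,
            indent=2,
        )
    paths["report.json"] = os.path.join(outdir, "report.json")
    return report
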