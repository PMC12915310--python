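"""Pan-genome partitioning and biosynthetic-gene (BG) mapping.

Core/accessory/singleton partitioning of a gene-cluster occurrence matrix, the
coordinate join that labels genes lying within biosynthetic gene cluster (BGC)
boundaries, per-partition BG class profiles, novelty summaries of
BGC-to-known-cluster similarity scores, and the ANI/dDDH species-delineation
rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "partition_occurrence",
    "bgc_gene_join",
    "bg_partition_profile",
    "NoveltySummary",
    "summarize_novelty",
    "classify_species_novelty",
]

PARTITIONS = ("core", "accessory", "singleton")


def partition_occurrence(matrix: pd.DataFrame, drop_empty: bool = True) -> pd.Series:
    """Classify each gene cluster as core, accessory or singleton.

    A cluster is core iff present (count >= 1) in every genome, singleton iff
    present in exactly one, accessory otherwise. Presence, not copy count, is
    what matters: a paralog expansion cannot eject a universal cluster from
    the core. All-zero rows are dropped with a warning (or rejected).
    """
    if matrix.size == 0:
        raise ValueError("empty occurrence matrix")
    if (matrix.to_numpy() < 0).any():
        raise ValueError("occurrence matrix has negative entries")
    presence = (matrix > 0).sum(axis=1)
    empty = presence == 0
    if empty.any():
        if not drop_empty:
            raise ValueError(f"{int(empty.sum())} all-zero cluster row(s)")
        warnings.warn(f"dropping {int(empty.sum())} all-zero cluster row(s)", stacklevel=2)
        presence = presence[~empty]
    n_genomes = matrix.shape[1]
    out = pd.Series("accessory", index=presence.index, name="partition")
    out[presence == n_genomes] = "core"
    out[presence == 1] = "singleton"
    return out


def bgc_gene_join(
    gene_calls: pd.DataFrame, bgc_records: pd.DataFrame, mode: str = "containment"
) -> pd.DataFrame:
    """Label genes biosynthetic by joining them onto BGC intervals.

    ``containment`` (default) labels a gene iff it lies fully within a BGC on
    the same genome and contig; ``any-overlap`` requires only a shared base.
    A gene matching several BGCs is assigned the one with the smallest span
    (ties: lexicographically smallest bgc_id). Strand is ignored. Records with
    inverted coordinates are rejected with a warning.
    """
    if mode not in ("containment", "any-overlap"):
        raise ValueError(f"unknown mode {mode!r}")

    def _clean(df: pd.DataFrame, kind: str) -> pd.DataFrame:
        bad = df["start"] > df["stop"]
        if bad.any():
            warnings.warn(
                f"rejecting {int(bad.sum())} {kind} record(s) with start > stop",
                stacklevel=3,
            )
            df = df[~bad]
        return df

    genes = _clean(gene_calls, "gene").copy()
    bgcs = _clean(bgc_records, "BGC").copy()
    bgcs["_span"] = bgcs["stop"] - bgcs["start"]

    out = genes[["genome_id", "contig_id", "gene_id", "start", "stop"]].copy()
    out["is_bg"] = False
    out["bgc_id"] = pd.NA
    out["bgc_class"] = pd.NA

    grouped_bgcs = bgcs.groupby(["genome_id", "contig_id"], sort=False)
    for key, gidx in genes.groupby(["genome_id", "contig_id"], sort=False).groups.items():
        try:
            cand = grouped_bgcs.get_group(key)
        except KeyError:
            continue
        g = genes.loc[gidx]
        gs = g["start"].to_numpy()[:, None]
        ge = g["stop"].to_numpy()[:, None]
        bs = cand["start"].to_numpy()[None, :]
        be = cand["stop"].to_numpy()[None, :]
        if mode == "containment":
            hit = (bs <= gs) & (ge <= be)
        else:
            hit = (gs <= be) & (bs <= ge)
        if not hit.any():
            continue
        # smallest span, then lexicographically smallest id, among hits
        order = np.lexsort(
            (cand["bgc_id"].astype(str).to_numpy(), cand["_span"].to_numpy())
        )
        hit_sorted = hit[:, order]
        first = np.argmax(hit_sorted, axis=1)
        any_hit = hit_sorted.any(axis=1)
        chosen = cand.iloc[order[first]]
        rows = np.asarray(gidx)[any_hit]
        out.loc[rows, "is_bg"] = True
        out.loc[rows, "bgc_id"] = chosen["bgc_id"].to_numpy()[any_hit]
        out.loc[rows, "bgc_class"] = chosen["bgc_class"].to_numpy()[any_hit]
    return out


def bg_partition_profile(
    partition_table: pd.Series, bg_labels: pd.DataFrame, classes: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """BG counts and within-partition percentages per (partition, BGC class).

    ``bg_labels`` must carry ``cluster_id`` (pan-genome membership of each BG)
    and ``bgc_class``. NI-siderophore and NAGGN stay separate classes — they
    are never folded into Others. Percentages within a partition sum to 100
    when the partition holds any BG; empty partitions report zeros.
    """
    bgs = bg_labels[bg_labels["is_bg"]] if "is_bg" in bg_labels.columns else bg_labels
    unknown = sorted(set(bgs["cluster_id"]) - set(partition_table.index))
    if unknown:
        raise ValueError(f"BGs with cluster_id absent from partition table: {unknown[:10]}")
    part = bgs["cluster_id"].map(partition_table)
    counts = pd.crosstab(part, bgs["bgc_class"])
    counts = counts.reindex(index=list(PARTITIONS), fill_value=0)
    if classes is not None:
        counts = counts.reindex(columns=list(classes), fill_value=0)
    totals = counts.sum(axis=1)
    pct = counts.div(totals.where(totals > 0, 1), axis=0) * 100.0
    counts.index.name = pct.index.name = "partition"
    out = pd.concat({"count": counts, "percent": pct}, axis=1)
    return out


@dataclass(frozen=True)
class NoveltySummary:
    """Novelty of BGCs relative to known clusters, from similarity scores."""

    n_total: int
    n_zero: int
    n_le50: int
    n_eq100: int
    mean_similarity: float

    @property
    def fraction_zero(self) -> float:
        return 100.0 * self.n_zero / self.n_total

    @property
    def fraction_le50(self) -> float:
        return 100.0 * self.n_le50 / self.n_total

    @property
    def fraction_eq100(self) -> float:
        return 100.0 * self.n_eq100 / self.n_total


def summarize_novelty(similarities) -> NoveltySummary:
    """Summarize percent-similarity scores of BGCs to known clusters.

    Scores of 0 mark entirely novel clusters, <= 50 low homology, and 100
    exact matches to characterized pathways.
    """
    sims = pd.Series(similarities, dtype=float)
    if len(sims) == 0:
        raise ValueError("no similarity values")
    bad = sims[(sims < 0) | (sims > 100) | sims.isna()]
    if len(bad):
        raise ValueError(
            f"similarity values outside [0, 100]: {dict(bad.head(10))}"
        )
    return NoveltySummary(
        n_total=int(len(sims)),
        n_zero=int((sims == 0).sum()),
        n_le50=int((sims <= 50).sum()),
        n_eq100=int((sims == 100).sum()),
        mean_similarity=float(sims.mean()),
    )


def classify_species_novelty(
    ani_matrix: pd.DataFrame,
    ddh_matrix: pd.DataFrame,
    query_ids: list[str],
    reference_ids: list[str],
    ani_threshold: float = 95.0,
    ddh_threshold: float = 70.0,
) -> pd.DataFrame:
    """Putative-novel-species call per query by the ANI < 95 / dDDH < 70 rule.

    A query is flagged novel iff its maximum ANI over the references is
    strictly below ``ani_threshold`` and the dDDH to that closest reference is
    strictly below ``ddh_threshold``. Boundary equality is not novel.
    """
    for q in query_ids:
        if q not in ani_matrix.index or q not in ddh_matrix.index:
            raise ValueError(f"query {q!r} absent from matrices")
    for r in reference_ids:
        if r not in ani_matrix.columns or r not in ddh_matrix.columns:
            raise ValueError(f"reference {r!r} absent from matrices")
    rows = []
    for q in query_ids:
        ani_row = ani_matrix.loc[q, reference_ids]
        closest = ani_row.idxmax()
        max_ani = float(ani_row[closest])
        ddh = float(ddh_matrix.loc[q, closest])
        rows.append(
            {
                "query": q,
                "closest_reference": closest,
                "max_ani": max_ani,
                "ddh_at_closest": ddh,
                "is_putative_novel": (max_ani < ani_threshold) and (ddh < ddh_threshold),
            }
        )
    return pd.DataFrame(rows).set_index("query")
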