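"""Pan-genome partitioning, BGC-gene joining, novelty and species rules."""

import numpy as np
import pandas as pd
import pytest

from micromulti.pangenome import (
    bg_partition_profile,
    bgc_gene_join,
    classify_species_novelty,
    partition_occurrence,
    summarize_novelty,
)


def _occurrence(rows, genomes):
    return pd.DataFrame(rows, index=[f"c{i}" for i in range(len(rows))], columns=genomes)


class TestPartition:
    def test_rule_on_three_genomes(self):
        mat = _occurrence([[1, 1, 1], [1, 0, 0], [1, 1, 0]], ["A", "B", "C"])
        parts = partition_occurrence(mat)
        assert parts.tolist() == ["core", "singleton", "accessory"]

    def test_core_means_present_in_all_107_genomes(self):
        genomes = [f"g{i}" for i in range(107)]
        mat = _occurrence([[1] * 107, [2] * 106 + [0]], genomes)
        parts = partition_occurrence(mat)
        assert parts["c0"] == "core"
        assert parts["c1"] == "accessory"

    def test_paralog_expansion_stays_core(self):
        mat = _occurrence([[5, 1, 3]], ["A", "B", "C"])
        assert partition_occurrence(mat)["c0"] == "core"

    def test_all_zero_row_dropped_with_warning_or_rejected(self):
        mat = _occurrence([[1, 1], [0, 0]], ["A", "B"])
        with pytest.warns(UserWarning):
            parts = partition_occurrence(mat)
        assert "c1" not in parts.index
        with pytest.raises(ValueError):
            partition_occurrence(mat, drop_empty=False)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            partition_occurrence(pd.DataFrame())

    def test_partitions_are_exhaustive_and_adding_genomes_shrinks_core(self, rng):
        """Adding a genome column can eject clusters from the core but never
        promote one into it."""
        for _ in range(20):
            n_c, n_g = rng.integers(5, 30), rng.integers(3, 8)
            mat = pd.DataFrame(
                rng.integers(0, 3, size=(n_c, n_g)),
                index=[f"c{i}" for i in range(n_c)],
                columns=[f"g{j}" for j in range(n_g)],
            )
            mat = mat[(mat > 0).any(axis=1)]
            parts = partition_occurrence(mat)
            assert len(parts) == len(mat)
            extra = mat.copy()
            extra["g_new"] = rng.integers(0, 2, size=len(mat))
            parts_after = partition_occurrence(extra)
            core_after = set(parts_after[parts_after == "core"].index)
            core_before = set(parts[parts == "core"].index)
            assert core_after <= core_before


class TestBgcGeneJoin:
    GENES = pd.DataFrame(
        {
            "genome_id": ["G"] * 3,
            "contig_id": ["c1"] * 3,
            "gene_id": ["g1", "g2", "g3"],
            "start": [100, 400, 600],
            "stop": [300, 500, 900],
        }
    )

    def test_full_containment_is_bg(self):
        bgcs = pd.DataFrame(
            [{"genome_id": "G", "contig_id": "c1", "bgc_id": "b1", "start": 50,
              "stop": 500, "bgc_class": "Terpene"}]
        )
        out = bgc_gene_join(self.GENES, bgcs).set_index("gene_id")
        assert out.loc["g1", "is_bg"] and out.loc["g2", "is_bg"]
        assert not out.loc["g3", "is_bg"]

    def test_partial_overlap_distinguishes_modes(self):
        genes = pd.DataFrame(
            [{"genome_id": "G", "contig_id": "c1", "gene_id": "g", "start": 400, "stop": 600}]
        )
        bgcs = pd.DataFrame(
            [{"genome_id": "G", "contig_id": "c1", "bgc_id": "b", "start": 50,
              "stop": 500, "bgc_class": "NRPS"}]
        )
        assert not bgc_gene_join(genes, bgcs, mode="containment")["is_bg"].iloc[0]
        assert bgc_gene_join(genes, bgcs, mode="any-overlap")["is_bg"].iloc[0]

    def test_exact_run_of_genes(self):
        genes = pd.DataFrame(
            {
                "genome_id": "G",
                "contig_id": "c1",
                "gene_id": [f"g{i}" for i in range(10)],
                "start": [i * 1000 + 100 for i in range(10)],
                "stop": [i * 1000 + 900 for i in range(10)],
            }
        )
        bgcs = pd.DataFrame(
            [{"genome_id": "G", "contig_id": "c1", "bgc_id": "b", "start": 2100,
              "stop": 6900, "bgc_class": "RiPPs"}]
        )
        out = bgc_gene_join(genes, bgcs)
        assert out["is_bg"].sum() == 5

    def test_overlapping_bgcs_assign_smallest_span_then_lexicographic(self):
        genes = pd.DataFrame(
            [{"genome_id": "G", "contig_id": "c1", "gene_id": "g", "start": 200, "stop": 300}]
        )
        bgcs = pd.DataFrame(
            [
                {"genome_id": "G", "contig_id": "c1", "bgc_id": "wide", "start": 1,
                 "stop": 1000, "bgc_class": "Others"},
                {"genome_id": "G", "contig_id": "c1", "bgc_id": "b_narrow", "start": 150,
                 "stop": 400, "bgc_class": "NRPS"},
                {"genome_id": "G", "contig_id": "c1", "bgc_id": "a_narrow", "start": 100,
                 "stop": 350, "bgc_class": "Terpene"},
            ]
        )
        out = bgc_gene_join(genes, bgcs)
        assert out["bgc_id"].iloc[0] == "a_narrow"  # same span 250, lexicographic

    def test_inverted_coordinates_rejected_with_warning(self):
        genes = self.GENES.copy()
        genes.loc[0, "stop"] = 50
        bgcs = pd.DataFrame(
            [{"genome_id": "G", "contig_id": "c1", "bgc_id": "b", "start": 1,
              "stop": 2000, "bgc_class": "NRPS"}]
        )
        with pytest.warns(UserWarning):
            out = bgc_gene_join(genes, bgcs)
        assert "g1" not in set(out["gene_id"])

    def test_matches_brute_force_double_loop(self, rng):
        """Vectorized join equals an O(genes x BGCs) reference on random data."""
        for _ in range(15):
            n_genes, n_bgcs = int(rng.integers(20, 120)), int(rng.integers(2, 15))
            genomes = rng.choice(["G1", "G2"], size=n_genes)
            contigs = rng.choice(["c1", "c2"], size=n_genes)
            starts = rng.integers(1, 50_000, size=n_genes)
            genes = pd.DataFrame(
                {
                    "genome_id": genomes,
                    "contig_id": contigs,
                    "gene_id": [f"g{i}" for i in range(n_genes)],
                    "start": starts,
                    "stop": starts + rng.integers(100, 3000, size=n_genes),
                }
            )
            bstarts = rng.integers(1, 50_000, size=n_bgcs)
            bgcs = pd.DataFrame(
                {
                    "genome_id": rng.choice(["G1", "G2"], size=n_bgcs),
                    "contig_id": rng.choice(["c1", "c2"], size=n_bgcs),
                    "bgc_id": [f"b{i}" for i in range(n_bgcs)],
                    "start": bstarts,
                    "stop": bstarts + rng.integers(500, 20_000, size=n_bgcs),
                    "bgc_class": "Terpene",
                }
            )
            out = bgc_gene_join(genes, bgcs).set_index("gene_id")
            for _, g in genes.iterrows():
                hits = [
                    b
                    for _, b in bgcs.iterrows()
                    if b["genome_id"] == g["genome_id"]
                    and b["contig_id"] == g["contig_id"]
                    and b["start"] <= g["start"]
                    and g["stop"] <= b["stop"]
                ]
                if hits:
                    best = min(hits, key=lambda b: (b["stop"] - b["start"], b["bgc_id"]))
                    assert out.loc[g["gene_id"], "is_bg"]
                    assert out.loc[g["gene_id"], "bgc_id"] == best["bgc_id"]
                else:
                    assert not out.loc[g["gene_id"], "is_bg"]


class TestBgPartitionProfile:
    def test_single_partition_percentages(self):
        parts = pd.Series({"c1": "core", "c2": "core"})
        bgs = pd.DataFrame(
            {
                "cluster_id": ["c1"] * 7 + ["c2"] * 3,
                "bgc_class": ["Terpene"] * 7 + ["NRPS"] * 3,
                "is_bg": True,
            }
        )
        prof = bg_partition_profile(parts, bgs)
        assert prof.loc["core", ("percent", "Terpene")] == pytest.approx(70.0)
        assert prof.loc["core", ("percent", "NRPS")] == pytest.approx(30.0)
        assert prof.loc["accessory"].sum() == 0

    def test_percentages_sum_to_100_within_nonempty_partitions(self, small_truth):
        labeled = small_truth.bg_labels.merge(
            small_truth.gene_calls[["gene_id", "cluster_id"]], on="gene_id"
        )
        joined = labeled[labeled["is_bg"]].merge(
            small_truth.gene_calls[["gene_id"]], on="gene_id"
        )
        bgcs = small_truth.bgcs
        # attach the class of the containing BGC via the coordinate join
        from micromulti.pangenome import bgc_gene_join

        full = bgc_gene_join(small_truth.gene_calls, bgcs).merge(
            small_truth.gene_calls[["gene_id", "cluster_id"]], on="gene_id"
        )
        parts = partition_occurrence(small_truth.occurrence)
        prof = bg_partition_profile(parts, full)
        for part in prof.index:
            total = prof.loc[part, "percent"].sum()
            assert total == pytest.approx(100.0, abs=1e-9) or total == 0.0

    def test_unknown_cluster_id_rejected(self):
        parts = pd.Series({"c1": "core"})
        bgs = pd.DataFrame({"cluster_id": ["c9"], "bgc_class": ["NRPS"], "is_bg": [True]})
        with pytest.raises(ValueError, match="c9"):
            bg_partition_profile(parts, bgs)


class TestNovelty:
    def test_small_worked_example(self):
        s = summarize_novelty([0, 0, 30, 100])
        assert (s.n_zero, s.n_le50, s.n_eq100) == (2, 3, 1)
        assert s.fraction_zero == pytest.approx(50.0)
        assert s.fraction_le50 == pytest.approx(75.0)
        assert s.fraction_eq100 == pytest.approx(25.0)
        assert s.mean_similarity == pytest.approx(32.5)

    def test_fraction_ordering_and_bounds(self, rng):
        for _ in range(20):
            vals = rng.uniform(0, 100, size=int(rng.integers(2, 200)))
            vals[rng.random(len(vals)) < 0.2] = 0.0
            s = summarize_novelty(vals)
            assert s.fraction_zero <= s.fraction_le50
            for f in (s.fraction_zero, s.fraction_le50, s.fraction_eq100):
                assert 0 <= f <= 100

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            summarize_novelty([5, 101])
        with pytest.raises(ValueError):
            summarize_novelty([-1])


class TestSpeciesNovelty:
    def _matrices(self, ani_qr, ddh_qr):
        ids = ["Q", "R1", "R2"]
        ani = pd.DataFrame(100.0, index=ids, columns=ids)
        ddh = pd.DataFrame(100.0, index=ids, columns=ids)
        ani.loc["Q", "R1"], ani.loc["Q", "R2"] = ani_qr, ani_qr - 2
        ddh.loc["Q", "R1"] = ddh.loc["Q", "R2"] = ddh_qr
        return ani, ddh

    def test_both_below_thresholds_is_novel(self):
        ani, ddh = self._matrices(94.0, 60.0)
        out = classify_species_novelty(ani, ddh, ["Q"], ["R1", "R2"])
        assert out.loc["Q", "is_putative_novel"]
        assert out.loc["Q", "closest_reference"] == "R1"

    def test_high_ani_gates_regardless_of_ddh(self):
        ani, ddh = self._matrices(96.2, 10.0)
        assert not classify_species_novelty(ani, ddh, ["Q"], ["R1", "R2"]).loc[
            "Q", "is_putative_novel"
        ]

    def test_boundary_equality_is_not_novel(self):
        ani, ddh = self._matrices(94.9, 70.0)
        assert not classify_species_novelty(ani, ddh, ["Q"], ["R1", "R2"]).loc[
            "Q", "is_putative_novel"
        ]

    def test_missing_query_rejected(self):
        ani, ddh = self._matrices(94.0, 60.0)
        with pytest.raises(ValueError):
            classify_species_novelty(ani, ddh, ["missing"], ["R1"])


class TestNoveltyProperties:
    """Summary invariants hold for arbitrary valid score vectors."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        st.lists(
            st.one_of(
                st.floats(min_value=0, max_value=100, allow_nan=False),
                st.sampled_from([0.0, 50.0, 100.0]),
            ),
            min_size=1,
            max_size=50,
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_counts_nest_and_fractions_bound(self, values):
        s = summarize_novelty(values)
        assert s.n_zero <= s.n_le50 <= s.n_total
        assert s.n_eq100 <= s.n_total
        assert 0 <= s.fraction_zero <= s.fraction_le50 <= 100
        assert 0 <= s.mean_similarity <= 100
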