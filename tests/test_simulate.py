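"""Generator behaviour: determinism, structural guarantees, effect recovery."""

import numpy as np
import pandas as pd
import pytest

from micromulti.distances import bray_curtis_matrix, jaccard_matrix
from micromulti.concordance import mantel
from micromulti.ordination import pcoa, permanova
from micromulti.phylo import leaf_labels, patristic, to_newick
from micromulti.profiles import build_presence
from micromulti.simulate import (
    EffectSizes,
    SimConfig,
    SyntheticTruth,
    assign_clades,
    emit_coordinate_tables,
    simulate_ani_ddh,
    simulate_gcf_matrix,
    simulate_metabolome,
    simulate_tree,
)


def _minimal_truth(tree, presence=None, n_sources=2):
    strains = leaf_labels(tree)
    source_of = {s: f"source{(i % n_sources) + 1}" for i, s in enumerate(strains)}
    clade_of = assign_clades(tree, 2)
    if presence is None:
        presence = pd.DataFrame(1, index=strains, columns=["GCF0001"])
    return SyntheticTruth(
        tree=tree,
        gcf_presence=presence,
        group_assignments={"source": source_of, "clade": clade_of, "media": ["GYM", "V22"]},
        effect_sizes=EffectSizes(),
    )


class TestSimulateTree:
    def test_small_tree_is_binary_rooted_with_positive_lengths(self):
        tree = simulate_tree(3, seed=1)
        leaves = [n for n in tree.leaf_node_iter()]
        internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
        assert len(leaves) == 3
        assert len(internals) == 2
        for node in tree.preorder_node_iter():
            if node is not tree.seed_node:
                assert node.edge.length > 0

    def test_patristic_is_a_metric(self):
        tree = simulate_tree(15, seed=7)
        d = patristic(tree).data
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        n = d.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_seeded_newick_is_byte_identical(self):
        assert to_newick(simulate_tree(10, seed=3)) == to_newick(simulate_tree(10, seed=3))

    def test_too_few_strains_rejected(self):
        with pytest.raises(ValueError):
            simulate_tree(2, seed=0)


class TestGcfMatrix:
    def test_zero_rate_freezes_root_state(self):
        tree = simulate_tree(8, seed=2)
        mat, _ = simulate_gcf_matrix(tree, 40, gain_loss_rate=0.0, seed=5)
        assert (mat.nunique(axis=0) == 1).all()

    def test_high_rate_approaches_independence(self):
        """Saturated chains behave like i.i.d. Bernoulli(1/2) draws.

        Oracle: mean pairwise Jaccard distance of an explicit i.i.d. matrix of
        the same shape, compared within Monte-Carlo error.
        """
        tree = simulate_tree(12, seed=4)
        mat, _ = simulate_gcf_matrix(tree, 500, gain_loss_rate=100.0, seed=6)
        obs = np.mean(jaccard_matrix(mat).condensed_form())

        rng = np.random.default_rng(123)
        iid = pd.DataFrame(rng.integers(0, 2, size=mat.shape), index=mat.index)
        exp = np.mean(jaccard_matrix(iid).condensed_form())
        assert abs(obs - exp) < 0.03

    def test_signal_decreases_with_rate(self):
        """Mantel r of Jaccard vs patristic falls as gain/loss rate rises."""
        rates = [0.1, 1.0, 10.0]
        means = []
        for rate in rates:
            rs = []
            for seed in range(6):
                tree = simulate_tree(12, seed=100 + seed)
                mat, _ = simulate_gcf_matrix(tree, 150, rate, seed=200 + seed)
                rs.append(
                    mantel(patristic(tree), jaccard_matrix(mat), n_perm=99, seed=seed).observed
                )
            means.append(np.mean(rs))
        assert means[0] > means[1] > means[2]

    def test_seeded_determinism_and_negative_rate(self):
        tree = simulate_tree(6, seed=1)
        a, _ = simulate_gcf_matrix(tree, 30, 0.5, seed=9)
        b, _ = simulate_gcf_matrix(tree, 30, 0.5, seed=9)
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ValueError):
            simulate_gcf_matrix(tree, 30, -1.0, seed=9)


class TestMetabolome:
    def test_no_variance_components_gives_identical_samples(self):
        tree = simulate_tree(5, seed=3)
        truth = _minimal_truth(tree)
        es = EffectSizes(sigma_phylo=0, sigma_medium=0, sigma_source=0, sigma_noise=0)
        ft = simulate_metabolome(truth, es, n_features=20, seed=1)
        assert np.allclose(ft.data.to_numpy(), ft.data.to_numpy()[0])

    def test_phylo_signal_increases_with_sigma_phylo(self):
        """Mantel r (patristic vs strain-profile Bray-Curtis) grows with the
        phylogenetic variance component.

        The rise is steep from zero and plateaus once the Brownian signal
        saturates the finite feature panel, so the check is a monotone trend:
        the no-signal level sits below both positive levels, and the pooled
        (sigma, r) trend is positive.
        """
        from scipy.stats import spearmanr

        sigmas = [0.0, 0.3, 1.0]
        rs_by_level = []
        for sigma in sigmas:
            rs = []
            for seed in range(8):
                tree = simulate_tree(12, seed=300 + seed)
                truth = _minimal_truth(tree)
                es = EffectSizes(sigma_phylo=sigma, sigma_medium=0, sigma_source=0, sigma_noise=0.3)
                ft = simulate_metabolome(truth, es, n_features=150, seed=400 + seed)
                strain_mean = ft.data.groupby(ft.sample_meta["strain"]).mean()
                rs.append(
                    mantel(patristic(tree), bray_curtis_matrix(strain_mean), n_perm=99, seed=seed).observed
                )
            rs_by_level.append(rs)
        means = [np.mean(r) for r in rs_by_level]
        assert means[0] < means[1]
        assert means[0] < means[2]
        pooled_sigma = np.repeat(sigmas, len(rs_by_level[0]))
        pooled_r = np.concatenate(rs_by_level)
        assert spearmanr(pooled_sigma, pooled_r).statistic > 0

    def test_dominant_medium_effect_separates_media_on_first_axis(self):
        hits = 0
        for seed in range(10):
            tree = simulate_tree(10, seed=500 + seed)
            truth = _minimal_truth(tree)
            es = EffectSizes(sigma_phylo=0.1, sigma_medium=2.0, sigma_source=0, sigma_noise=0.3)
            ft = simulate_metabolome(truth, es, n_features=150, seed=600 + seed)
            res = pcoa(bray_curtis_matrix(ft.data))
            pc1 = res.coordinates["PC1"]
            media = ft.sample_meta["medium"]
            a, b = pc1[media == "GYM"], pc1[media == "V22"]
            if a.max() < b.min() or b.max() < a.min():
                hits += 1
        assert hits >= 9

    def test_single_active_sigma_is_recovered_by_the_matching_grouping(self):
        """Variance knobs are separable: only the active component's grouping
        comes out significant under PERMANOVA."""
        active_by = {"medium": 0, "source": 0, "clade": 0}
        inactive_fail = 0
        n_rep = 10
        for seed in range(n_rep):
            for active in ("medium", "source"):
                kwargs = dict(sigma_phylo=0, sigma_medium=0, sigma_source=0, sigma_noise=0.3)
                kwargs[f"sigma_{active}"] = 1.0
                tree = simulate_tree(12, seed=700 + seed)
                truth = _minimal_truth(tree)
                ft = simulate_metabolome(truth, EffectSizes(**kwargs), 120, seed=800 + seed)
                d = bray_curtis_matrix(ft.data)
                for grouping in ("medium", "source"):
                    p = permanova(d, ft.sample_meta[grouping], n_perm=99, seed=seed).p_value
                    if grouping == active:
                        active_by[active] += p <= 0.05
                    else:
                        inactive_fail += p <= 0.05
        assert active_by["medium"] >= 9
        assert active_by["source"] >= 9
        assert inactive_fail <= 0.15 * 2 * n_rep

    def test_missing_group_assignment_rejected(self):
        tree = simulate_tree(5, seed=3)
        truth = _minimal_truth(tree)
        del truth.group_assignments["source"][leaf_labels(tree)[0]]
        with pytest.raises(ValueError):
            simulate_metabolome(truth, EffectSizes(), 10, seed=0)


class TestCoordinateTables:
    def test_bg_labels_consistent_with_intervals(self, small_truth):
        genes = small_truth.gene_calls.set_index("gene_id")
        labels = small_truth.bg_labels.set_index("gene_id")
        bgcs = small_truth.bgcs
        for gid, row in genes.iterrows():
            contained = (
                (bgcs["genome_id"] == row["genome_id"])
                & (bgcs["contig_id"] == row["contig_id"])
                & (bgcs["start"] <= row["start"])
                & (row["stop"] <= bgcs["stop"])
            ).any()
            assert contained == labels.loc[gid, "is_bg"]

    def test_bgc_intervals_span_contiguous_gene_runs(self, small_truth):
        genes = small_truth.gene_calls
        for _, bgc in small_truth.bgcs.iterrows():
            members = genes[
                (genes["genome_id"] == bgc["genome_id"])
                & (genes["contig_id"] == bgc["contig_id"])
                & (genes["start"] >= bgc["start"])
                & (genes["stop"] <= bgc["stop"])
            ]
            assert len(members) >= 2
            assert bgc["start"] == members["start"].min()
            assert bgc["stop"] == members["stop"].max()

    def test_presence_round_trip(self, small_truth):
        rebuilt = build_presence(small_truth.bgcs)
        expected = small_truth.gcf_presence
        rebuilt = rebuilt.reindex(index=expected.index, columns=expected.columns, fill_value=0)
        pd.testing.assert_frame_equal(rebuilt, expected)

    def test_no_presence_means_no_bg_labels(self):
        tree = simulate_tree(4, seed=8)
        strains = leaf_labels(tree)
        presence = pd.DataFrame(0, index=strains, columns=["GCF0001"])
        truth = _minimal_truth(tree, presence=presence)
        _, bgcs, labels = emit_coordinate_tables(truth, 50, 0, seed=1)
        assert len(bgcs) == 0
        assert not labels["is_bg"].any()

    def test_seeded_rerun_identical(self, small_truth):
        g1, b1, l1 = emit_coordinate_tables(small_truth, 180, 8, seed=77)
        g2, b2, l2 = emit_coordinate_tables(small_truth, 180, 8, seed=77)
        pd.testing.assert_frame_equal(g1, g2)
        pd.testing.assert_frame_equal(b1, b2)
        pd.testing.assert_frame_equal(l1, l2)


def test_ani_ddh_span_thresholds(small_truth):
    ani, ddh = simulate_ani_ddh(small_truth.tree)
    assert np.allclose(np.diag(ani), 100)
    assert (ani.to_numpy() >= 78 - 1e-9).all()
    assert ani.to_numpy().min() < 95
    assert ddh.to_numpy().min() < 70


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(n_strains=2)
    with pytest.raises(ValueError):
        SimConfig(tree_model="coalescent")
    with pytest.raises(ValueError):
        EffectSizes(sigma_phylo=-0.1)
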