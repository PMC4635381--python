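"""MSP distances, dendrograms, Newick export, and gel views."""

import itertools

import numpy as np
import pytest
import skbio

import archaeotype as at

from conftest import make_reference


def random_reference(rng, strain_id="r", n=15):
    return make_reference(
        np.sort(rng.uniform(2500, 19000, n)), rng.uniform(10, 100, n),
        strain_id=strain_id,
    )


class TestMspDistance:
    def test_identical_msps_distance_zero(self):
        a = make_reference([3000.0, 6000.0, 9000.0], [10.0, 20.0, 30.0])
        assert at.msp_distance(a, a) == 0.0

    def test_disjoint_msps_distance_1000(self):
        a = make_reference([3000.0, 6000.0, 9000.0])
        b = make_reference([4000.0, 7000.0, 10000.0])
        assert at.msp_distance(a, b) == 1000.0

    @pytest.mark.parametrize("seed", range(10))
    def test_symmetric_in_both_arguments(self, seed):
        rng = np.random.default_rng(seed)
        a = random_reference(rng, "a")
        b = random_reference(rng, "b")
        assert at.msp_distance(a, b) == pytest.approx(at.msp_distance(b, a))

    def test_bounded_premetric(self):
        rng = np.random.default_rng(77)
        refs = [random_reference(rng, f"s{k}") for k in range(5)]
        for a, b in itertools.combinations(refs, 2):
            d = at.msp_distance(a, b)
            assert 0.0 <= d <= 1000.0
        for a in refs:
            assert at.msp_distance(a, a) == 0.0


def naive_average_linkage(d):
    """Brute-force agglomerative average linkage; returns sorted merge heights."""
    clusters = [[i] for i in range(d.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for x, y in itertools.combinations(range(len(clusters)), 2):
            dist = np.mean([d[i, j] for i in clusters[x] for j in clusters[y]])
            if best is None or dist < best[0]:
                best = (dist, x, y)
        dist, x, y = best
        heights.append(dist)
        merged = clusters[x] + clusters[y]
        clusters = [c for k, c in enumerate(clusters) if k not in (x, y)]
        clusters.append(merged)
    return sorted(heights)


class TestBuildDendrogram:
    def test_two_identical_one_disjoint(self):
        a = make_reference([3000.0, 6000.0, 9000.0], strain_id="a")
        b = make_reference([3000.0, 6000.0, 9000.0], strain_id="b")
        c = make_reference([4000.0, 7000.0, 10000.0], strain_id="c")
        tree = at.build_dendrogram([a, b, c])
        heights = tree.merge_heights()
        assert heights[0] == 0.0
        assert heights[1] == 1000.0
        left, right = tree.root_bipartition()
        assert {frozenset({"a", "b"}), frozenset({"c"})} == {left, right}

    def test_single_msp_rejected(self):
        with pytest.raises(at.InputError):
            at.build_dendrogram([make_reference([3000.0])])

    @pytest.mark.parametrize("n_leaves", [4, 5, 6])
    def test_average_linkage_matches_bruteforce(self, n_leaves):
        rng = np.random.default_rng(n_leaves)
        refs = [random_reference(rng, f"s{k}") for k in range(n_leaves)]
        tree = at.build_dendrogram(refs)
        d = at.distance_matrix(refs).d
        np.testing.assert_allclose(
            sorted(tree.merge_heights()), naive_average_linkage(d), rtol=1e-9
        )

    def test_topology_invariant_to_input_order(self):
        rng = np.random.default_rng(123)
        refs = [random_reference(rng, f"s{k}") for k in range(6)]
        base = at.to_newick(at.build_dendrogram(refs))
        for _ in range(10):
            rng.shuffle(refs)
            assert at.to_newick(at.build_dendrogram(refs)) == base

    def test_planted_taxonomy_distance_ordering(self):
        """Within-species < within-genus < between-genus mean distances."""
        within_sp, within_gen, between = [], [], []
        for seed in range(5):
            spec = at.PanelSpec(n_genera=2, species_per_genus=2,
                                strains_per_species=2, n_replicates=10, seed=seed)
            models, spectra, _ = at.make_panel(spec, at.SimulationConfig(seed=seed))
            lib = []
            for m in models:
                pls = [at.preprocess(s) for s in spectra[m.strain_id]]
                lib.append(at.build_msp(pls, m.strain_id)[0])
            tax = {m.strain_id: m.taxonomy for m in models}
            for a, b in itertools.combinations(lib, 2):
                d = at.msp_distance(a, b)
                ga, sa = tax[a.strain_id]
                gb, sb = tax[b.strain_id]
                if sa == sb:
                    within_sp.append(d)
                elif ga == gb:
                    within_gen.append(d)
                else:
                    between.append(d)
        assert np.mean(within_sp) < np.mean(within_gen) < np.mean(between)


class TestNewick:
    def test_two_leaf_tree_splits_height(self):
        a = make_reference([3000.0, 6000.0, 9000.0], strain_id="A")
        b = make_reference([4000.0, 7000.0, 10000.0], strain_id="B")
        tree = at.build_dendrogram([a, b])
        assert at.to_newick(tree) == "(A:500,B:500);"

    def test_round_trip_preserves_topology(self):
        rng = np.random.default_rng(9)
        refs = [random_reference(rng, f"s{k}") for k in range(6)]
        tree = at.build_dendrogram(refs)
        parsed = skbio.TreeNode.read([at.to_newick(tree)])
        assert {t.name for t in parsed.tips()} == set(tree.labels)
        left, right = tree.root_bipartition()
        parsed_parts = {
            frozenset(t.name for t in child.tips()) if not child.is_tip()
            else frozenset({child.name})
            for child in parsed.children
        }
        assert parsed_parts == {left, right}

    def test_labels_with_spaces_quoted(self, tmp_path):
        a = make_reference([3000.0, 6000.0], strain_id="Halobacterium sp. A")
        b = make_reference([4000.0, 7000.0], strain_id="strain B")
        tree = at.build_dendrogram([a, b])
        text = at.to_newick(tree)
        assert "'Halobacterium sp. A'" in text and "'strain B'" in text
        f = tmp_path / "t.nwk"
        at.write_newick(tree, f)
        assert f.read_text().strip() == text


class TestGelView:
    def test_single_strain_three_peaks_three_cells(self):
        msp = make_reference([2505.0, 8000.0, 15000.0], strain_id="only")
        gel = at.gel_view_matrix([msp], bin_width=10.0)
        assert (gel.loc["only"] > 0).sum() == 3

    def test_row_order_equals_dendrogram_leaf_order(self):
        rng = np.random.default_rng(4)
        refs = [random_reference(rng, f"s{k}") for k in range(5)]
        tree = at.build_dendrogram(refs)
        gel = at.gel_view_matrix(refs, tree=tree)
        assert list(gel.index) == tree.leaf_order()

    def test_shared_peak_forms_column_block(self):
        shared = 9005.0
        refs = [
            make_reference([3000.0 + 700 * k, shared], strain_id=f"g1s{k}")
            for k in range(3)
        ] + [make_reference([16000.0, 17000.0, 18000.0], strain_id="g2")]
        gel = at.gel_view_matrix(refs, bin_width=10.0)
        col = gel[9000.0]
        assert all(col.loc[f"g1s{k}"] > 0 for k in range(3))
        assert col.loc["g2"] == 0

    def test_empty_library_rejected(self):
        with pytest.raises(at.InputError):
            at.gel_view_matrix([])
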