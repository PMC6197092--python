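"""PCA, classical MDS and neighbor-joining."""

import io

import dendropy
import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

import strpopkit as sk
from strpopkit import AlleleLabel, DistanceMatrix, FrequencyTable, StrDataError


def ft(name, **loci):
    return FrequencyTable(
        name,
        {l: {AlleleLabel.from_number(a): f for a, f in m.items()} for l, m in loci.items()},
    )


def random_additive_tree(rng, n=6):
    """Random unrooted binary tree with positive branch lengths and its
    exact leaf-to-leaf path-length matrix (brute force over the tree)."""
    import networkx as nx

    leaves = [f"T{i}" for i in range(n)]
    g = nx.Graph()
    nodes = list(leaves)
    nxt = 0
    while len(nodes) > 3:
        rng.shuffle(nodes)
        a, b = nodes.pop(), nodes.pop()
        new = f"I{nxt}"; nxt += 1
        g.add_edge(a, new, length=rng.uniform(0.1, 2.0))
        g.add_edge(b, new, length=rng.uniform(0.1, 2.0))
        nodes.append(new)
    center = f"I{nxt}"
    for v in nodes:
        g.add_edge(v, center, length=rng.uniform(0.1, 2.0))
    import networkx as nx_

    d = dict(nx_.all_pairs_dijkstra_path_length(g, weight="length"))
    labels = sorted(leaves)
    m = np.array([[d[a][b] if a != b else 0.0 for b in labels] for a in labels])
    m = (m + m.T) / 2.0  # dijkstra sums in different orders leave ~1e-16 asymmetry
    return DistanceMatrix(labels, m), g


class TestPca:
    def test_identical_populations_have_zero_explained_variance(self):
        t = ft("a", L={8: 0.4, 9: 0.6})
        tabs = {n: FrequencyTable(n, t.freqs) for n in "abc"}
        res = sk.pca_frequencies(tabs)
        assert np.allclose(res.explained_percent, 0.0)

    def test_rank_one_line_explained_by_first_component(self):
        tabs = {
            "a": ft("a", L={8: 0.2, 9: 0.8}),
            "b": ft("b", L={8: 0.4, 9: 0.6}),
            "c": ft("c", L={8: 0.6, 9: 0.4}),
            "d": ft("d", L={8: 0.8, 9: 0.2}),
        }
        res = sk.pca_frequencies(tabs)
        assert res.explained_percent[0] == pytest.approx(100.0, abs=1e-9)

    def test_duplicated_populations_coincide_in_score_space(self, panel):
        pops = sk.balding_nichols_freqs(panel.frequencies, 3, 0.05, seed=1)
        names = list(pops)
        pops["dup"] = FrequencyTable("dup", pops[names[0]].freqs)
        res = sk.pca_frequencies(pops)
        a = res.coordinates.loc[names[0]].to_numpy()
        b = res.coordinates.loc["dup"].to_numpy()
        assert np.abs(a - b).max() < 1e-9

    def test_explained_sums_to_100_at_full_rank(self, panel):
        pops = sk.balding_nichols_freqs(panel.frequencies, 5, 0.1, seed=2)
        res = sk.pca_frequencies(pops)
        assert res.explained_percent.sum() == pytest.approx(100.0, abs=1e-9)

    def test_matches_sklearn(self, panel):
        from sklearn.decomposition import PCA

        pops = sk.balding_nichols_freqs(panel.frequencies, 5, 0.1, seed=3)
        res = sk.pca_frequencies(pops, k=2)
        from strpopkit.phylo import frequency_matrix
        X = frequency_matrix(pops).to_numpy()
        ref = PCA(n_components=2).fit_transform(X)
        ours = res.coordinates.to_numpy()
        for j in range(2):  # sign conventions may differ per component
            assert min(np.abs(ours[:, j] - ref[:, j]).max(),
                       np.abs(ours[:, j] + ref[:, j]).max()) < 1e-8

    def test_fewer_than_three_populations_rejected(self):
        tabs = {n: ft(n, L={8: 1.0}) for n in "ab"}
        with pytest.raises(StrDataError):
            sk.pca_frequencies(tabs)


class TestClassicalMds:
    def test_reconstructs_planar_point_set(self):
        rng = np.random.default_rng(4)
        pts = rng.random((6, 2))
        dm = DistanceMatrix(list("ABCDEF"), squareform(pdist(pts)))
        res = sk.classical_mds(dm, k=2)
        emb = squareform(pdist(res.coordinates.to_numpy()))
        assert np.abs(emb - dm.values).max() < 1e-6

    def test_all_zero_matrix_gives_origin(self):
        dm = DistanceMatrix(list("abc"), np.zeros((3, 3)))
        res = sk.classical_mds(dm, k=2)
        assert np.allclose(res.coordinates.to_numpy(), 0.0)

    def test_k_beyond_positive_eigenvalues_pads_zeros(self):
        pts = np.array([[0.0], [1.0], [3.0]])
        dm = DistanceMatrix(list("abc"), squareform(pdist(pts)))
        res = sk.classical_mds(dm, k=3)
        assert np.allclose(res.coordinates.to_numpy()[:, 1:], 0.0, atol=1e-9)

    def test_asymmetric_matrix_rejected(self):
        dm = DistanceMatrix(list("ab"), np.zeros((2, 2)))
        dm.values = np.array([[0.0, 1.0], [2.0, 0.0]])  # corrupt after validation
        with pytest.raises(StrDataError):
            sk.classical_mds(dm, k=1)

    def test_idempotent_on_own_euclidean_output(self):
        rng = np.random.default_rng(5)
        pts = rng.random((5, 2))
        dm = DistanceMatrix(list("abcde"), squareform(pdist(pts)))
        first = sk.classical_mds(dm, k=2).coordinates.to_numpy()
        dm2 = DistanceMatrix(list("abcde"), squareform(pdist(first)))
        second = sk.classical_mds(dm2, k=2).coordinates.to_numpy()
        assert np.abs(squareform(pdist(second)) - dm2.values).max() < 1e-9


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(list("ABC"), np.array(
            [[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]]))
        tree = sk.nj_tree(dm)
        center = [v for v in tree.graph if v not in set("ABC")][0]
        limbs = {leaf: tree.graph[leaf][center]["length"] for leaf in "ABC"}
        assert limbs == {"A": pytest.approx(1.0), "B": pytest.approx(2.0),
                         "C": pytest.approx(3.0)}

    def test_recovers_random_additive_trees(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            dm, _ = random_additive_tree(rng, n=6)
            tree = sk.nj_tree(dm)
            rec = tree.path_length_matrix()
            assert rec.labels == dm.labels
            assert np.abs(rec.values - dm.values).max() < 1e-9

    def test_star_tree_has_zero_internal_branches(self):
        n = 5
        labels = [f"T{i}" for i in range(n)]
        m = np.full((n, n), 2.0)
        np.fill_diagonal(m, 0.0)
        tree = sk.nj_tree(DistanceMatrix(labels, m))
        internal = [e for e in tree.graph.edges(data=True)
                    if e[0] not in labels and e[1] not in labels]
        assert all(abs(d["length"]) < 1e-9 for _, _, d in internal)

    def test_matches_skbio_topology(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(7)
        dm, _ = random_additive_tree(rng, n=7)
        ours = sk.nj_tree(dm)
        ref = skbio_nj(SkbioDM(dm.values, ids=dm.labels))
        ref_d = {frozenset((a, b)): ref.find(a).distance(ref.find(b))
                 for i, a in enumerate(dm.labels) for b in dm.labels[i + 1:]}
        our_m = ours.path_length_matrix()
        for i, a in enumerate(dm.labels):
            for b in dm.labels[i + 1:]:
                assert our_m[a, b] == pytest.approx(ref_d[frozenset((a, b))], abs=1e-6)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(StrDataError):
            sk.nj_tree(DistanceMatrix(["A", "B"], np.zeros((2, 2))))

    def test_newick_round_trips_through_dendropy(self, tmp_path):
        rng = np.random.default_rng(8)
        dm, _ = random_additive_tree(rng, n=6)
        tree = sk.nj_tree(dm)
        nwk = tree.to_newick()
        assert nwk.endswith(";")
        dt = dendropy.Tree.get(data=nwk, schema="newick")
        pdm = dt.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in dt.taxon_namespace}
        our_m = tree.path_length_matrix()
        for i, a in enumerate(dm.labels):
            for b in dm.labels[i + 1:]:
                assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(
                    our_m[a, b], abs=1e-8)


class TestPipeline:
    def test_three_population_newick(self, panel, tmp_path):
        pops = sk.balding_nichols_freqs(panel.frequencies, 3, 0.05, seed=9)
        tabs = {n: sk.FrequencyTable(n, t.freqs, {l: 100 for l in t.loci})
                for n, t in pops.items()}
        out = sk.pipeline_phylo(tabs, out_prefix=str(tmp_path / "run"))
        assert sorted(out["tree"].leaves) == sorted(tabs)
        dendropy.Tree.get(data=out["newick"], schema="newick")
        assert (tmp_path / "run_nj.nwk").exists()
        assert (tmp_path / "run_da.phy").exists()

    def test_deterministic_outputs(self, panel, tmp_path):
        pops = sk.balding_nichols_freqs(panel.frequencies, 4, 0.05, seed=10)
        tabs = {n: sk.FrequencyTable(n, t.freqs, {l: 100 for l in t.loci})
                for n, t in pops.items()}
        a = sk.pipeline_phylo(tabs, out_prefix=str(tmp_path / "a"))
        b = sk.pipeline_phylo(tabs, out_prefix=str(tmp_path / "b"))
        assert (tmp_path / "a_nj.nwk").read_bytes() == (tmp_path / "b_nj.nwk").read_bytes()
        assert (tmp_path / "a_da.csv").read_text() == (tmp_path / "b_da.csv").read_text()

    def test_han_like_populations_cluster(self, panel):
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(2000 + rep)
            han = sk.balding_nichols_freqs(panel.frequencies, 3, 0.005,
                                           seed=rng, name_prefix="Han")
            other = sk.balding_nichols_freqs(panel.frequencies, 11, 0.05,
                                             seed=rng, name_prefix="Ref")
            da = sk.nei_da_matrix({**han, **other})
            tree = sk.nj_tree(da)
            hits += tree.leaves_form_subtree(["Han1", "Han2", "Han3"])
        assert hits >= 9
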