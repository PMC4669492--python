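"""Phylogeny: p-distance, NJ exactness on additive matrices, bootstrap supports."""

import itertools

import numpy as np
import pandas as pd
import pytest

from spinachseq import phylogeny as ph
from spinachseq import synthetic_data as sd


def _table(rows, accs, contig="c1"):
    idx = pd.MultiIndex.from_tuples(
        [(contig, i + 1) for i in range(len(rows))], names=["contig", "pos"]
    )
    return pd.DataFrame(rows, index=idx, columns=accs)


class TestPDistance:
    def test_identical_rows_zero(self):
        table = _table([["A", "A"], ["C", "C"], ["G", "G"]], ["x", "y"])
        d = ph.p_distance_matrix(table)
        assert d.loc["x", "y"] == 0.0

    def test_quarter_distance(self):
        table = _table([["A", "A"], ["C", "C"], ["G", "G"], ["T", "A"]], ["x", "y"])
        assert ph.p_distance_matrix(table).loc["x", "y"] == 0.25

    def test_matches_brute_force_with_missing(self):
        rng = np.random.default_rng(3)
        data = rng.choice(["A", "G"], size=(50, 5)).astype(object)
        data[rng.random((50, 5)) < 0.2] = np.nan
        table = _table(list(data), [f"a{i}" for i in range(5)])
        d = ph.p_distance_matrix(table)
        for i, j in itertools.combinations(range(5), 2):
            diff = shared = 0
            for s in range(50):
                x, y = data[s, i], data[s, j]
                if pd.isna(x) or pd.isna(y):
                    continue
                shared += 1
                diff += x != y
            assert d.iloc[i, j] == pytest.approx(diff / shared)

    def test_zero_shared_sites_named_error(self):
        table = _table([["A", np.nan], [np.nan, "G"]], ["x", "y"])
        with pytest.raises(ValueError, match="'x' and 'y'"):
            ph.p_distance_matrix(table)


def _random_additive(rng, n):
    """Random binary tree with positive branch lengths -> (distance df, bipartitions).

    Built by sequential random joins; after a join, ``lengths[leaf]`` is the path
    length from the leaf to the newly created node, so leaves on opposite sides
    are exactly ``lengths[a] + lengths[b]`` apart.
    """
    labels = [f"t{i}" for i in range(n)]
    dist = np.zeros((n, n))
    clusters = [[i] for i in range(n)]
    parts = []
    lengths = {i: 0.0 for i in range(n)}
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        li, lj = rng.uniform(0.05, 1.0, size=2)
        for a in clusters[i]:
            lengths[a] += li
        for b in clusters[j]:
            lengths[b] += lj
        for a in clusters[i]:
            for b in clusters[j]:
                dist[a, b] = dist[b, a] = lengths[a] + lengths[b]
        merged = clusters[i] + clusters[j]
        if 2 <= len(clusters[i]) <= n - 2:
            parts.append(frozenset(labels[a] for a in clusters[i]))
        if 2 <= len(clusters[j]) <= n - 2:
            parts.append(frozenset(labels[a] for a in clusters[j]))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return pd.DataFrame(dist, index=labels, columns=labels), parts


def _tree_distance_matrix(tree: ph.SupportTree) -> pd.DataFrame:
    labels = sorted(tree.leaves)
    out = pd.DataFrame(0.0, index=labels, columns=labels)
    for a, b in itertools.combinations(labels, 2):
        out.loc[a, b] = out.loc[b, a] = tree.path_length(a, b)
    return out


class TestNeighborJoining:
    def test_four_taxon_worked_example(self):
        # d(A,B)=d(C,D)=2, cross pairs 4: additive with AB|CD and internal edge 2
        labels = list("ABCD")
        d = pd.DataFrame(
            [[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]],
            index=labels, columns=labels, dtype=float,
        )
        # oracle: least-squares score of all three resolved quartet topologies,
        # fitting the five branch lengths per topology by ordinary least squares
        def ls_score(split):
            (a, b), (c, d2) = split
            # path-length design matrix for pairs under topology ab|cd
            pairs = list(itertools.combinations(labels, 2))
            cols = {a: 0, b: 1, c: 2, d2: 3}
            x = np.zeros((len(pairs), 5))
            for r, (p, q) in enumerate(pairs):
                x[r, cols[p]] = x[r, cols[q]] = 1
                same_side = {p, q} in ({a, b}, {c, d2})
                if not same_side:
                    x[r, 4] = 1
            y = np.array([d.loc[p, q] for p, q in pairs])
            beta, *_ = np.linalg.lstsq(x, y, rcond=None)
            resid = y - x @ beta
            return float(resid @ resid)

        splits = [(("A", "B"), ("C", "D")), (("A", "C"), ("B", "D")),
                  (("A", "D"), ("B", "C"))]
        scores = {s: ls_score(s) for s in splits}
        assert min(scores, key=scores.get) == (("A", "B"), ("C", "D"))
        assert scores[(("A", "B"), ("C", "D"))] == pytest.approx(0.0, abs=1e-18)

        tree = ph.neighbor_joining(d)
        assert frozenset({"C", "D"}) in tree.bipartitions() or frozenset(
            {"A", "B"}
        ) in tree.bipartitions()
        # tree reproduces the additive matrix, so the internal edge is 2
        recovered = _tree_distance_matrix(tree)
        np.testing.assert_allclose(
            recovered.to_numpy(), d.loc[recovered.index, recovered.columns].to_numpy(),
            atol=1e-12,
        )

    def test_three_taxa_closed_form(self):
        labels = list("ABC")
        d = pd.DataFrame(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]], index=labels, columns=labels, dtype=float
        )
        tree = ph.neighbor_joining(d)
        # three-point formulas: a=(3+4-5)/2=1, b=(3+5-4)/2=2, c=(4+5-3)/2=3
        assert tree.path_length("A", "B") == pytest.approx(3)
        assert tree.path_length("A", "C") == pytest.approx(4)
        assert tree.path_length("B", "C") == pytest.approx(5)
        assert tree.newick().startswith("(A:1")

    def test_fewer_than_three_taxa_rejected(self):
        d = pd.DataFrame([[0, 1], [1, 0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError, match=">= 3"):
            ph.neighbor_joining(d)

    @pytest.mark.parametrize("seed", range(10))
    def test_additive_matrices_recovered_exactly(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        d, parts = _random_additive(rng, n)
        tree = ph.neighbor_joining(d)
        recovered = _tree_distance_matrix(tree)
        np.testing.assert_allclose(
            recovered.loc[d.index, d.columns].to_numpy(), d.to_numpy(), atol=1e-9
        )
        for side in parts:
            assert tree.has_clade(side)

    def test_agrees_with_skbio_on_additive_input(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(99)
        d, _ = _random_additive(rng, 7)
        ours = ph.neighbor_joining(d)
        dm = skbio.DistanceMatrix(d.to_numpy(), ids=list(d.index))
        theirs = skbio.tree.nj(dm)
        their_parts = set()
        for node in theirs.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            their_parts.add(ours.canonical_side(side))
        expected = {p for p in their_parts if 2 <= len(p) <= len(d) - 2}
        assert ours.bipartitions() == expected


class TestBootstrap:
    def test_unanimous_split_gets_full_support(self):
        rows = [["A", "A", "G", "G", "G"]] * 12
        table = _table(rows, list("abcde"))
        tree = ph.bootstrap_tree(table, replicates=50, seed=0)
        side = tree.canonical_side(frozenset({"a", "b"}))
        assert tree.supports[side] == 100.0

    def test_single_replicate_supports_are_zero_or_hundred(self):
        rng = np.random.default_rng(12)
        rows = rng.choice(["A", "C"], size=(30, 5)).astype(object)
        table = _table(list(rows), list("abcde"))
        tree = ph.bootstrap_tree(table, replicates=1, seed=5)
        assert set(tree.supports.values()) <= {0.0, 100.0}

    def test_supports_invariant_to_column_permutation(self):
        rng = np.random.default_rng(4)
        rows = rng.choice(["A", "C"], size=(60, 6)).astype(object)
        table = _table(list(rows), list("abcdef"))
        tree1 = ph.bootstrap_tree(table, replicates=30, seed=9)
        shuffled = table[list("fcadbe")]
        tree2 = ph.bootstrap_tree(shuffled, replicates=30, seed=9)
        assert tree1.supports == tree2.supports

    def test_species_bipartitions_strongly_supported(self):
        scenario = sd.SpeciesScenario(
            species_labels=("A", "B", "C"),
            accessions_per_species=(3, 3, 2),
            species_tree="((A:0.01,B:0.01):0.04,C:0.05):0.0;",
            accession_branch_length=0.003,
        )
        cfg = sd.SimulationConfig(n_unigenes=300, n_snp_sites=600, seed=15)
        truth = sd.plant_genotypes(sd.generate_unigenes(cfg), scenario, cfg)
        geno = truth.planted_site_genotypes.T  # sites x accessions
        tree = ph.bootstrap_tree(geno, replicates=200, seed=15)
        groups = scenario.groups(true=True)
        for sp in ("A", "B"):
            side = tree.canonical_side(frozenset(groups[sp]))
            assert tree.supports[side] >= 95.0

    def test_true_topology_recovered_across_seeds(self, scenario_clean):
        hits = 0
        for seed in range(20):
            cfg = sd.SimulationConfig(n_unigenes=300, n_snp_sites=500, seed=100 + seed)
            truth = sd.plant_genotypes(
                sd.generate_unigenes(cfg), scenario_clean, cfg
            )
            tree = ph.neighbor_joining(
                ph.p_distance_matrix(truth.planted_site_genotypes.T)
            )
            groups = scenario_clean.groups(true=True)
            if all(tree.has_clade(set(m)) for m in groups.values()):
                hits += 1
        assert hits == 20


class TestNewick:
    def test_three_leaf_shape(self):
        labels = list("ABC")
        d = pd.DataFrame(
            [[0, 2, 2], [2, 0, 2], [2, 2, 0]], index=labels, columns=labels, dtype=float
        )
        assert ph.neighbor_joining(d).newick() == "(A:1,B:1,C:1);"

    def test_labels_with_spaces_quoted(self):
        labels = ["tax one", "tax two", "tax three"]
        d = pd.DataFrame(
            [[0, 2, 2], [2, 0, 2], [2, 2, 0]], index=labels, columns=labels, dtype=float
        )
        text = ph.neighbor_joining(d).newick()
        assert "'tax one'" in text

    def test_round_trip_preserves_structure(self, tmp_path):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(2)
        rows = rng.choice(["A", "C"], size=(40, 6)).astype(object)
        table = _table(list(rows), list("abcdef"))
        tree = ph.bootstrap_tree(table, replicates=20, seed=3)
        text = ph.write_newick(tree, tmp_path / "t.nwk")
        parsed = dendropy.Tree.get(data=text, schema="newick")
        assert {t.taxon.label for t in parsed.leaf_node_iter()} == tree.leaves
        parsed.encode_bipartitions()
        # every internal support value written must be readable back as a label
        supports_in_text = {
            float(node.label)
            for node in parsed.preorder_internal_node_iter()
            if node.label is not None
        }
        assert supports_in_text <= set(tree.supports.values())
        # branch lengths round-trip: total tree length preserved
        total_ours = sum(
            length
            for u, nbrs in tree.adjacency.items()
            for v, length in nbrs.items()
        ) / 2
        total_parsed = sum(
            e.length for e in parsed.preorder_edge_iter() if e.length is not None
        )
        assert total_parsed == pytest.approx(total_ours, rel=1e-9)
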