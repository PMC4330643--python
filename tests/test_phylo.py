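import math

import dendropy
import numpy as np
import pytest
from scipy.linalg import expm

from capclade.anchor import MultiAlignment
from capclade.phylo import (
    DistanceMatrix,
    SubstitutionModel,
    _bipartitions,
    bootstrap_support,
    compare_frequency_models,
    distance_matrix,
    empirical_frequencies,
    estimate_gamma_shape,
    nj_tree,
    pairwise_distance,
    tree_log_likelihood,
)
from capclade.seqio import AMINO_ACIDS
from capclade.simulate import evolve_sequence


def _aln(ids_rows, core_start=38):
    ids = [i for i, _ in ids_rows]
    return MultiAlignment(ids=ids, matrix=[r for _, r in ids_rows],
                          insertions={i: [] for i in ids}, core_start=core_start)


@pytest.fixture(scope="module")
def lg():
    return SubstitutionModel.load("LG")


class TestModel:
    def test_rate_matrix_normalized(self, lg):
        Q = lg.rate_matrix()
        assert np.allclose(Q.sum(axis=1), 0, atol=1e-12)
        assert -(lg.pi * np.diag(Q)).sum() == pytest.approx(1.0)

    def test_transition_matrix_against_expm(self, lg):
        Q = lg.rate_matrix()
        for t in (0.01, 0.3, 2.0):
            assert np.allclose(lg.transition_matrix(t), expm(Q * t), atol=1e-10)

    def test_stationarity_and_reversibility(self, lg):
        P = lg.transition_matrix(0.7)
        assert np.allclose(lg.pi @ P, lg.pi, atol=1e-12)
        flux = lg.pi[:, None] * P
        assert np.allclose(flux, flux.T, atol=1e-12)

    def test_gamma_category_rates_mean_one(self, lg):
        for alpha in (0.2, 1.0, 5.0):
            rates = lg.with_alpha(alpha).category_rates()
            assert len(rates) == 4
            assert rates.mean() == pytest.approx(1.0, abs=1e-9)
            assert all(a < b for a, b in zip(rates, rates[1:]))


class TestDistances:
    def test_identical_rows_zero(self, lg):
        row = "ACDEFGHIKL" * 5
        for method in ("poisson", "kimura", "lg_ml"):
            assert pairwise_distance(row, row, method, lg) == pytest.approx(0.0, abs=1e-6)

    def test_kimura_half_different(self):
        a = "A" * 10
        b = "A" * 5 + "C" * 5
        assert pairwise_distance(a, b, "kimura") == pytest.approx(-math.log(0.45))

    def test_kimura_cap_on_saturation(self):
        a = "ACDEFGHIKLMNPQRSTVWY"
        b = "CDEFGHIKLMNPQRSTVWYA"
        with pytest.warns(UserWarning, match="capped"):
            assert pairwise_distance(a, b, "kimura") == 5.2

    def test_gaps_and_x_excluded_from_denominator(self):
        # gap and X columns are missing data: comparable columns are
        # 0, 3, 4 (identical) plus the C/G mismatch at 1
        assert pairwise_distance("AC-DE", "AGFDE", "poisson") == pytest.approx(
            -math.log(1 - 1 / 4))
        assert pairwise_distance("AC-DE", "AXFDE", "poisson") == 0.0

    def test_no_comparable_columns_errors(self):
        with pytest.raises(ValueError):
            pairwise_distance("A---", "-CCC", "poisson")

    def test_lg_ml_recovers_simulated_branch_length(self, lg):
        rng = np.random.default_rng(8)
        t_true = 0.3
        root = "".join(rng.choice(list(AMINO_ACIDS), size=10_000, p=lg.pi))
        tip = evolve_sequence(root, t_true, lg, rng)
        d = pairwise_distance(root, tip, "lg_ml", lg)
        assert abs(d - t_true) / t_true < 0.10


class TestNeighborJoining:
    def test_additive_four_taxon_exact(self):
        # distances from ((A:1,B:2):1,(C:3,D:1))
        ids = ["A", "B", "C", "D"]
        d = np.array([
            [0, 3, 5, 3],
            [3, 0, 6, 4],
            [5, 6, 0, 4],
            [3, 4, 4, 0],
        ], dtype=float)
        tree = nj_tree(DistanceMatrix(ids=ids, values=d))
        assert frozenset({"A", "B"}) in _bipartitions(tree) or \
               frozenset({"C", "D"}) in _bipartitions(tree)
        # path lengths reproduce the additive matrix exactly
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                if i < j:
                    assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(d[i, j])

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(ids=["a", "b", "c"], values=d))
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths == pytest.approx({"a": 0.5, "b": 1.5, "c": 2.5})

    def test_fewer_than_three_taxa_errors(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(ids=["a", "b"], values=np.zeros((2, 2))))

    def test_permutation_gives_isomorphic_tree(self):
        rng = np.random.default_rng(17)
        ids, d = _random_additive_matrix(rng, 7)
        t1 = nj_tree(DistanceMatrix(ids=ids, values=d))
        perm = list(rng.permutation(len(ids)))
        t2 = nj_tree(DistanceMatrix(ids=[ids[i] for i in perm],
                                    values=d[np.ix_(perm, perm)]))
        assert _bipartitions(t1) == _bipartitions(t2)

    def test_additive_recovery_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as sknj

        rng = np.random.default_rng(23)
        for n in (5, 8):
            ids, d = _random_additive_matrix(rng, n)
            mine = _bipartitions(nj_tree(DistanceMatrix(ids=ids, values=d)))
            sk = sknj(skbio.DistanceMatrix(d, ids=ids))
            theirs = _skbio_bipartitions(sk, ids)
            assert mine == theirs

    def test_negative_lengths_clamped(self):
        # non-additive matrix that provokes a negative NJ branch length
        d = np.array([
            [0, 0.1, 0.9, 1.0],
            [0.1, 0, 1.0, 0.9],
            [0.9, 1.0, 0, 0.1],
            [1.0, 0.9, 0.1, 0],
        ])
        tree = nj_tree(DistanceMatrix(ids=list("abcd"), values=d))
        assert all((n.edge.length or 0) >= 0 for n in tree)


def _random_additive_matrix(rng, n):
    """Distances induced by a random binary tree with positive lengths."""
    ids = [f"t{i}" for i in range(n)]
    nodes = {i: {i} for i in range(n)}
    dist = np.zeros((n, n))
    depth = {i: rng.uniform(0.1, 0.5) for i in range(n)}
    clusters = list(nodes)
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), 2, replace=False))
        cj, ci = clusters.pop(j), clusters.pop(i)
        li, lj = rng.uniform(0.1, 1.0), rng.uniform(0.1, 1.0)
        for a in nodes[ci]:
            for b in nodes[cj]:
                dist[a, b] = dist[b, a] = depth[a] + li + lj + depth[b]
        new = max(nodes) + 1
        nodes[new] = nodes[ci] | nodes[cj]
        for a in nodes[ci]:
            depth[a] += li
        for b in nodes[cj]:
            depth[b] += lj
        clusters.append(new)
    return ids, dist


def _skbio_bipartitions(sk_tree, ids):
    labels = sorted(ids)
    full = set(labels)
    out = set()
    for node in sk_tree.traverse(include_self=False):
        if node.is_tip():
            continue
        below = frozenset(t.name for t in node.tips())
        if labels[0] in below:
            below = frozenset(full - below)
        if 1 < len(below) < len(full) - 1:
            out.add(below)
    return out


class TestBootstrap:
    def test_clean_split_gets_full_support(self):
        rows = [("A", "A" * 200), ("B", "A" * 200),
                ("C", "A" * 100 + "C" * 100), ("D", "A" * 100 + "C" * 100)]
        tws = bootstrap_support(_aln(rows), B=30, seed=0)
        supports = [n.edge.support for n in tws.tree.preorder_node_iter()
                    if getattr(n.edge, "support", None) is not None]
        assert supports and all(s == 100.0 for s in supports)

    def test_reproducible_for_fixed_seed(self, core_small):
        t1 = bootstrap_support(core_small, B=10, seed=7)
        t2 = bootstrap_support(core_small, B=10, seed=7)
        s1 = sorted(n.edge.support for n in t1.tree.preorder_node_iter()
                    if getattr(n.edge, "support", None) is not None)
        s2 = sorted(n.edge.support for n in t2.tree.preorder_node_iter()
                    if getattr(n.edge, "support", None) is not None)
        assert s1 == s2

    def test_single_replicate_support_binary(self, core_small):
        tws = bootstrap_support(core_small, B=1, seed=3)
        supports = {n.edge.support for n in tws.tree.preorder_node_iter()
                    if getattr(n.edge, "support", None) is not None}
        assert supports <= {0.0, 100.0}


@pytest.fixture(scope="module")
def core_small():
    rng = np.random.default_rng(5)
    lg = SubstitutionModel.load("LG")
    root = "".join(rng.choice(list(AMINO_ACIDS), size=150, p=lg.pi))
    rows = []
    for i, t in enumerate((0.1, 0.2, 0.4, 0.6, 0.8)):
        rows.append((f"s{i}", evolve_sequence(root, t, lg, rng)))
    return _aln(rows)


class TestLikelihood:
    def _two_taxon(self, col_a, col_b, t):
        tree = dendropy.Tree.get(data=f"(a:{t / 2},b:{t / 2});", schema="newick")
        m = _aln([("a", col_a), ("b", col_b)])
        return tree, m

    def test_limit_of_zero_branch_length(self, lg):
        tree, m = self._two_taxon("A", "A", 1e-9)
        lnl = tree_log_likelihood(tree, m, lg)
        assert lnl == pytest.approx(math.log(lg.pi[0]), abs=1e-6)

    def test_two_taxon_matches_matrix_exponential_oracle(self, lg):
        """Pruning equals the closed form sum_r pi_a P_ab(t r)/K computed
        with an independent scipy matrix exponential."""
        model = lg.with_alpha(0.7)
        Q = model.rate_matrix()
        rates = model.category_rates()
        rng = np.random.default_rng(2)
        t = 0.85
        cols = [(rng.integers(20), rng.integers(20)) for _ in range(30)]
        row_a = "".join(AMINO_ACIDS[a] for a, _ in cols)
        row_b = "".join(AMINO_ACIDS[b] for _, b in cols)
        tree, m = self._two_taxon(row_a, row_b, t)
        expected = 0.0
        for a, b in cols:
            site = sum(model.pi[a] * expm(Q * t * r)[a, b] for r in rates) / len(rates)
            expected += math.log(site)
        got = tree_log_likelihood(tree, m, model)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_gap_is_missing_data(self, lg):
        tree, m = self._two_taxon("A", "-", 0.4)
        assert tree_log_likelihood(tree, m, lg) == pytest.approx(
            math.log(lg.pi[0]), abs=1e-12)

    def test_rerooting_invariance(self, lg):
        """Pulley principle: the likelihood of an unrooted topology does
        not depend on where the root is placed."""
        rng = np.random.default_rng(31)
        model = lg.with_alpha(1.2)
        root = "".join(rng.choice(list(AMINO_ACIDS), size=60, p=model.pi))
        rows = [(f"s{i}", evolve_sequence(root, rng.uniform(0.05, 0.5), model, rng))
                for i in range(6)]
        m = _aln(rows)
        newick = "((s0:0.1,s1:0.2):0.15,(s2:0.3,(s3:0.1,s4:0.2):0.05):0.1,s5:0.4);"
        base_tree = dendropy.Tree.get(data=newick, schema="newick")
        base = tree_log_likelihood(base_tree, m, model)
        for _ in range(20):
            t = dendropy.Tree.get(data=newick, schema="newick")
            edges = [e for e in t.preorder_edge_iter()
                     if e.length and e.head_node.parent_node]
            e = edges[rng.integers(len(edges))]
            x = rng.uniform(0.0, e.length)
            t.reroot_at_edge(e, length1=e.length - x, length2=x)
            assert tree_log_likelihood(t, m, model) == pytest.approx(base, abs=1e-8)

    def test_missing_leaf_row_errors(self, lg):
        tree = dendropy.Tree.get(data="(a:0.1,b:0.1,zz:0.1);", schema="newick")
        m = _aln([("a", "AC"), ("b", "AC")])
        with pytest.raises(ValueError, match="zz"):
            tree_log_likelihood(tree, m, lg)


class TestModelFrequencyComparison:
    def test_comparison_behaves_sanely_on_lg_data(self, lg):
        """The model-vs-empirical frequency comparison is exposed and well
        behaved: on LG-equilibrium data the two scorings stay within the
        in-sample overfitting margin of the 19 frequency parameters, while
        a grossly mis-specified frequency vector loses to both."""
        from capclade.phylo import tree_log_likelihood

        rng = np.random.default_rng(12)
        newick = "((a:0.2,b:0.3):0.1,(c:0.25,d:0.15):0.1);"
        skewed = np.full(20, 0.3 / 19)
        skewed[0] = 0.7
        for _ in range(10):
            root = "".join(rng.choice(list(AMINO_ACIDS), size=300, p=lg.pi))
            rows = [(lab, evolve_sequence(root, t, lg, rng))
                    for lab, t in [("a", 0.3), ("b", 0.4), ("c", 0.35), ("d", 0.25)]]
            m = _aln(rows)
            tree = dendropy.Tree.get(data=newick, schema="newick")
            scores = compare_frequency_models(tree, m, lg)
            gap = scores["model_frequencies"] - scores["empirical_frequencies"]
            assert -30 < gap < 5
            bad = tree_log_likelihood(tree, m, lg.with_frequencies(skewed))
            assert bad < min(scores.values())

    def test_empirical_frequencies_normalized(self, core_small):
        f = empirical_frequencies(core_small)
        assert f.sum() == pytest.approx(1.0)
        assert np.all(f > 0)


def test_gamma_shape_estimate_recovers_order_of_magnitude(lg=None):
    lg = SubstitutionModel.load("LG")
    rng = np.random.default_rng(40)
    alpha_true = 0.5
    model = lg.with_alpha(alpha_true)
    rates = model.category_rates()
    root = "".join(rng.choice(list(AMINO_ACIDS), size=400, p=lg.pi))
    # per-site rate heterogeneity shared across the tree
    site_rates = rates[rng.integers(0, 4, size=400)]
    rows = []
    for lab, t in [("a", 0.3), ("b", 0.3), ("c", 0.3), ("d", 0.3)]:
        seq = "".join(
            evolve_sequence(ch, t * r, lg, rng) for ch, r in zip(root, site_rates)
        )
        rows.append((lab, seq))
    m = _aln(rows)
    tree = dendropy.Tree.get(data="((a:0.15,b:0.15):0.01,(c:0.15,d:0.15):0.01);",
                             schema="newick")
    est = estimate_gamma_shape(tree, m, lg)
    assert 0.1 < est < 2.0
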