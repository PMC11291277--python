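import numpy as np
import pytest
from scipy.linalg import expm

from paleozooms.phylo import (
    AMINO_ACIDS,
    Node,
    PatternData,
    bipartitions,
    bootstrap_support,
    dayhoff_model,
    enumerate_topologies,
    log_likelihood,
    ml_search,
    nni_neighbors,
    optimize_branch_lengths,
    simulate_sites,
    tree_from_newick,
)


@pytest.fixture(scope="module")
def model():
    return dayhoff_model()


def _quartet(bl=None):
    bl = bl or dict(A=0.1, B=0.3, C=0.2, D=0.15, I=0.25)
    return Node(children=[
        Node("A", length=bl["A"]),
        Node("B", length=bl["B"]),
        Node(children=[Node("C", length=bl["C"]), Node("D", length=bl["D"])],
             length=bl["I"]),
    ])


def _random_alignment(taxa, n_sites, seed):
    rng = np.random.default_rng(seed)
    return {t: "".join(rng.choice(list(AMINO_ACIDS), size=n_sites)) for t in taxa}


class TestRateModel:
    def test_q_rows_sum_to_zero(self, model):
        assert np.abs(model.Q.sum(axis=1)).max() < 1e-12

    def test_transition_rows_sum_to_one(self, model):
        for t in (0.0, 0.01, 0.5, 1.0, 5.0, 10.0):
            P = model.transition_matrix(t)
            assert np.abs(P.sum(axis=1) - 1.0).max() < 1e-10
            assert (P >= 0).all()

    def test_unit_substitution_rate(self, model):
        pi = model.frequencies
        assert -np.sum(pi * np.diag(model.Q)) == pytest.approx(1.0, abs=1e-12)

    def test_matches_scipy_expm(self, model):
        P = model.transition_matrix(0.37)
        assert np.abs(P - expm(model.Q * 0.37)).max() < 1e-10

    def test_negative_branch_rejected(self, model):
        with pytest.raises(ValueError):
            model.transition_matrix(-0.1)


class TestLogLikelihood:
    def test_zero_branches_identical_sequences(self, model):
        # two identical single-residue leaves at zero distance: L = pi(aa)
        tree = Node(children=[Node("A", length=0.0), Node("B", length=0.0)])
        data = PatternData.from_alignment(["A", "B"], ["W", "W"])
        expected = np.log(model.frequencies[AMINO_ACIDS.index("W")])
        assert log_likelihood(tree, data, model) == pytest.approx(expected, abs=1e-12)

    def test_brute_force_enumeration_oracle(self, model):
        # exhaustive sum over both internal node states with scipy expm
        bl = dict(A=0.1, B=0.3, C=0.2, D=0.15, I=0.25)
        tree = _quartet(bl)
        seqs = _random_alignment("ABCD", 30, seed=0)
        data = PatternData.from_alignment(list("ABCD"), [seqs[t] for t in "ABCD"])
        ll = log_likelihood(tree, data, model)
        P = {k: expm(model.Q * v) for k, v in bl.items()}
        pi = model.frequencies
        idx = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
        total = 0.0
        for site in range(30):
            a, b, c, d = (idx[seqs[t][site]] for t in "ABCD")
            site_l = sum(
                pi[u] * P["A"][u, a] * P["B"][u, b] * P["I"][u, v]
                * P["C"][v, c] * P["D"][v, d]
                for u in range(20) for v in range(20)
            )
            total += np.log(site_l)
        assert ll == pytest.approx(total, abs=1e-8)

    def test_rerooting_invariance(self, model):
        bl = dict(A=0.1, B=0.3, C=0.2, D=0.15, I=0.25)
        at_ab = _quartet(bl)
        at_cd = Node(children=[
            Node("C", length=bl["C"]), Node("D", length=bl["D"]),
            Node(children=[Node("A", length=bl["A"]), Node("B", length=bl["B"])],
                 length=bl["I"]),
        ])
        seqs = _random_alignment("ABCD", 40, seed=3)
        data = PatternData.from_alignment(list("ABCD"), [seqs[t] for t in "ABCD"])
        assert log_likelihood(at_ab, data, model) == pytest.approx(
            log_likelihood(at_cd, data, model), abs=1e-9
        )

    def test_missing_data_treated_as_one(self, model):
        tree = _quartet()
        seqs = {"A": "W", "B": "W", "C": "-", "D": "X"}
        data = PatternData.from_alignment(list("ABCD"), [seqs[t] for t in "ABCD"])
        reduced = Node(children=[Node("A", length=0.1), Node("B", length=0.3)])
        reduced_data = PatternData.from_alignment(["A", "B"], ["W", "W"])
        # C and D contribute nothing: likelihood reduces to the A-B pair
        # joined through extra marginalized nodes, which is exact for a
        # reversible stationary model
        assert log_likelihood(tree, data, model) == pytest.approx(
            log_likelihood(reduced, reduced_data, model), abs=1e-9
        )

    def test_unknown_leaf_rejected(self, model):
        tree = _quartet()
        data = PatternData.from_alignment(["A", "B", "C"], ["W", "W", "W"])
        with pytest.raises(ValueError, match="absent"):
            log_likelihood(tree, data, model)


class TestBranchLengthOptimization:
    def test_likelihood_never_decreases(self, model):
        true = _quartet()
        seqs = simulate_sites(true, model, 500, np.random.default_rng(2))
        data = PatternData.from_alignment(list(seqs), list(seqs.values()))
        tree = _quartet(dict(A=0.5, B=0.5, C=0.5, D=0.5, I=0.5))
        before = log_likelihood(tree, data, model)
        after = optimize_branch_lengths(tree, data, model)
        assert after >= before

    def test_local_optimality(self, model):
        true = _quartet()
        seqs = simulate_sites(true, model, 800, np.random.default_rng(4))
        data = PatternData.from_alignment(list(seqs), list(seqs.values()))
        tree = _quartet()
        best = optimize_branch_lengths(tree, data, model, tol=1e-6)
        edge = tree.children[2]  # internal edge
        for delta in (-0.02, 0.02):
            perturbed = tree.copy()
            perturbed.children[2].length = max(1e-8, edge.length + delta)
            assert log_likelihood(perturbed, data, model) <= best + 1e-9


class TestTopologySearch:
    def test_topology_counts(self):
        assert len(list(enumerate_topologies(list("ABCD")))) == 3
        assert len(list(enumerate_topologies(list("ABCDE")))) == 15
        assert len(list(enumerate_topologies(list("ABCDEF")))) == 105

    def test_exhaustive_recovers_true_tree(self, model):
        true = Node(children=[
            Node("A", length=0.3), Node("B", length=0.08),
            Node(children=[Node("C", length=0.08),
                           Node(children=[Node("D", length=0.06), Node("E", length=0.06)],
                                length=0.12)], length=0.12),
        ])
        seqs = simulate_sites(true, model, 2000, np.random.default_rng(8))
        data = PatternData.from_alignment(list(seqs), list(seqs.values()))
        result = ml_search(data, model, strategy="exhaustive_le8", bl_tol=1e-2)
        assert bipartitions(result.tree) == bipartitions(true)

    def test_identical_taxa_become_siblings(self, model):
        true = Node(children=[
            Node("A", length=0.3), Node("B", length=0.2),
            Node(children=[Node("C", length=0.15),
                           Node(children=[Node("D", length=0.1), Node("E", length=0.1)],
                                length=0.1)], length=0.1),
        ])
        seqs = simulate_sites(true, model, 800, np.random.default_rng(9))
        seqs["E"] = seqs["D"]  # E is a copy of D
        data = PatternData.from_alignment(list(seqs), list(seqs.values()))
        result = ml_search(data, model, strategy="exhaustive_le8", bl_tol=1e-2)
        assert frozenset({"D", "E"}) in {
            frozenset(s) for s in bipartitions(result.tree)
        } or any(
            set(n.leaf_names()) == {"D", "E"} for n in result.tree.postorder()
        )

    def test_nni_bounded_by_exhaustive(self, model):
        true = _quartet()
        seqs = simulate_sites(true, model, 300, np.random.default_rng(10))
        data = PatternData.from_alignment(list(seqs), list(seqs.values()))
        exhaustive = ml_search(data, model, strategy="exhaustive_le8", bl_tol=1e-2)
        nni = ml_search(data, model, strategy="nni", bl_tol=1e-2)
        # bound holds up to the branch-length optimizer's convergence noise
        assert nni.log_likelihood <= exhaustive.log_likelihood + 0.01

    def test_too_few_taxa(self, model):
        data = PatternData.from_alignment(["A", "B", "C"], ["WW", "WW", "WW"])
        with pytest.raises(ValueError, match="4 taxa"):
            ml_search(data, model)

    def test_nni_neighbors_nonempty(self):
        tree = _quartet()
        assert len(nni_neighbors(tree)) == 2


class TestBootstrap:
    def _data(self, model, n_sites=300, seed=12):
        true = _quartet()
        seqs = simulate_sites(true, model, n_sites, np.random.default_rng(seed))
        return PatternData.from_alignment(list(seqs), list(seqs.values()))

    def test_supports_in_range_and_deterministic(self, model):
        data = self._data(model)
        a = bootstrap_support(data, model, n_boot=10, seed=5)
        b = bootstrap_support(data, model, n_boot=10, seed=5)
        sup_a = [n.support for n in a.tree.postorder() if n.support is not None]
        sup_b = [n.support for n in b.tree.postorder() if n.support is not None]
        assert sup_a == sup_b
        assert all(0.0 <= s <= 1.0 for s in sup_a)

    def test_minimum_replicates(self, model):
        with pytest.raises(ValueError):
            bootstrap_support(self._data(model), model, n_boot=5, seed=1)


class TestNewick:
    def test_round_trip_preserves_splits(self):
        tree = Node(children=[
            Node("A", length=0.3), Node("B", length=0.2),
            Node(children=[Node("C", length=0.15), Node("D", length=0.1)],
                 length=0.07),
        ])
        again = tree_from_newick(tree.newick())
        assert bipartitions(again) == bipartitions(tree)
        leaf = {n.name: n.length for n in again.postorder() if n.is_leaf}
        assert leaf["C"] == pytest.approx(0.15, abs=1e-6)


class TestSimulateSites:
    def test_deterministic(self, model):
        tree = _quartet()
        a = simulate_sites(tree, model, 50, np.random.default_rng(1))
        b = simulate_sites(tree, model, 50, np.random.default_rng(1))
        assert a == b

    def test_equilibrium_composition(self, model):
        tree = Node(children=[Node("A", length=0.01), Node("B", length=0.01)])
        seqs = simulate_sites(tree, model, 20000, np.random.default_rng(2))
        freqs = np.array([
            seqs["A"].count(aa) / 20000 for aa in AMINO_ACIDS
        ])
        assert np.abs(freqs - model.frequencies).max() < 0.02
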