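"""Maximum-likelihood placement of protein sequences under the Dayhoff model.

Implements Felsenstein pruning over site patterns with per-pattern scaling,
per-branch univariate branch-length optimization, exhaustive topology
enumeration for small taxon sets with NNI hill-climbing beyond that, and
nonparametric bootstrap support.

Gaps and X are treated as missing data (partial likelihood 1 in all states).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .data.dayhoff import (
    AMINO_ACIDS,
    DAYHOFF_EXCHANGEABILITIES,
    DAYHOFF_FREQUENCIES,
)

N_STATES = 20
_STATE_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
MISSING = N_STATES  # gap / X / unknown

_MIN_BRANCH = 1e-8
_MAX_BRANCH = 10.0


# ---------------------------------------------------------------------------
# Substitution model
# ---------------------------------------------------------------------------


class RateModel:
    """A reversible amino-acid rate model from exchangeabilities + frequencies.

    The generator is rescaled to one expected substitution per unit time;
    transition matrices come from the symmetrized eigendecomposition.
    """

    def __init__(
        self,
        exchangeabilities: np.ndarray,
        frequencies: np.ndarray,
        name: str = "custom",
    ):
        S = np.asarray(exchangeabilities, dtype=float)
        pi = np.asarray(frequencies, dtype=float)
        if S.shape != (N_STATES, N_STATES) or not np.allclose(S, S.T):
            raise ValueError("exchangeabilities must be a symmetric 20x20 matrix")
        if pi.shape != (N_STATES,) or np.any(pi < 0):
            raise ValueError("frequencies must be 20 non-negative reals")
        pi = pi / pi.sum()
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -np.sum(pi * np.diag(Q))
        Q /= mu
        self.name = name
        self.frequencies = pi
        self.Q = Q
        sqrt_pi = np.sqrt(pi)
        B = Q * sqrt_pi[:, None] / sqrt_pi[None, :]
        eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
        self._eigval = eigval
        self._U = eigvec / sqrt_pi[:, None]
        self._W = eigvec.T * sqrt_pi[None, :]

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        P = (self._U * np.exp(self._eigval * t)[None, :]) @ self._W
        return np.clip(P, 0.0, None)


def dayhoff_model() -> RateModel:
    return RateModel(
        np.array(DAYHOFF_EXCHANGEABILITIES),
        np.array(DAYHOFF_FREQUENCIES),
        name="Dayhoff",
    )


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


class Node:
    __slots__ = ("name", "children", "length", "support")

    def __init__(
        self,
        name: str | None = None,
        children: list["Node"] | None = None,
        length: float = 0.1,
    ):
        self.name = name
        self.children = children or []
        self.length = length
        self.support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        return [leaf for child in self.children for leaf in child.leaves()]

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]

    def copy(self) -> "Node":
        node = Node(self.name, [c.copy() for c in self.children], self.length)
        node.support = self.support
        return node

    def postorder(self) -> list["Node"]:
        out = []
        for child in self.children:
            out.extend(child.postorder())
        out.append(self)
        return out

    def newick(self, with_support: bool = False) -> str:
        return self._newick_part(with_support) + ";"

    def _newick_part(self, with_support: bool) -> str:
        if self.is_leaf:
            return f"{self.name}:{self.length:.6f}"
        inner = ",".join(c._newick_part(with_support) for c in self.children)
        label = ""
        if with_support and self.support is not None:
            label = f"{self.support:.3f}"
        return f"({inner}){label}:{self.length:.6f}"


def tree_from_newick(newick: str) -> Node:
    """Parse a Newick string (via dendropy) into the internal node type."""
    import dendropy

    dt = dendropy.Tree.get(data=newick, schema="newick")

    def convert(dnode) -> Node:
        children = [convert(c) for c in dnode.child_nodes()]
        name = dnode.taxon.label if dnode.taxon else None
        length = dnode.edge.length if dnode.edge.length is not None else 0.0
        return Node(name, children, float(length))

    root = convert(dt.seed_node)
    root.length = 0.0
    return root


def bipartitions(root: Node) -> set[frozenset[str]]:
    """Non-trivial splits of an unrooted tree, canonicalized as the side not
    containing the lexicographically smallest leaf."""
    all_leaves = sorted(root.leaf_names())
    anchor = all_leaves[0]
    universe = set(all_leaves)
    splits = set()
    for node in root.postorder():
        if node is root or node.is_leaf:
            continue
        side = set(node.leaf_names())
        if anchor in side:
            side = universe - side
        if 1 < len(side) < len(universe) - 1:
            splits.add(frozenset(side))
    return splits


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


@dataclass
class PatternData:
    """Alignment columns compressed to unique patterns with weights."""

    taxa: list[str]
    patterns: np.ndarray  # (n_taxa, n_patterns) int8, MISSING for gap/X
    weights: np.ndarray  # (n_patterns,)

    @classmethod
    def from_alignment(cls, taxa: Sequence[str], rows: Sequence[str]) -> "PatternData":
        n_taxa = len(taxa)
        n_sites = len(rows[0])
        mat = np.full((n_taxa, n_sites), MISSING, dtype=np.int8)
        for i, row in enumerate(rows):
            if len(row) != n_sites:
                raise ValueError("alignment rows differ in length")
            for j, aa in enumerate(row):
                mat[i, j] = _STATE_INDEX.get(aa, MISSING)
        patterns, weights = np.unique(mat, axis=1, return_counts=True)
        return cls(list(taxa), patterns, weights.astype(float))

    @property
    def n_sites(self) -> int:
        return int(self.weights.sum())

    def resample_columns(self, rng: np.random.Generator) -> "PatternData":
        """Bootstrap: resample sites with replacement (as pattern weights)."""
        probs = self.weights / self.weights.sum()
        counts = rng.multinomial(self.n_sites, probs)
        keep = counts > 0
        return PatternData(
            self.taxa, self.patterns[:, keep], counts[keep].astype(float)
        )


def _leaf_partial(states: np.ndarray) -> np.ndarray:
    """(n_patterns, 20) indicator partials; missing rows are all-ones."""
    n = states.shape[0]
    partial = np.zeros((n, N_STATES))
    missing = states == MISSING
    partial[missing, :] = 1.0
    observed = ~missing
    partial[np.nonzero(observed)[0], states[observed].astype(int)] = 1.0
    return partial


class _Pruner:
    """Pruning engine over one tree + pattern data with per-node scaling."""

    def __init__(self, root: Node, data: PatternData, model: RateModel):
        self.root = root
        self.data = data
        self.model = model
        self.leaf_index = {name: i for i, name in enumerate(data.taxa)}
        self._memo: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        missing = [n.name for n in root.leaves() if n.name not in self.leaf_index]
        if missing:
            raise ValueError(f"tree leaves absent from alignment: {missing}")

    def _down(self, node: Node) -> tuple[np.ndarray, np.ndarray]:
        """(partial (P,20), log-scale (P,)) conditional on node's state."""
        cached = self._memo.get(id(node))
        if cached is not None:
            return cached
        result = self._down_uncached(node)
        self._memo[id(node)] = result
        return result

    def _down_uncached(self, node: Node) -> tuple[np.ndarray, np.ndarray]:
        if node.is_leaf:
            states = self.data.patterns[self.leaf_index[node.name]]
            return _leaf_partial(states), np.zeros(len(self.data.weights))
        partial = np.ones((len(self.data.weights), N_STATES))
        log_scale = np.zeros(len(self.data.weights))
        for child in node.children:
            cp, cs = self._down(child)
            P = self.model.transition_matrix(child.length)
            partial = partial * (cp @ P.T)
            log_scale += cs
        mx = partial.max(axis=1)
        mx = np.where(mx > 0, mx, 1.0)
        partial /= mx[:, None]
        log_scale += np.log(mx)
        if not np.all(np.isfinite(log_scale)):
            bad = int(np.nonzero(~np.isfinite(log_scale))[0][0])
            raise FloatingPointError(
                f"non-finite partial likelihood at pattern index {bad}"
            )
        return partial, log_scale

    def log_likelihood(self) -> float:
        partial, log_scale = self._down(self.root)
        site_l = partial @ self.model.frequencies
        return float(np.sum(self.data.weights * (np.log(site_l) + log_scale)))


def log_likelihood(root: Node, data: PatternData, model: RateModel) -> float:
    """Felsenstein pruning log-likelihood of an (un)rooted tree."""
    return _Pruner(root, data, model).log_likelihood()


def _edge_partials(
    root: Node, target: Node, data: PatternData, model: RateModel
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """For the edge above ``target``: (outside, below, log_scale).

    outside[p, a]: likelihood of everything except target's subtree, given
    state ``a`` at target's parent, including root frequencies.
    below[p, b]: partial of target's subtree given state ``b`` at target.
    """
    pruner = _Pruner(root, data, model)
    # path of internal nodes from root down to target's parent
    path = []

    def locate(node: Node) -> bool:
        if node is target:
            return True
        for child in node.children:
            if locate(child):
                path.append(node)
                return True
        return False

    if not locate(root):
        raise ValueError("target edge not found in tree")
    path.reverse()

    outside = np.ones((len(data.weights), N_STATES)) * model.frequencies[None, :]
    out_scale = np.zeros(len(data.weights))
    for depth, node in enumerate(path):
        on_path = path[depth + 1] if depth + 1 < len(path) else target
        for child in node.children:
            if child is on_path:
                continue
            cp, cs = pruner._down(child)
            outside = outside * (cp @ model.transition_matrix(child.length).T)
            out_scale = out_scale + cs
        if on_path is not target:
            outside = outside @ model.transition_matrix(on_path.length)
        mx = outside.max(axis=1)
        mx = np.where(mx > 0, mx, 1.0)
        outside = outside / mx[:, None]
        out_scale = out_scale + np.log(mx)
    below, below_scale = pruner._down(target)
    return outside, below, out_scale + below_scale


def optimize_branch_lengths(
    root: Node,
    data: PatternData,
    model: RateModel,
    tol: float = 1e-4,
    max_sweeps: int = 8,
) -> float:
    """Coordinate-ascent branch-length optimization; returns final logL."""
    edges = [n for n in root.postorder() if n is not root]
    last = log_likelihood(root, data, model)
    for _ in range(max_sweeps):
        for edge in edges:
            outside, below, log_scale = _edge_partials(root, edge, data, model)
            weights = data.weights

            def neg_ll(t: float) -> float:
                P = model.transition_matrix(t)
                site = ((outside @ P) * below).sum(axis=1)
                site = np.maximum(site, 1e-300)
                return -float(np.sum(weights * (np.log(site) + log_scale)))

            res = minimize_scalar(
                neg_ll,
                bounds=(_MIN_BRANCH, _MAX_BRANCH),
                method="bounded",
                options={"xatol": 1e-6},
            )
            if -res.fun > -neg_ll(edge.length):
                edge.length = float(res.x)
        current = log_likelihood(root, data, model)
        if current - last < tol:
            last = current
            break
        last = current
    return last


# ---------------------------------------------------------------------------
# Topology search
# ---------------------------------------------------------------------------


def _star3(names: Sequence[str]) -> Node:
    return Node(children=[Node(n) for n in names[:3]])


def enumerate_topologies(taxa: Sequence[str]) -> Iterable[Node]:
    """All unrooted binary topologies by stepwise addition (use for <=8 taxa)."""
    taxa = list(taxa)
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")
    trees = [_star3(taxa)]
    for name in taxa[3:]:
        nxt = []
        for tree in trees:
            edges = [n for n in tree.postorder() if n is not tree]
            for idx in range(len(edges)):
                clone = tree.copy()
                cedges = [n for n in clone.postorder() if n is not clone]
                target = cedges[idx]
                parent = _find_parent(clone, target)
                new_internal = Node(children=[target, Node(name)], length=0.1)
                parent.children[parent.children.index(target)] = new_internal
                nxt.append(clone)
        trees = nxt
    return trees


def _find_parent(root: Node, target: Node) -> Node:
    for node in root.postorder():
        if target in node.children:
            return node
    raise ValueError("node not in tree")


def nni_neighbors(root: Node) -> list[Node]:
    """The trees one nearest-neighbour interchange away."""
    out = []
    nodes = root.postorder()
    internal = [n for n in nodes if not n.is_leaf and n is not root]
    for node in internal:
        parent = _find_parent(root, node)
        siblings = [c for c in parent.children if c is not node]
        if not siblings:
            continue
        sibling = siblings[0]
        for child_idx in range(len(node.children)):
            clone = root.copy()
            cnodes = clone.postorder()
            cnode = cnodes[nodes.index(node)]
            cparent = _find_parent(clone, cnode)
            csibling = cparent.children[parent.children.index(sibling)]
            cchild = cnode.children[child_idx]
            # swap cchild <-> csibling
            cnode.children[child_idx] = csibling
            cparent.children[cparent.children.index(csibling)] = cchild
            out.append(clone)
    return out


@dataclass
class SearchResult:
    tree: Node
    log_likelihood: float


def ml_search(
    data: PatternData,
    model: RateModel,
    strategy: str = "auto",
    start_tree: Node | None = None,
    bl_tol: float = 1e-3,
) -> SearchResult:
    """Best-scoring ML tree.

    ``exhaustive_le8`` enumerates all topologies (<=8 taxa); ``nni``
    hill-climbs from ``start_tree`` (or a default stepwise topology);
    ``auto`` picks exhaustive when feasible.
    """
    taxa = data.taxa
    if len(taxa) < 4:
        raise ValueError("need at least 4 taxa for an unrooted search")
    if strategy == "auto":
        strategy = "exhaustive_le8" if len(taxa) <= 8 else "nni"
    if strategy == "exhaustive_le8":
        if len(taxa) > 8:
            raise ValueError("exhaustive search limited to 8 taxa")
        best: SearchResult | None = None
        for tree in enumerate_topologies(taxa):
            ll = optimize_branch_lengths(tree, data, model, tol=bl_tol)
            if best is None or ll > best.log_likelihood:
                best = SearchResult(tree, ll)
        assert best is not None
        return best
    if strategy == "nni":
        tree = start_tree.copy() if start_tree is not None else _default_tree(taxa)
        ll = optimize_branch_lengths(tree, data, model, tol=bl_tol)
        improved = True
        while improved:
            improved = False
            for neighbor in nni_neighbors(tree):
                nll = optimize_branch_lengths(neighbor, data, model, tol=bl_tol)
                if nll > ll + 1e-6:
                    tree, ll = neighbor, nll
                    improved = True
                    break
        return SearchResult(tree, ll)
    raise ValueError(f"unknown strategy {strategy!r}")


def _default_tree(taxa: Sequence[str]) -> Node:
    tree = _star3(taxa)
    for name in taxa[3:]:
        first_edge = next(n for n in tree.postorder() if n is not tree)
        parent = _find_parent(tree, first_edge)
        new_internal = Node(children=[first_edge, Node(name)], length=0.1)
        parent.children[parent.children.index(first_edge)] = new_internal
    return tree


def bootstrap_support(
    data: PatternData,
    model: RateModel,
    n_boot: int = 100,
    seed: int = 42,
    ml_tree: Node | None = None,
) -> SearchResult:
    """Nonparametric bootstrap: support = fraction of replicate ML trees
    containing each internal split, annotated onto the full-data ML tree."""
    if n_boot < 10:
        raise ValueError("n_boot must be >= 10")
    rng = np.random.default_rng(seed)
    if ml_tree is None:
        best = ml_search(data, model)
        tree, ll = best.tree, best.log_likelihood
    else:
        tree = ml_tree.copy()
        ll = optimize_branch_lengths(tree, data, model)
    split_counts: dict[frozenset, int] = {}
    for _ in range(n_boot):
        replicate = data.resample_columns(rng)
        result = ml_search(
            replicate, model, strategy="nni", start_tree=tree, bl_tol=1e-2
        )
        for split in bipartitions(result.tree):
            split_counts[split] = split_counts.get(split, 0) + 1
    for node in tree.postorder():
        if node is tree or node.is_leaf:
            continue
        side = set(node.leaf_names())
        universe = set(tree.leaf_names())
        anchor = sorted(universe)[0]
        if anchor in side:
            side = universe - side
        if 1 < len(side) < len(universe) - 1:
            node.support = split_counts.get(frozenset(side), 0) / n_boot
    return SearchResult(tree, ll)


# ---------------------------------------------------------------------------
# Simulation under the model (used by the synthetic-data generators)
# ---------------------------------------------------------------------------


def simulate_sites(
    root: Node, model: RateModel, n_sites: int, rng: np.random.Generator
) -> dict[str, str]:
    """Evolve ``n_sites`` residues along ``root``; returns leaf sequences."""
    sequences: dict[str, np.ndarray] = {}

    def recurse(node: Node, states: np.ndarray) -> None:
        for child in node.children:
            P = model.transition_matrix(child.length)
            cum = np.cumsum(P, axis=1)
            u = rng.random(n_sites)
            child_states = (u[:, None] > cum[states]).sum(axis=1)
            if child.is_leaf:
                sequences[child.name] = child_states
            else:
                recurse(child, child_states)

    root_states = rng.choice(N_STATES, size=n_sites, p=model.frequencies)
    recurse(root, root_states)
    return {
        name: "".join(AMINO_ACIDS[s] for s in states)
        for name, states in sequences.items()
    }
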