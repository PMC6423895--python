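"""HKY85 substitution model and Felsenstein pruning on small species trees.

The rate matrix follows HKY85: transitions (A<->G, C<->T) are scaled by kappa
relative to transversions, target frequencies are pi. The matrix is normalised
so that one unit of branch length equals one expected substitution per site at
equilibrium. Transition matrices are obtained from the symmetrised
eigendecomposition (exact for reversible models), so likelihood evaluation
over a grid of branch lengths costs one 4x4 eigendecomposition per (kappa, pi).

Trees are stored as flat arrays (parent pointers + postorder) for speed; Newick
parsing and serialisation go through dendropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
MISSING = 4  # code for gap / N / any ambiguity: treated as missing data

_TRANSITION = np.zeros((4, 4), dtype=bool)
for _i, _j in ((0, 2), (2, 0), (1, 3), (3, 1)):
    _TRANSITION[_i, _j] = True


def hky_rate_matrix(kappa: float, pi: np.ndarray) -> np.ndarray:
    """HKY85 rate matrix scaled to one expected substitution/site per unit time."""
    pi = np.asarray(pi, dtype=float)
    if not np.isfinite(kappa) or kappa <= 0:
        raise ValueError(f"kappa must be a positive finite real, got {kappa}")
    if pi.shape != (4,) or np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-12:
        raise ValueError("pi must be 4 non-negative frequencies summing to 1")
    q = np.where(_TRANSITION, kappa, 1.0) * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    rate = -np.dot(pi, np.diag(q))
    if rate <= 0:
        raise ValueError("degenerate base frequencies: zero total rate")
    return q / rate


class HKYModel:
    """HKY85 model with cached spectral decomposition.

    ``transition_matrix(t)`` returns P(t) = exp(Qt); rows sum to 1 and
    P(0) = I. Detailed balance pi_i Q_ij = pi_j Q_ji holds by construction.
    """

    def __init__(self, kappa: float, pi: np.ndarray):
        self.kappa = float(kappa)
        self.pi = np.asarray(pi, dtype=float)
        self.q = hky_rate_matrix(kappa, self.pi)
        d = np.sqrt(self.pi)
        sym = self.q * d[:, None] / d[None, :]
        w, v = np.linalg.eigh((sym + sym.T) / 2.0)
        self._w = w
        self._left = v / d[:, None]      # D^-1 V
        self._right = v.T * d[None, :]   # V^T D

    def transition_matrix(self, t: float) -> np.ndarray:
        if t < 0 or not np.isfinite(t):
            raise ValueError(f"branch length must be finite and >= 0, got {t}")
        return (self._left * np.exp(self._w * t)) @ self._right


@dataclass
class Tree:
    """Rooted species tree in flat-array form.

    ``parent[i]`` is the parent node index (-1 for the root), ``blen[i]`` the
    length of the branch above node i, ``postorder`` visits children before
    parents. Leaves carry species names. A trifurcating root expresses an
    unrooted topology (all branch lengths then identifiable under a
    reversible model).
    """

    parent: np.ndarray
    blen: np.ndarray
    children: list[list[int]]
    postorder: np.ndarray
    leaf_names: dict[str, int]
    newick_template: str = ""
    _leaf_set: frozenset = field(init=False)

    def __post_init__(self):
        self._leaf_set = frozenset(self.leaf_names)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(self.postorder[-1])

    @property
    def species(self) -> frozenset:
        return self._leaf_set

    def terminal_branch(self, species: str) -> int:
        """Node index identifying the terminal branch of a leaf species."""
        return self.leaf_names[species]

    def free_branches(self) -> list[int]:
        """Indices of nodes carrying an estimable branch (all but the root)."""
        return [i for i in range(self.n_nodes) if self.parent[i] >= 0]

    def path_length(self, a: str, b: str) -> float:
        """Sum of branch lengths on the path between two leaves."""
        anc_a = {}
        i = self.leaf_names[a]
        d = 0.0
        while i >= 0:
            anc_a[i] = d
            d += self.blen[i] if self.parent[i] >= 0 else 0.0
            i = self.parent[i]
        i = self.leaf_names[b]
        d = 0.0
        while i not in anc_a:
            d += self.blen[i]
            i = self.parent[i]
        return d + anc_a[i]

    def copy(self) -> "Tree":
        return Tree(
            self.parent.copy(), self.blen.copy(),
            [list(c) for c in self.children], self.postorder.copy(),
            dict(self.leaf_names), self.newick_template,
        )

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dtree = dendropy.Tree.get(data=newick, schema="newick")
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=int)
        blen = np.zeros(n)
        children: list[list[int]] = [[] for _ in range(n)]
        leaf_names: dict[str, int] = {}
        for nd in nodes:
            i = index[id(nd)]
            if nd.parent_node is not None:
                p = index[id(nd.parent_node)]
                parent[i] = p
                children[p].append(i)
                blen[i] = float(nd.edge.length or 0.0)
            if nd.is_leaf():
                name = nd.taxon.label.replace(" ", "_")
                leaf_names[name] = i
        post = [index[id(nd)] for nd in dtree.postorder_node_iter()]
        return cls(parent, blen, children, np.array(post), leaf_names, newick)

    def to_newick(self) -> str:
        def render(i: int) -> str:
            if not self.children[i]:
                name = next(k for k, v in self.leaf_names.items() if v == i)
                return f"{name}:{self.blen[i]:.10g}"
            inner = ",".join(render(c) for c in self.children[i])
            if self.parent[i] < 0:
                return f"({inner});"
            return f"({inner}):{self.blen[i]:.10g}"

        return render(self.root)

    def pruned_to(self, keep: set[str]) -> "Tree":
        """Restriction of the tree to a subset of leaves.

        Degree-two internal nodes created by the restriction are suppressed,
        summing branch lengths, so the likelihood of the retained species is
        unchanged.
        """
        missing = keep - self._leaf_set
        if missing:
            raise KeyError(f"species absent from tree: {sorted(missing)}")
        keep_idx = {self.leaf_names[s] for s in keep}
        alive = np.zeros(self.n_nodes, dtype=bool)
        for i in self.postorder:
            if not self.children[i]:
                alive[i] = i in keep_idx
            else:
                alive[i] = any(alive[c] for c in self.children[i])
        # rebuild top-down, suppressing single-child chains
        new_parent: list[int] = []
        new_blen: list[float] = []
        new_children: list[list[int]] = []
        new_leaf: dict[str, int] = {}
        name_of = {v: k for k, v in self.leaf_names.items()}

        def build(i: int, extra: float, parent_new: int) -> None:
            kids = [c for c in self.children[i] if alive[c]]
            if len(kids) == 1 and parent_new >= 0:
                build(kids[0], extra + self.blen[kids[0]], parent_new)
                return
            j = len(new_parent)
            new_parent.append(parent_new)
            new_blen.append(extra)
            new_children.append([])
            if parent_new >= 0:
                new_children[parent_new].append(j)
            if not kids:
                new_leaf[name_of[i]] = j
            for c in kids:
                build(c, self.blen[c], j)

        root = self.root
        # collapse a root left with one live child
        while True:
            kids = [c for c in self.children[root] if alive[c]]
            if len(kids) == 1:
                root = kids[0]
            else:
                break
        build(root, 0.0, -1)
        n = len(new_parent)
        order: list[int] = []

        def post(i: int) -> None:
            for c in new_children[i]:
                post(c)
            order.append(i)

        post(0)
        return Tree(
            np.array(new_parent), np.array(new_blen), new_children,
            np.array(order), new_leaf,
        )


def encode_sequences(seqs: dict[str, str]) -> dict[str, np.ndarray]:
    """Map sequences over {A,C,G,T,-,N,...} to integer codes (4 = missing)."""
    table = np.full(256, MISSING, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return {
        name: table[np.frombuffer(s.encode(), dtype=np.uint8)]
        for name, s in seqs.items()
    }


def site_patterns(
    codes: dict[str, np.ndarray], species_order: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Compress alignment columns to unique site patterns with counts.

    Returns (patterns, counts) where patterns has shape (n_patterns, n_species)
    with entries in {0..3, 4=missing}.
    """
    mat = np.stack([codes[s] for s in species_order], axis=1)
    patterns, counts = np.unique(mat, axis=0, return_counts=True)
    return patterns, counts


_EYE5 = np.vstack([np.eye(4), np.ones(4)])  # row 4 = missing data


class PruningEngine:
    """Felsenstein pruning over compressed site patterns, with inside/outside
    conditional likelihoods for cheap single-branch optimisation.

    Leaf partial-likelihood vectors are precomputed once; gap/N states are
    missing data (vector of ones), so all-missing columns contribute exactly
    0 to the log-likelihood.
    """

    def __init__(
        self,
        patterns: np.ndarray,
        counts: np.ndarray,
        species_order: list[str],
        tree: Tree,
    ):
        extra = set(species_order) - tree.species
        if extra:
            raise KeyError(f"alignment species not in tree: {sorted(extra)}")
        self.tree = tree
        self.counts = np.asarray(counts, dtype=float)
        self.n_pat = patterns.shape[0]
        leaf_col = {tree.leaf_names[s]: k for k, s in enumerate(species_order)}
        self.leaf_partial: dict[int, np.ndarray] = {}
        for i in range(tree.n_nodes):
            if not tree.children[i]:
                col = leaf_col.get(i)
                self.leaf_partial[i] = (
                    np.ones((self.n_pat, 4)) if col is None
                    else _EYE5[patterns[:, col]]
                )

    def _branch_lengths(
        self,
        branch_scales: dict[int, float] | None,
        tree_scale: float,
        branch_override: dict[int, float] | None = None,
    ) -> np.ndarray:
        t = self.tree.blen * tree_scale
        if branch_scales:
            for node, f in branch_scales.items():
                t[node] = t[node] * f
        if branch_override:
            for node, v in branch_override.items():
                t[node] = v
        return t

    def _inside(self, model: HKYModel, t: np.ndarray):
        """Postorder pass: D[i][pat, j] = P(data below i | state at i = j),
        plus the per-child propagated contributions M_c D_c."""
        tree = self.tree
        D: dict[int, np.ndarray] = {}
        up: dict[int, np.ndarray] = {}  # (D_c @ M_c.T) per child c
        for i in tree.postorder:
            i = int(i)
            if not tree.children[i]:
                D[i] = self.leaf_partial[i]
            else:
                acc = None
                for c in tree.children[i]:
                    m = model.transition_matrix(t[c])
                    term = D[c] @ m.T
                    up[c] = term
                    acc = term if acc is None else acc * term
                D[i] = acc
        return D, up

    def loglik(
        self,
        model: HKYModel,
        branch_scales: dict[int, float] | None = None,
        tree_scale: float = 1.0,
        branch_override: dict[int, float] | None = None,
    ) -> float:
        """``branch_override`` pins named branches to absolute lengths,
        bypassing any scaling."""
        t = self._branch_lengths(branch_scales, tree_scale, branch_override)
        D, _ = self._inside(model, t)
        site_l = D[self.tree.root] @ model.pi
        return float(np.dot(self.counts, np.log(site_l)))

    def branch_objective(
        self,
        model: HKYModel,
        node: int,
        branch_scales: dict[int, float] | None = None,
        tree_scale: float = 1.0,
    ):
        """Closure f(t) -> log-likelihood with branch ``node`` set to length
        ``t`` and everything else fixed.

        Built from one inside and one outside pass; each subsequent
        evaluation costs only a (patterns x 4) x (4 x 4) product, making
        scalar branch optimisation cheap.
        """
        tree = self.tree
        if tree.parent[node] < 0:
            raise ValueError("the root carries no branch")
        t = self._branch_lengths(branch_scales, tree_scale)
        D, up = self._inside(model, t)
        # outside pass down the path root -> node only
        path = []
        i = node
        while i >= 0:
            path.append(i)
            i = tree.parent[i]
        path.reverse()  # root ... node
        U = np.broadcast_to(model.pi, (self.n_pat, 4))
        for parent, child in zip(path, path[1:]):
            siblings = [up[s] for s in tree.children[parent] if s != child]
            V = U * np.prod(siblings, axis=0) if siblings else np.asarray(U)
            if child == node:
                D_c = D[child]
                counts = self.counts

                def f(tb: float, V=V, D_c=D_c, counts=counts) -> float:
                    m = model.transition_matrix(tb)
                    site_l = ((V @ m) * D_c).sum(axis=1)
                    return float(np.dot(counts, np.log(site_l)))

                return f
            U = V @ model.transition_matrix(t[child])
        raise AssertionError("unreachable")


def pruning_loglik(
    patterns: np.ndarray,
    counts: np.ndarray,
    species_order: list[str],
    tree: Tree,
    model: HKYModel,
    branch_scales: dict[int, float] | None = None,
    tree_scale: float = 1.0,
) -> float:
    """Log-likelihood of site patterns by postorder pruning.

    ``branch_scales`` maps node indices (identifying the branch above each
    node) to multiplicative rate factors; ``tree_scale`` multiplies every
    branch.
    """
    engine = PruningEngine(patterns, counts, species_order, tree)
    return engine.loglik(model, branch_scales, tree_scale)
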