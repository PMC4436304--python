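"""Tree building and subfamily classification.

Three independent reconstructions — neighbor joining on p-distances (with
column-bootstrap supports), Fitch maximum parsimony, and maximum likelihood
under the Poisson (equal-rates, equal-frequencies) amino-acid model — feed a
consensus rule: a clade becomes a named subfamily only when its bipartition
has NJ bootstrap support above a threshold (default 88%) *and* appears in at
least one of the other two methods' trees. Subfamily names are carried by
anchor sequences (one or more reference domains per subfamily); genes
falling in no supported clade are orphans.

The Poisson model keeps the likelihood analytically checkable: for two
sequences the MLE branch length satisfies p = (19/20)(1 - exp(-20 t / 19)),
where p is the observed p-distance.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .seqio import Alignment
from .trees import Node, Tree

__all__ = [
    "DistanceMatrix",
    "SupportedTree",
    "SubfamilyAssignment",
    "p_distance",
    "nj_tree",
    "bootstrap_support",
    "fitch_score",
    "mp_tree",
    "ml_tree_poisson",
    "call_subfamilies",
]

_MISSING = {"-", "X"}


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("labels/matrix shape mismatch")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("distance matrix diagonal not zero")
        if not np.all(np.isfinite(m)):
            raise ValueError("non-finite distances")
        self.matrix = m


@dataclass
class SupportedTree:
    """An NJ tree with per-bipartition bootstrap support (percent)."""

    tree: Tree
    supports: dict[frozenset, float] = field(default_factory=dict)


@dataclass
class SubfamilyAssignment:
    assignments: dict[str, str]  # leaf -> subfamily name or "orphan"/"unresolved"
    clades: dict[str, frozenset]  # subfamily name -> leaf set of its clade
    unresolved: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# distances and neighbor joining
# ---------------------------------------------------------------------------


def p_distance(aln: Alignment) -> DistanceMatrix:
    """Pairwise proportion of mismatches over mutually non-gap columns."""
    if len(aln.rows) < 2:
        raise ValueError("need at least 2 rows")
    labels = aln.ids
    arr = np.array([list(g) for _, g in aln.rows])
    valid = ~np.isin(arr, ["-", "."])
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            total = int(both.sum())
            if total == 0:
                raise ValueError(
                    f"no comparable columns between {labels[i]!r} and {labels[j]!r}"
                )
            mism = int((arr[i][both] != arr[j][both]).sum())
            d[i, j] = d[j, i] = mism / total
    return DistanceMatrix(labels=labels, matrix=d)


def nj_tree(D: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are resolved toward the pair whose (smallest
    leaf label of each cluster) sorted pair is lexicographically least.
    Negative limb lengths are clamped to zero.
    """
    n = len(D.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = D.matrix.astype(float).copy()
    nodes = [Node(name=l) for l in D.labels]
    minleaf = list(D.labels)
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = np.argwhere(q <= qmin + 1e-12)
        best = min(
            (tuple(sorted((minleaf[active[i]], minleaf[active[j]]))), i, j)
            for i, j in ties
            if i < j
        )
        _, ti, tj = best
        i, j = active[ti], active[tj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ti] - r[tj]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = Node()
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = li
        child_j.length = lj
        parent.add(child_i)
        parent.add(child_j)
        # distances to the new node
        new = np.zeros(d.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            new[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new[:-1]
        d[:-1, -1] = new[:-1]
        nodes.append(parent)
        minleaf.append(min(minleaf[i], minleaf[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]
    # final three clusters join at a trifurcating root
    i, j, k = active
    root = Node()
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for idx, length in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = max(length, 0.0)
        root.add(nodes[idx])
    return Tree(root)


def bootstrap_support(
    aln: Alignment,
    reps: int = 1000,
    seed: int = 0,
    builder=None,
) -> SupportedTree:
    """Column-bootstrap supports attached to the point-estimate NJ tree."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if builder is None:
        builder = lambda a: nj_tree(p_distance(a))
    point = builder(aln)
    target = point.bipartitions()
    counts = {b: 0 for b in target}
    rng = np.random.default_rng(seed)
    ncol = aln.length
    ids = aln.ids
    rows = [list(g) for _, g in aln.rows]
    arr = np.array(rows)
    for _ in range(reps):
        cols = rng.integers(0, ncol, size=ncol)
        rep_rows = ["".join(row) for row in arr[:, cols]]
        rep_aln = Alignment(rows=list(zip(ids, rep_rows)))
        rep_bip = builder(rep_aln).bipartitions()
        for b in counts:
            if b in rep_bip:
                counts[b] += 1
    supports = {b: 100.0 * c / reps for b, c in counts.items()}
    tree = point.copy()
    all_leaves = frozenset(tree.leaf_names())
    ref = min(all_leaves)
    for node in tree.root.walk():
        if node is tree.root or node.is_leaf:
            continue
        side = frozenset(l.name for l in node.leaves())
        if ref in side:
            side = all_leaves - side
        if side in supports:
            node.support = supports[side]
    return SupportedTree(tree=Tree(tree.root), supports=supports)


# ---------------------------------------------------------------------------
# parsimony
# ---------------------------------------------------------------------------


def _postorder(tree: Tree):
    order: list[Node] = []

    def rec(node: Node) -> None:
        for c in node.children:
            rec(c)
        order.append(node)

    rec(tree.root)
    return order


def fitch_score(tree: Tree, aln: Alignment) -> int:
    """Minimum number of substitutions over all ancestral labelings.

    Gaps (and X) are missing data: they contribute no state and no change.
    """
    if set(tree.leaf_names()) != set(aln.ids):
        raise ValueError("tree leaves and alignment rows differ")
    rows = dict(aln.rows)
    order = _postorder(tree)
    total = 0
    for c in range(aln.length):
        states: dict[int, frozenset | None] = {}
        changes = 0
        for node in order:
            if node.is_leaf:
                ch = rows[node.name][c]
                states[id(node)] = None if ch in _MISSING else frozenset((ch,))
            else:
                acc: frozenset | None = None
                for child in node.children:
                    s = states[id(child)]
                    if s is None:
                        continue
                    if acc is None:
                        acc = s
                    else:
                        inter = acc & s
                        if inter:
                            acc = inter
                        else:
                            acc = acc | s
                            changes += 1
                states[id(node)] = acc
        total += changes
    return total


def _enumerate_topologies(labels: list[str]):
    """All unrooted binary topologies (trifurcating root representation)."""
    labels = list(labels)

    def build(k: int):
        if k == 3:
            root = Node()
            for l in labels[:3]:
                root.add(Node(name=l))
            yield root
            return
        for base in build(k - 1):
            # edges = every non-root node
            nodes = [n for n in base.walk() if n is not base]
            for target in nodes:
                parent = target.parent
                joint = Node()
                idx = parent.children.index(target)
                parent.children[idx] = joint
                joint.parent = parent
                joint.add(target)
                joint.add(Node(name=labels[k - 1]))
                yield base
                # undo the insertion before trying the next edge
                parent.children[idx] = target
                target.parent = parent

    for root in build(len(labels)):
        yield Tree(root).copy()


def _random_topology(labels: list[str], rng: np.random.Generator) -> Tree:
    labels = list(labels)
    rng.shuffle(labels)
    root = Node()
    for l in labels[:3]:
        root.add(Node(name=l))
    for l in labels[3:]:
        nodes = [n for n in root.walk() if n is not root]
        target = nodes[rng.integers(0, len(nodes))]
        parent = target.parent
        joint = Node()
        idx = parent.children.index(target)
        parent.children[idx] = joint
        joint.parent = parent
        joint.add(target)
        joint.add(Node(name=l))
    return Tree(root)


def _nni_neighbors(tree: Tree):
    """All trees one nearest-neighbor interchange away.

    Nodes are matched between copies by their leaf-set signature (unique
    within a tree), so the swap can operate on a fresh copy each time.
    """
    result = []
    sig = lambda n: frozenset(l.name for l in n.leaves())
    for node in tree.root.walk():
        if node is tree.root or node.is_leaf or node.parent is None:
            continue
        v_sig = sig(node)
        p = node.parent
        for s in [c for c in p.children if c is not node]:
            s_sig = sig(s)
            for child in node.children:
                c_sig = sig(child)
                t = tree.copy()
                # find corresponding nodes in the copy
                v2 = next(n for n in t.root.walk() if not n.is_leaf and sig(n) == v_sig and n is not t.root)
                p2 = v2.parent
                s2 = next(c for c in p2.children if c is not v2 and sig(c) == s_sig)
                c2 = next(c for c in v2.children if sig(c) == c_sig)
                vi = v2.children.index(c2)
                pi = p2.children.index(s2)
                v2.children[vi], p2.children[pi] = s2, c2
                s2.parent, c2.parent = v2, p2
                result.append(Tree(t.root))
    return result


def mp_tree(aln: Alignment, seed: int = 0, n_restarts: int = 10) -> Tree:
    """Most-parsimonious tree.

    Exhaustive search over all unrooted topologies for up to 8 taxa;
    otherwise NNI hill-climbing from the NJ tree plus seed-controlled random
    restarts. Ties resolve toward the smallest canonical Newick string.
    """
    labels = aln.ids
    if len(labels) < 4:
        raise ValueError("parsimony needs at least 4 taxa")
    if len(labels) <= 8:
        best = None
        for t in _enumerate_topologies(labels):
            s = fitch_score(t, aln)
            key = (s, t.canonical_newick(include_support=False))
            if best is None or key < best[0]:
                best = (key, t)
        return best[1]
    rng = np.random.default_rng(seed)
    starts = [nj_tree(p_distance(aln))]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(_random_topology(labels, rng))
    best = None
    for start in starts:
        current = start.copy()
        for node in current.root.walk():
            node.length = None
            node.support = None
        score = fitch_score(current, aln)
        improved = True
        while improved:
            improved = False
            for nb in _nni_neighbors(current):
                s = fitch_score(nb, aln)
                if s < score:
                    current, score = nb, s
                    improved = True
                    break
        key = (score, current.canonical_newick(include_support=False))
        if best is None or key < best[0]:
            best = (key, current)
    return best[1]


# ---------------------------------------------------------------------------
# Poisson maximum likelihood
# ---------------------------------------------------------------------------

_N_STATES = 20
_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_IDX = {a: i for i, a in enumerate(_AA)}


def _pmatrix(t: float) -> np.ndarray:
    e = np.exp(-_N_STATES * t / (_N_STATES - 1))
    same = 1.0 / _N_STATES + (_N_STATES - 1) / _N_STATES * e
    diff = (1.0 - e) / _N_STATES
    P = np.full((_N_STATES, _N_STATES), diff)
    np.fill_diagonal(P, same)
    return P


def _leaf_conditionals(aln: Alignment) -> tuple[dict[str, np.ndarray], int]:
    cols_keep = []
    arr = {rid: g for rid, g in aln.rows}
    L = aln.length
    dropped = 0
    for c in range(L):
        if all(arr[rid][c] in _MISSING for rid in arr):
            dropped += 1
        else:
            cols_keep.append(c)
    if dropped:
        warnings.warn(f"dropped {dropped} all-gap column(s)")
    cond = {}
    for rid, g in aln.rows:
        mat = np.ones((_N_STATES, len(cols_keep)))
        for k, c in enumerate(cols_keep):
            ch = g[c]
            if ch not in _MISSING:
                if ch not in _AA_IDX:
                    raise ValueError(f"unknown residue {ch!r}")
                mat[:, k] = 0.0
                mat[_AA_IDX[ch], k] = 1.0
        cond[rid] = mat
    return cond, len(cols_keep)


def _loglik(tree: Tree, leaf_cond: dict[str, np.ndarray], ncols: int) -> float:
    order = _postorder(tree)
    partial: dict[int, np.ndarray] = {}
    logscale = 0.0
    for node in order:
        if node.is_leaf:
            partial[id(node)] = leaf_cond[node.name]
        else:
            acc = np.ones((_N_STATES, ncols))
            for child in node.children:
                P = _pmatrix(child.length if child.length is not None else 0.1)
                acc = acc * (P @ partial[id(child)])
            mx = acc.max(axis=0)
            mx[mx == 0] = 1.0
            logscale += float(np.log(mx).sum())
            partial[id(node)] = acc / mx
    root_like = partial[id(tree.root)].mean(axis=0)  # uniform 1/20 prior
    return float(np.log(root_like).sum()) + logscale


def _optimize_branches(
    tree: Tree, leaf_cond, ncols, tol: float = 1e-6, rounds: int = 2
) -> float:
    branches = [n for n in tree.root.walk() if n is not tree.root]
    for n in branches:
        if n.length is None or n.length <= 0:
            n.length = 0.05
    ll = _loglik(tree, leaf_cond, ncols)
    for _ in range(rounds):
        for node in branches:
            def neg(t: float) -> float:
                node.length = t
                return -_loglik(tree, leaf_cond, ncols)

            res = minimize_scalar(
                neg, bounds=(1e-9, 10.0), method="bounded",
                options={"xatol": tol / 10},
            )
            node.length = float(res.x)
        new_ll = _loglik(tree, leaf_cond, ncols)
        if abs(new_ll - ll) < 1e-8:
            ll = new_ll
            break
        ll = new_ll
    return ll


def ml_tree_poisson(
    aln: Alignment, start: Tree | None = None, do_nni: bool = True
) -> tuple[Tree, float]:
    """Maximum-likelihood tree under the Poisson amino-acid model.

    Branch lengths are optimised by bounded one-dimensional search; NNI
    rearrangements are accepted when the log-likelihood improves. For two
    sequences the single path length is returned on a two-leaf tree.
    """
    if len(aln.rows) < 2:
        raise ValueError("need at least 2 rows")
    leaf_cond, ncols = _leaf_conditionals(aln)
    if len(aln.rows) == 2:
        (ida, _), (idb, _) = aln.rows
        root = Node()
        a = root.add(Node(name=ida))
        b = root.add(Node(name=idb))
        tree = Tree(root)

        def neg(t: float) -> float:
            a.length = t / 2
            b.length = t / 2
            return -_loglik(tree, leaf_cond, ncols)

        res = minimize_scalar(
            neg, bounds=(1e-12, 10.0), method="bounded", options={"xatol": 1e-10}
        )
        t = float(res.x)
        a.length = b.length = t / 2
        return tree, -float(res.fun)
    if start is None:
        start = nj_tree(p_distance(aln))
    tree = start.copy()
    for node in tree.root.walk():
        node.support = None
    ll = _optimize_branches(tree, leaf_cond, ncols)
    if do_nni:
        improved = True
        while improved:
            improved = False
            # neighbors are screened at current branch lengths; branches are
            # re-optimised only after an accepted move
            for nb in _nni_neighbors(tree):
                nb_ll = _loglik(nb, leaf_cond, ncols)
                if nb_ll > ll + 1e-8:
                    tree = nb
                    ll = _optimize_branches(tree, leaf_cond, ncols, rounds=1)
                    improved = True
                    break
        ll = _optimize_branches(tree, leaf_cond, ncols)
    return tree, ll


# ---------------------------------------------------------------------------
# subfamily calling
# ---------------------------------------------------------------------------


def call_subfamilies(
    nj: SupportedTree,
    mp: Tree,
    ml: Tree,
    anchors: dict[str, str],
    min_support: float = 88.0,
    require_both_other: bool = False,
) -> SubfamilyAssignment:
    """Label genes by supported clades containing subfamily anchors.

    A candidate clade is one side of an NJ bipartition with bootstrap
    support strictly above ``min_support`` that is also present in at least
    one (or both, with ``require_both_other``) of the MP and ML trees. Each
    subfamily is the maximal candidate clade containing all of its anchors
    and no anchor of another subfamily; leaves in no named clade are
    orphans. Anchor pairs of different names that no candidate clade
    separates leave both subfamilies unresolved.
    """
    leaves = set(nj.tree.leaf_names())
    if set(mp.leaf_names()) != leaves or set(ml.leaf_names()) != leaves:
        raise ValueError("trees must share one leaf set")
    missing = set(anchors) - leaves
    if missing:
        raise ValueError(f"anchors missing from tree: {sorted(missing)}")
    mp_bip = mp.bipartitions()
    ml_bip = ml.bipartitions()
    all_leaves = frozenset(leaves)
    ref = min(all_leaves)

    # candidate clades: both sides of every qualifying bipartition
    candidates: list[frozenset] = []
    for bip, sup in nj.supports.items():
        if sup is None or sup <= min_support:
            continue
        present = (bip in mp_bip) + (bip in ml_bip)
        needed = 2 if require_both_other else 1
        if present < needed:
            continue
        candidates.append(bip)
        candidates.append(all_leaves - bip)

    names = sorted(set(anchors.values()))
    anchor_sets = {n: {a for a, an in anchors.items() if an == n} for n in names}
    clades: dict[str, frozenset] = {}
    unresolved: set[str] = set()
    for name in names:
        own = anchor_sets[name]
        foreign = set(anchors) - own
        qualifying = [
            c for c in candidates if own <= c and not (foreign & c)
        ]
        if qualifying:
            clades[name] = max(qualifying, key=lambda c: (len(c), sorted(c)))
    # unresolved: names whose anchors cannot be separated from another name
    for na, nb in itertools.combinations(names, 2):
        if na in clades or nb in clades:
            continue
        separable = any(
            (anchor_sets[na] <= c and not (anchor_sets[nb] & c))
            or (anchor_sets[nb] <= c and not (anchor_sets[na] & c))
            for c in candidates
        )
        if not separable:
            unresolved.update((na, nb))

    assignments: dict[str, str] = {}
    for leaf in leaves:
        if leaf in anchors:
            assignments[leaf] = (
                "unresolved" if anchors[leaf] in unresolved else anchors[leaf]
            )
            continue
        containing = [(len(c), n) for n, c in clades.items() if leaf in c]
        if containing:
            assignments[leaf] = min(containing)[1]  # most specific clade
        else:
            assignments[leaf] = "orphan"
    return SubfamilyAssignment(
        assignments=assignments, clades=clades, unresolved=unresolved
    )
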