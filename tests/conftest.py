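import numpy as np
import pytest

from gofamcat.domains import ConsensusProfile
from gofamcat.seqio import Alignment, SequenceRecord
from gofamcat.trees import Node, Tree


@pytest.fixture(scope="session")
def profile() -> ConsensusProfile:
    return ConsensusProfile.default()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_protein(rng: np.random.Generator, n: int) -> str:
    aa = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(aa[i] for i in rng.integers(0, 20, size=n))


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def random_additive_tree(rng: np.random.Generator, labels: list[str]) -> Tree:
    """Random binary topology with strictly positive branch lengths."""
    nodes = [Node(name=l, length=float(rng.uniform(0.05, 0.5))) for l in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node(length=float(rng.uniform(0.05, 0.5)))
        parent.add(nodes[i])
        parent.add(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = Node()
    for n in nodes:
        root.add(n)
    return Tree(root)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def oracle_local_score(q: str, s: str, matrix, gap_open=11, gap_extend=1) -> float:
    """Exhaustive enumeration of local alignment paths (no DP tables).

    Every alignment path is walked explicitly; affine gap state is carried
    along the path. Exponential — only for very short peptides.
    """
    best = 0.0

    def rec(i: int, j: int, score: float, state: int) -> None:
        nonlocal best
        if score > best:
            best = score
        if i < len(q) and j < len(s):
            rec(i + 1, j + 1, score + matrix[q[i]][s[j]], 0)
        if i < len(q):
            cost = gap_extend if state == 1 else gap_open + gap_extend
            rec(i + 1, j, score - cost, 1)
        if j < len(s):
            cost = gap_extend if state == 2 else gap_open + gap_extend
            rec(i, j + 1, score - cost, 2)

    for i0 in range(len(q)):
        for j0 in range(len(s)):
            # a maximal local alignment always starts on a matched pair
            rec(i0 + 1, j0 + 1, float(matrix[q[i0]][s[j0]]), 0)
    return best


def _tree_edges(tree: Tree):
    """(parent index, node) pairs and leaf/internal bookkeeping."""
    nodes = list(tree.root.walk())
    index = {id(n): k for k, n in enumerate(nodes)}
    edges = [
        (index[id(n.parent)], index[id(n)]) for n in nodes if n.parent is not None
    ]
    return nodes, index, edges


def oracle_parsimony_column(tree: Tree, states: dict[str, str | None]) -> int:
    """Minimum substitutions for one column by exhaustive ancestral labeling."""
    import itertools

    nodes, index, edges = _tree_edges(tree)
    observed = sorted({s for s in states.values() if s is not None})
    if len(observed) <= 1:
        return 0
    internals = [k for k, n in enumerate(nodes) if not n.is_leaf]
    best = None
    for combo in itertools.product(observed, repeat=len(internals)):
        assign: dict[int, str | None] = {k: v for k, v in zip(internals, combo)}
        for k, n in enumerate(nodes):
            if n.is_leaf:
                assign[k] = states[n.name]
        changes = 0
        for p, c in edges:
            if assign[p] is not None and assign[c] is not None and assign[p] != assign[c]:
                changes += 1
        if best is None or changes < best:
            best = changes
    return best


def oracle_parsimony_score(tree: Tree, aln: Alignment) -> int:
    rows = dict(aln.rows)
    total = 0
    for c in range(aln.length):
        states = {
            rid: (None if rows[rid][c] in "-X" else rows[rid][c]) for rid in rows
        }
        total += oracle_parsimony_column(tree, states)
    return total


def all_unrooted_topologies(labels: list[str]):
    """Independent stepwise enumeration of unrooted topologies as Trees."""
    def attach_everywhere(tree: Tree, label: str):
        out = []
        sig_nodes = [n for n in tree.root.walk() if n is not tree.root]
        for k in range(len(sig_nodes)):
            t = tree.copy()
            nodes = [n for n in t.root.walk() if n is not t.root]
            target = nodes[k]
            parent = target.parent
            joint = Node()
            idx = parent.children.index(target)
            parent.children[idx] = joint
            joint.parent = parent
            joint.add(target)
            joint.add(Node(name=label))
            out.append(Tree(t.root))
        return out

    root = Node()
    for l in labels[:3]:
        root.add(Node(name=l))
    trees = [Tree(root)]
    for label in labels[3:]:
        trees = [t2 for t in trees for t2 in attach_everywhere(t, label)]
    return trees
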