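import math

import numpy as np
import pytest

from gofamcat.phylo import (
    DistanceMatrix,
    SupportedTree,
    bootstrap_support,
    call_subfamilies,
    fitch_score,
    ml_tree_poisson,
    mp_tree,
    nj_tree,
    p_distance,
)
from gofamcat.seqio import Alignment
from gofamcat.trees import Node, Tree, parse_newick

from conftest import (
    all_unrooted_topologies,
    oracle_parsimony_score,
    random_additive_tree,
)


class TestPDistance:
    def test_identical_rows_zero(self):
        d = p_distance(Alignment(rows=[("a", "MKLR"), ("b", "MKLR")]))
        assert d.matrix[0, 1] == 0

    def test_three_of_thirty(self):
        a = "A" * 30
        b = "C" * 3 + "A" * 27
        d = p_distance(Alignment(rows=[("a", a), ("b", b)]))
        assert d.matrix[0, 1] == pytest.approx(0.1)

    def test_gap_columns_excluded_pairwise(self):
        # only 3 comparable columns between the two rows
        d = p_distance(Alignment(rows=[("a", "A-CC"), ("b", "ATCG")]))
        assert d.matrix[0, 1] == pytest.approx(1 / 3)

    def test_zero_overlap_pair_raises(self):
        with pytest.raises(ValueError, match="comparable"):
            p_distance(Alignment(rows=[("a", "AA--"), ("b", "--CC")]))


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = DistanceMatrix(
            labels=["A", "B", "C"],
            matrix=np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]]),
        )
        t = nj_tree(d)
        la = t.find_leaf("A").length
        lb = t.find_leaf("B").length
        lc = t.find_leaf("C").length
        assert la == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lb == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lc == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_additive_six_taxon_recovery(self, rng):
        for _ in range(10):
            true = random_additive_tree(rng, list("ABCDEF"))
            labels, mat = true.patristic_matrix()
            est = nj_tree(DistanceMatrix(labels=labels, matrix=mat))
            assert est.bipartitions() == true.bipartitions()
            l2, m2 = est.patristic_matrix()
            assert l2 == labels
            assert np.abs(m2 - mat).max() < 1e-9

    def test_label_permutation_invariance(self, rng):
        true = random_additive_tree(rng, list("ABCDEF"))
        labels, mat = true.patristic_matrix()
        t1 = nj_tree(DistanceMatrix(labels=labels, matrix=mat))
        perm = rng.permutation(len(labels))
        t2 = nj_tree(
            DistanceMatrix(
                labels=[labels[i] for i in perm], matrix=mat[np.ix_(perm, perm)]
            )
        )
        assert t1.bipartitions() == t2.bipartitions()

    def test_fewer_than_three_taxa_raises(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(labels=["A", "B"], matrix=np.zeros((2, 2))))

    def test_agrees_with_independent_nj_implementation(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as skbio_nj

        for _ in range(5):
            true = random_additive_tree(rng, list("ABCDEFG"))
            labels, mat = true.patristic_matrix()
            ours = nj_tree(DistanceMatrix(labels=labels, matrix=mat))
            theirs = skbio_nj(skbio.DistanceMatrix(mat, ids=labels))
            their_bips = set()
            all_leaves = frozenset(labels)
            ref = min(labels)
            for node in theirs.non_tips(include_self=False):
                side = frozenset(t.name for t in node.tips())
                if ref in side:
                    side = all_leaves - side
                if 2 <= len(side) <= len(labels) - 2:
                    their_bips.add(side)
            assert ours.bipartitions() == their_bips


def _clan_alignment():
    """Two 4-taxon clans with saturated diagnostic signal, zero noise."""
    rows = []
    for k in range(4):
        rows.append((f"a{k}", "A" * 40 + "CG" * (k + 1) + "AT" * (4 - k)))
        rows.append((f"b{k}", "C" * 40 + "CG" * (k + 1) + "AT" * (4 - k)))
    return Alignment(rows=rows)


class TestBootstrap:
    def test_same_seed_identical_supports(self):
        aln = _clan_alignment()
        s1 = bootstrap_support(aln, reps=50, seed=7)
        s2 = bootstrap_support(aln, reps=50, seed=7)
        assert s1.supports == s2.supports

    def test_single_rep_supports_are_zero_or_hundred(self):
        st = bootstrap_support(_clan_alignment(), reps=1, seed=0)
        assert set(st.supports.values()) <= {0.0, 100.0}

    def test_saturated_clan_split_at_hundred(self):
        st = bootstrap_support(_clan_alignment(), reps=200, seed=3)
        clan = frozenset({"b0", "b1", "b2", "b3"})
        assert st.supports[clan] == 100.0

    def test_supports_in_range(self):
        st = bootstrap_support(_clan_alignment(), reps=30, seed=1)
        assert all(0 <= v <= 100 for v in st.supports.values())


class TestParsimony:
    def test_invariant_alignment_scores_zero(self):
        t = parse_newick("((A,B),(C,D),E);")
        aln = Alignment(rows=[(l, "AAAA") for l in "ABCDE"])
        assert fitch_score(t, aln) == 0

    def test_single_change_column(self):
        t = parse_newick("((A1,A2),(C1,C2));")
        aln = Alignment(
            rows=[("A1", "A"), ("A2", "A"), ("C1", "C"), ("C2", "C")]
        )
        assert fitch_score(t, aln) == 1

    def test_matches_exhaustive_sankoff_oracle(self, rng):
        for _ in range(5):
            t = random_additive_tree(rng, list("ABCDE"))
            cols = ["".join("ACGT"[i] for i in rng.integers(0, 4, 5)) for _ in range(8)]
            aln = Alignment(
                rows=[(l, "".join(col[k] for col in cols)) for k, l in enumerate("ABCDE")]
            )
            assert fitch_score(t, aln) == oracle_parsimony_score(t, aln)

    def test_mp_tree_matches_exhaustive_search(self, rng):
        for _ in range(3):
            cols = ["".join("ACGT"[i] for i in rng.integers(0, 4, 5)) for _ in range(12)]
            aln = Alignment(
                rows=[(l, "".join(col[k] for col in cols)) for k, l in enumerate("ABCDE")]
            )
            best = mp_tree(aln)
            scores = [
                oracle_parsimony_score(t, aln)
                for t in all_unrooted_topologies(list("ABCDE"))
            ]
            assert fitch_score(best, aln) == min(scores)

    def test_dominant_split_recovered(self):
        rows = [
            ("A", "AAAAAAAAGC"),
            ("B", "AAAAAAAAGG"),
            ("C", "CCCCCCCCGC"),
            ("D", "CCCCCCCCGG"),
            ("E", "CCCCCCCCCC"),
        ]
        best = mp_tree(Alignment(rows=rows))
        assert frozenset({"C", "D", "E"}) in best.bipartitions() or frozenset(
            {"A", "B"}
        ) in best.bipartitions()

    def test_three_taxa_raises(self):
        with pytest.raises(ValueError):
            mp_tree(Alignment(rows=[("A", "AC"), ("B", "AC"), ("C", "AC")]))


class TestPoissonML:
    @pytest.mark.parametrize("p_hat", [0.05, 0.15, 0.30, 0.45, 0.60])
    def test_two_taxon_mle_matches_closed_form(self, p_hat):
        n = 400
        k = round(p_hat * n)
        aln = Alignment(rows=[("x", "A" * n), ("y", "C" * k + "A" * (n - k))])
        tree, _ll = ml_tree_poisson(aln)
        t_hat = sum(c.length for c in tree.root.children)
        t_expected = -(19 / 20) * math.log(1 - 20 * (k / n) / 19)
        assert t_hat == pytest.approx(t_expected, abs=1e-5)

    def test_identical_pair_maximised_at_zero(self):
        aln = Alignment(rows=[("x", "ACDEF" * 20), ("y", "ACDEF" * 20)])
        tree, _ = ml_tree_poisson(aln)
        assert sum(c.length for c in tree.root.children) < 1e-6

    def test_four_taxon_concordance_on_clean_signal(self):
        rows = [
            ("A", "A" * 20 + "C" * 10),
            ("B", "A" * 20 + "G" * 10),
            ("C", "T" * 20 + "C" * 10),
            ("D", "T" * 20 + "G" * 10),
        ]
        aln = Alignment(rows=rows)
        nj = nj_tree(p_distance(aln))
        mp = mp_tree(aln)
        ml, _ = ml_tree_poisson(aln)
        assert nj.bipartitions() == mp.bipartitions() == ml.bipartitions()

    def test_all_gap_column_dropped_with_warning(self):
        aln = Alignment(rows=[("x", "AC-"), ("y", "AG-"), ("z", "AT-")])
        with pytest.warns(UserWarning, match="all-gap"):
            ml_tree_poisson(aln, do_nni=False)


def _three_clan_trees(support: float):
    """Identical NJ/MP/ML topology over three labelled clans."""
    newick = "(((a1,a2,x1)," "(b1,b2,x2)),(c1,c2,x3));"
    nj = parse_newick(newick)
    supports = {b: support for b in nj.bipartitions()}
    return SupportedTree(tree=nj, supports=supports), parse_newick(newick), parse_newick(newick)


class TestCallSubfamilies:
    ANCHORS = {"x1": "S1", "x2": "S2", "x3": "S3"}

    def test_concordant_full_support_labels_all(self):
        nj, mp, ml = _three_clan_trees(100.0)
        out = call_subfamilies(nj, mp, ml, self.ANCHORS)
        assert out.assignments["a1"] == "S1"
        assert out.assignments["b2"] == "S2"
        assert out.assignments["c1"] == "S3"
        assert not out.unresolved

    def test_clade_present_only_in_nj_is_ignored(self):
        nj, _, _ = _three_clan_trees(100.0)
        other = parse_newick("((a1,b1,x1),(a2,b2,x2),(c1,c2,x3));")
        out = call_subfamilies(nj, other, other, self.ANCHORS)
        # clan S1/S2 clades exist only in the NJ tree -> genes fall through
        assert out.assignments["a1"] in ("orphan", "S1")
        # with no candidate clade at all for S1, a1 must be orphan
        if "S1" not in out.clades:
            assert out.assignments["a1"] == "orphan"

    def test_support_exactly_at_threshold_rejected(self):
        nj, mp, ml = _three_clan_trees(88.0)
        out = call_subfamilies(nj, mp, ml, self.ANCHORS, min_support=88)
        assert out.clades == {}
        assert all(
            v in ("orphan", "unresolved") for k, v in out.assignments.items()
            if k not in self.ANCHORS
        )

    def test_leaf_order_permutation_invariance(self):
        nj, mp, ml = _three_clan_trees(95.0)
        permuted = parse_newick("((c2,c1,x3),((x2,b2,b1),(x1,a2,a1)));")
        out1 = call_subfamilies(nj, mp, ml, self.ANCHORS)
        out2 = call_subfamilies(nj, permuted, permuted, self.ANCHORS)
        assert out1.assignments == out2.assignments

    def test_missing_anchor_raises(self):
        nj, mp, ml = _three_clan_trees(95.0)
        with pytest.raises(ValueError, match="missing"):
            call_subfamilies(nj, mp, ml, {"nope": "S1"})

    def test_inseparable_anchor_pair_reported_unresolved(self):
        # anchors x1 and x2 sit in one cherry that no candidate clade splits
        newick = "(((x1,x2),(a1,a2)),(c1,x3));"
        t = parse_newick(newick)
        nj = SupportedTree(tree=t, supports={b: 100.0 for b in t.bipartitions()})
        anchors = {"x1": "S1", "x2": "S2", "x3": "S3"}
        out = call_subfamilies(nj, parse_newick(newick), parse_newick(newick), anchors)
        assert {"S1", "S2"} <= out.unresolved
        assert out.assignments["x1"] == "unresolved"
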