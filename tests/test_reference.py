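import numpy as np
import pytest

from gofamcat.reference import (
    GuideTree,
    OrthologGroup,
    assign_codes,
    build_guide_tree,
    collapse_identical_tandem,
    group_by_thresholds,
    overlap_matrix,
    select_representative,
)
from gofamcat.seqio import SequenceRecord, Source
from gofamcat.simulate import mutate

from conftest import random_protein


def _rec(rid, seq, source=Source.user):
    return SequenceRecord(id=rid, residues=seq, source=source)


def _guide(labels, dists):
    n = len(labels)
    m = np.zeros((n, n))
    for (a, b), d in dists.items():
        i, j = labels.index(a), labels.index(b)
        m[i, j] = m[j, i] = d
    return GuideTree(labels=labels, bl=m)


class TestCollapse:
    def test_identical_within_source_merge(self, rng):
        seq = random_protein(rng, 60)
        out = collapse_identical_tandem(
            {Source.GaCGP: [_rec("t1", seq, Source.GaCGP), _rec("t2", seq, Source.GaCGP)]}
        )
        assert len(out[Source.GaCGP]) == 1
        assert "identical:t2" in out[Source.GaCGP][0].description

    def test_identical_across_sources_kept(self, rng):
        seq = random_protein(rng, 60)
        out = collapse_identical_tandem(
            {
                Source.GrJGI: [_rec("a", seq, Source.GrJGI)],
                Source.GrCGP: [_rec("b", seq, Source.GrCGP)],
            }
        )
        assert sum(len(v) for v in out.values()) == 2

    def test_distinct_proteins_untouched(self, rng):
        recs = [_rec(f"r{i}", random_protein(rng, 60)) for i in range(3)]
        out = collapse_identical_tandem({Source.user: recs})
        assert len(out[Source.user]) == 3


class TestGuideTree:
    def test_ten_percent_divergence_recovered(self, rng):
        base = random_protein(rng, 300)
        other = mutate(base, 0.105, 1)  # ~10% of sites substituted
        gt = build_guide_tree([_rec("a", base), _rec("b", other)])
        assert gt.distance("a", "b") == pytest.approx(0.10, abs=0.02)

    def test_identical_records_zero_bl(self, rng):
        seq = random_protein(rng, 100)
        gt = build_guide_tree([_rec("a", seq), _rec("b", seq), _rec("c", seq)])
        assert np.allclose(gt.bl, 0)

    def test_bl_matrix_symmetric_zero_diagonal(self, rng):
        recs = [_rec(f"r{i}", random_protein(rng, 80)) for i in range(5)]
        gt = build_guide_tree(recs)
        assert np.allclose(gt.bl, gt.bl.T)
        assert np.allclose(np.diag(gt.bl), 0)

    def test_single_record_raises(self, rng):
        with pytest.raises(ValueError):
            build_guide_tree([_rec("a", random_protein(rng, 50))])


class TestGrouping:
    def _records(self, labels, rng):
        return [_rec(l, random_protein(rng, 40)) for l in labels]

    def test_single_linkage_partition_and_labels(self, rng):
        labels = ["A", "B", "C", "D"]
        dists = {
            ("A", "B"): 0.01,
            ("A", "C"): 0.10,
            ("B", "C"): 0.10,
            ("A", "D"): 0.50,
            ("B", "D"): 0.50,
            ("C", "D"): 0.50,
        }
        groups = group_by_thresholds(_guide(labels, dists), self._records(labels, rng))
        parts = sorted(tuple(g.member_ids) for g in groups)
        assert parts == [("A", "B", "C"), ("D",)]
        abc = next(g for g in groups if len(g.members) == 3)
        assert abc.pair_labels[frozenset(("A", "B"))] == "allele"
        assert abc.pair_labels[frozenset(("A", "C"))] == "ortholog"
        assert abc.pair_labels[frozenset(("B", "C"))] == "ortholog"

    def test_all_distant_gives_singletons(self, rng):
        labels = [f"x{i}" for i in range(5)]
        dists = {
            (a, b): 0.5 for i, a in enumerate(labels) for b in labels[i + 1 :]
        }
        groups = group_by_thresholds(_guide(labels, dists), self._records(labels, rng))
        assert len(groups) == 5

    def test_linkage_chaining_flagged(self, rng):
        labels = ["A", "B", "C"]
        dists = {("A", "B"): 0.14, ("B", "C"): 0.14, ("A", "C"): 0.20}
        groups = group_by_thresholds(_guide(labels, dists), self._records(labels, rng))
        assert len(groups) == 1
        assert groups[0].pair_labels[frozenset(("A", "C"))] == "chained"

    def test_partition_is_order_invariant(self, rng):
        labels = ["A", "B", "C", "D", "E"]
        base = {
            ("A", "B"): 0.05, ("A", "C"): 0.12, ("B", "C"): 0.09,
            ("A", "D"): 0.4, ("B", "D"): 0.4, ("C", "D"): 0.4,
            ("A", "E"): 0.4, ("B", "E"): 0.4, ("C", "E"): 0.4, ("D", "E"): 0.1,
        }
        recs = self._records(labels, rng)
        ref = {tuple(g.member_ids) for g in group_by_thresholds(_guide(labels, base), recs)}
        perm = ["E", "C", "A", "D", "B"]
        permuted = _guide(perm, base)
        got = {
            tuple(g.member_ids)
            for g in group_by_thresholds(permuted, recs)
        }
        assert got == ref

    def test_bad_thresholds_raise(self, rng):
        labels = ["A", "B"]
        with pytest.raises(ValueError):
            group_by_thresholds(
                _guide(labels, {("A", "B"): 0.1}),
                self._records(labels, rng),
                allele_thr=0.2,
                ortholog_thr=0.1,
            )


class TestRepresentativesAndCodes:
    def test_priority_prefers_grjgi(self, rng):
        g = OrthologGroup(
            members=[
                _rec("zz", random_protein(rng, 30), Source.GaCGP),
                _rec("aa", random_protein(rng, 30), Source.GrJGI),
            ]
        )
        assert select_representative(g) == "aa"

    def test_fallback_to_mrna_smallest_id(self, rng):
        g = OrthologGroup(
            members=[
                _rec("m2", random_protein(rng, 30), Source.mRNA),
                _rec("m1", random_protein(rng, 30), Source.mRNA),
            ]
        )
        assert select_representative(g) == "m1"

    def test_codes_follow_natural_sort_of_representatives(self, rng):
        groups = [
            OrthologGroup(members=[_rec(rid, random_protein(rng, 30), Source.GrJGI)])
            for rid in ("zzz", "aaa", "mmm", "g10", "g2")
        ]
        coded = assign_codes(groups)
        assert [(g.representative, g.code) for g in coded] == [
            ("aaa", "GobHLH001"),
            ("g2", "GobHLH002"),
            ("g10", "GobHLH003"),
            ("mmm", "GobHLH004"),
            ("zzz", "GobHLH005"),
        ]

    def test_zero_groups(self):
        assert assign_codes([]) == []


class TestOverlap:
    def test_hand_counts(self, rng):
        g1 = OrthologGroup(
            members=[
                _rec("a", random_protein(rng, 30), Source.GrJGI),
                _rec("b", random_protein(rng, 30), Source.GaCGP),
            ]
        )
        g2 = OrthologGroup(members=[_rec("c", random_protein(rng, 30), Source.GrJGI)])
        t = overlap_matrix([g1, g2]).table
        assert t.loc["GrJGI", "GrJGI"] == 2
        assert t.loc["GaCGP", "GaCGP"] == 1
        assert t.loc["GrJGI", "GaCGP"] == 1

    def test_single_source_off_diagonals_zero(self, rng):
        groups = [
            OrthologGroup(members=[_rec(f"r{i}", random_protein(rng, 30), Source.GhUni)])
            for i in range(3)
        ]
        t = overlap_matrix(groups).table
        assert t.shape == (1, 1)
        assert t.iloc[0, 0] == 3

    def test_symmetry(self, rng):
        from gofamcat.simulate import emulate_sources, make_family

        recs, truth = make_family(seed=4, n_subfam=3, genes_per_subfam=2)
        by_source = emulate_sources(recs, truth, dropout=0.3, seed=4)
        groups = []
        pooled = [r for rs in by_source.values() for r in rs]
        for gene, ids in truth.partition([r.id for r in pooled]).items():
            groups.append(
                OrthologGroup(members=[r for r in pooled if r.id in ids])
            )
        t = overlap_matrix(groups).table
        assert (t.values == t.values.T).all()
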