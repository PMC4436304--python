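"""Collapse multi-source redundancy into a coded reference gene set.

Proteins gathered from the six annotation sources are aligned, and the
guide-tree branch lengths (patristic leaf-to-leaf distances) classify each
pair: below 0.03 the two records are treated as copies of one allele,
between 0.03 and 0.15 as orthologs of different genomes, above 0.15 as
distinct paralogous genes. Single-linkage clustering at the ortholog
threshold yields the ortholog groups; one representative per group (source
priority Gr-JGI first) is coded GobHLH001, 002, ... in natural-sort order
of representative ids. The source-overlap matrix summarises how many genes
each pair of sources shares.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import align_progressive
from .phylo import DistanceMatrix, nj_tree, p_distance
from .seqio import SequenceRecord, Source, SOURCE_PRIORITY
from .trees import Node, Tree

__all__ = [
    "GuideTree",
    "OrthologGroup",
    "OverlapMatrix",
    "collapse_identical_tandem",
    "build_guide_tree",
    "group_by_thresholds",
    "select_representative",
    "assign_codes",
    "overlap_matrix",
]


@dataclass
class GuideTree:
    """Alignment guide tree with its pairwise branch-length (BL) matrix."""

    labels: list[str]
    bl: np.ndarray
    tree: Tree | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.bl, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("labels/BL shape mismatch")
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0):
            raise ValueError("BL matrix must be symmetric with zero diagonal")
        self.bl = m

    def distance(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.bl[i, j])


@dataclass
class OrthologGroup:
    members: list[SequenceRecord]
    pair_labels: dict[frozenset, str] = field(default_factory=dict)
    representative: str | None = None
    code: str | None = None

    @property
    def member_ids(self) -> list[str]:
        return sorted(r.id for r in self.members)

    @property
    def sources(self) -> set[Source]:
        return {r.source for r in self.members}


@dataclass
class OverlapMatrix:
    """Per-source gene counts (diagonal) and pairwise shared-group counts."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        diag = np.diag(t.values)
        if (t.values > np.minimum.outer(diag, diag)).any():
            raise ValueError("off-diagonal exceeds a diagonal count")


def collapse_identical_tandem(
    records_by_source: dict[Source, list[SequenceRecord]],
) -> dict[Source, list[SequenceRecord]]:
    """Merge byte-identical proteins *within* one source into one record.

    Tandem-duplicated genes encoding the same protein count as a single
    gene; identical proteins in different sources are kept (they become an
    allele-band pair downstream).
    """
    out: dict[Source, list[SequenceRecord]] = {}
    for source, records in records_by_source.items():
        seen: dict[str, SequenceRecord] = {}
        kept: list[SequenceRecord] = []
        for rec in records:
            prev = seen.get(rec.residues)
            if prev is None:
                seen[rec.residues] = rec
                kept.append(rec)
            else:
                extra = f"identical:{rec.id}"
                prev.description = (
                    f"{prev.description} {extra}".strip() if prev.description else extra
                )
        out[source] = kept
    return out


def build_guide_tree(
    records: list[SequenceRecord], mode: str = "patristic"
) -> GuideTree:
    """Align all records and materialise the BL matrix.

    ``mode`` selects the divergence measure: leaf-to-leaf patristic
    distance on the NJ guide tree (default) or the raw pairwise p-distance.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records to build a guide tree")
    if mode not in ("patristic", "pdistance"):
        raise ValueError(f"unknown BL mode {mode!r}")
    aln = align_progressive(records)
    dm = p_distance(aln)
    if len(records) == 2:
        root = Node()
        for lab in dm.labels:
            root.add(Node(name=lab, length=dm.matrix[0, 1] / 2))
        tree = Tree(root)
    else:
        tree = nj_tree(dm)
    if mode == "patristic":
        labels, bl = tree.patristic_matrix()
    else:
        order = np.argsort(dm.labels)
        labels = [dm.labels[k] for k in order]
        bl = dm.matrix[np.ix_(order, order)]
    return GuideTree(labels=labels, bl=bl, tree=tree)


def group_by_thresholds(
    guide: GuideTree,
    records: list[SequenceRecord],
    allele_thr: float = 0.03,
    ortholog_thr: float = 0.15,
) -> list[OrthologGroup]:
    """Single-linkage partition of the BL matrix at the ortholog threshold.

    Pairs with BL <= ortholog_thr connect; within a group each pair is
    labelled allele (BL < allele_thr), ortholog (allele_thr <= BL <=
    ortholog_thr) or chained (BL > ortholog_thr but linked transitively).
    The partition is independent of record order.
    """
    if not (0 < allele_thr < ortholog_thr):
        raise ValueError("thresholds must satisfy 0 < allele_thr < ortholog_thr")
    by_id = {r.id: r for r in records}
    missing = set(guide.labels) - set(by_id)
    if missing:
        raise ValueError(f"records missing for labels: {sorted(missing)}")
    labels = guide.labels
    n = len(labels)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if guide.bl[i, j] <= ortholog_thr:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    groups: list[OrthologGroup] = []
    for idxs in sorted(clusters.values(), key=lambda ix: min(labels[i] for i in ix)):
        members = sorted((by_id[labels[i]] for i in idxs), key=lambda r: r.id)
        pair_labels: dict[frozenset, str] = {}
        for a in range(len(idxs)):
            for b in range(a + 1, len(idxs)):
                d = guide.bl[idxs[a], idxs[b]]
                if d < allele_thr:
                    lab = "allele"
                elif d <= ortholog_thr:
                    lab = "ortholog"
                else:
                    lab = "chained"
                pair_labels[frozenset((labels[idxs[a]], labels[idxs[b]]))] = lab
        groups.append(OrthologGroup(members=members, pair_labels=pair_labels))
    return groups


def select_representative(
    group: OrthologGroup,
    priority: tuple[Source, ...] = SOURCE_PRIORITY,
) -> str:
    """Member from the highest-priority source; ties break on smallest id."""
    if not group.members:
        raise ValueError("empty group")
    rank = {s: k for k, s in enumerate(priority)}
    best = min(group.members, key=lambda r: (rank.get(r.source, len(rank)), r.id))
    group.representative = best.id
    return best.id


def _natural_key(s: str):
    return [int(tok) if tok.isdigit() else tok for tok in re.split(r"(\d+)", s)]


def assign_codes(
    groups: list[OrthologGroup], prefix: str = "GobHLH", digits: int = 3
) -> list[OrthologGroup]:
    """Sort groups by representative id (natural order) and code them."""
    for g in groups:
        if g.representative is None:
            select_representative(g)
    ordered = sorted(groups, key=lambda g: _natural_key(g.representative))
    for k, g in enumerate(ordered, start=1):
        g.code = f"{prefix}{k:0{digits}d}"
    return ordered


def overlap_matrix(
    groups: list[OrthologGroup], sources: list[Source] | None = None
) -> OverlapMatrix:
    """Diagonal: groups with >=1 member of the source; off-diagonal: shared."""
    if sources is None:
        present = {s for g in groups for s in g.sources}
        sources = [s for s in SOURCE_PRIORITY if s in present]
    names = [s.value for s in sources]
    mat = np.zeros((len(sources), len(sources)), dtype=int)
    for g in groups:
        gs = g.sources
        for i, si in enumerate(sources):
            if si not in gs:
                continue
            for j, sj in enumerate(sources):
                if sj in gs:
                    mat[i, j] += 1
    return OverlapMatrix(table=pd.DataFrame(mat, index=names, columns=names))
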