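"""Homoeologous gene comparison: structure mapping and variant detection.

Covers the tetraploid case study: assign each tetraploid gene to its A- or
D-genome progenitor by sequence relatedness, map exon–intron structure by
splicing the CDS back onto the genomic sequence (GT..AG introns), and call
the variant classes seen between homoeologs — in-frame/frameshift indels,
simple-sequence-repeat (SSR) tract-length differences, intron loss, and
large intron insertions whose direct terminal repeats flag an LTR
retrotransposon.

All genomic coordinates are 0-based half-open; exon/intron ordinals in
reports are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import global_align

__all__ = [
    "GeneModel",
    "GenomeOrigin",
    "Indel",
    "SSRDifference",
    "InsertionRecord",
    "VariantReport",
    "map_cds_to_genome",
    "assign_genome_origin",
    "detect_indels",
    "find_ssr",
    "ssr_difference",
    "detect_ltr_insertion",
    "compare_structures",
    "compare_pair",
]


@dataclass
class GeneModel:
    """Forward-strand gene: genomic sequence plus ordered exon spans."""

    gene_id: str
    genomic: str
    exons: list[tuple[int, int]]
    min_intron: int = 40
    check_splice: bool = True

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError("gene model needs at least one exon")
        prev_end = -1
        for s, e in self.exons:
            if not (0 <= s < e <= len(self.genomic)):
                raise ValueError(f"exon span ({s},{e}) outside genomic sequence")
            if s < prev_end:
                raise ValueError("exons overlap or are unordered")
            prev_end = e
        for i, (istart, iend) in enumerate(self.introns, start=1):
            if iend - istart < self.min_intron:
                raise ValueError(
                    f"intron {i} shorter than min_intron ({iend - istart} < {self.min_intron})"
                )
            if self.check_splice:
                donor = self.genomic[istart : istart + 2]
                acceptor = self.genomic[iend - 2 : iend]
                if donor != "GT" or acceptor != "AG":
                    raise ValueError(
                        f"intron {i} violates GT..AG rule ({donor}..{acceptor})"
                    )

    @property
    def cds(self) -> str:
        return "".join(self.genomic[s:e] for s, e in self.exons)

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    def intron_seq(self, index: int) -> str:
        """Sequence of the 1-based intron ``index``."""
        s, e = self.introns[index - 1]
        return self.genomic[s:e]

    def exon_lengths(self) -> list[int]:
        return [e - s for s, e in self.exons]

    def junctions(self) -> list[int]:
        """CDS coordinates of intron insertion points (cumulative exon ends)."""
        out, acc = [], 0
        for length in self.exon_lengths()[:-1]:
            acc += length
            out.append(acc)
        return out

    def exon_of_cds_position(self, pos: int) -> int:
        """1-based exon ordinal containing a CDS coordinate."""
        acc = 0
        for k, length in enumerate(self.exon_lengths(), start=1):
            if pos < acc + length:
                return k
            acc += length
        return len(self.exons)


@dataclass
class GenomeOrigin:
    gene_id: str
    origin: str  # "A", "D" or "ambiguous"
    dist_a: float
    dist_d: float

    @property
    def margin(self) -> float:
        return abs(self.dist_a - self.dist_d)


@dataclass
class Indel:
    position: int  # CDS coordinate on the first sequence
    position_other: int  # CDS coordinate on the second sequence
    length: int
    deleted_in: str  # "a" or "b": which sequence lacks the bases
    in_frame: bool
    exon: int | None = None  # 1-based ordinal on the first gene's model

    def __post_init__(self) -> None:
        assert self.in_frame == (self.length % 3 == 0)


@dataclass
class SSRDifference:
    unit: str
    copies_a: int
    copies_b: int
    exon: int | None = None

    @property
    def length_difference_nt(self) -> int:
        return (self.copies_a - self.copies_b) * len(self.unit)


@dataclass
class InsertionRecord:
    host: str  # "a" or "b": sequence carrying the insertion
    start: int  # position within the host intron, 0-based
    length: int
    intron: int | None = None  # 1-based ordinal
    terminal_repeat: tuple[int, float] | None = None  # (length, identity)

    @property
    def is_ltr_like(self) -> bool:
        return self.terminal_repeat is not None


@dataclass
class VariantReport:
    gene_a: str
    gene_b: str
    indels: list[Indel] = field(default_factory=list)
    ssr: list[SSRDifference] = field(default_factory=list)
    insertions: list[InsertionRecord] = field(default_factory=list)


# ---------------------------------------------------------------------------
# spliced CDS-to-genome mapping
# ---------------------------------------------------------------------------


def map_cds_to_genome(
    cds: str,
    genomic: str,
    min_intron: int = 40,
    relax_splice: bool = False,
    gene_id: str = "gene",
) -> GeneModel:
    """Chain exact exon matches of the CDS onto the genomic sequence.

    The exon chain must be collinear, cover the entire CDS, and every
    intron must start GT, end AG (unless ``relax_splice``) and be at least
    ``min_intron`` long. Among exact-coverage chains the one with the
    fewest introns wins (iterative deepening on intron count), and within
    that the longest leftmost exon extension — deterministic results.
    """
    if len(cds) < 30:
        raise ValueError("CDS shorter than 30 nt")
    n, m = len(cds), len(genomic)
    best_partial: list[tuple[int, list[tuple[int, int]]]] = [(0, [])]

    def donor_ok(d: int) -> bool:
        return relax_splice or genomic[d : d + 2] == "GT"

    def acceptor_ok(a: int) -> bool:
        return relax_splice or genomic[a - 2 : a] == "AG"

    def search(c: int, g: int, exons: list[tuple[int, int]], budget: int, failed: set):
        entry = (c, g, budget)
        if entry in failed:
            return None
        start_g = g
        donors: list[tuple[int, int]] = []  # (genomic pos, cds pos)
        while c < n and g < m and genomic[g] == cds[c]:
            c += 1
            g += 1
            if donor_ok(g):
                donors.append((g, c))
        if c > best_partial[0][0]:
            best_partial[0:] = [(c, exons + [(start_g, g)])]
        if c == n:
            return exons + [(start_g, g)]
        if budget > 0:
            # prefer the latest (longest-exon) donor first
            for d, cd in reversed(donors):
                if d == start_g:
                    continue  # empty exon
                a = d + min_intron
                while a <= m - (n - cd):
                    if acceptor_ok(a) and genomic[a] == cds[cd]:
                        res = search(cd, a, exons + [(start_g, d)], budget - 1, failed)
                        if res is not None:
                            return res
                    a += 1
        failed.add(entry)
        return None

    # candidate start offsets: occurrences of a short CDS prefix seed
    seed = cds[: min(12, n)]
    starts = []
    p = genomic.find(seed)
    while p != -1:
        starts.append(p)
        p = genomic.find(seed, p + 1)
    max_introns = min(30, m // max(min_intron, 1))
    for budget in range(0, max_introns + 1):
        failed: set = set()
        for start in starts:
            res = search(0, start, [], budget, failed)
            if res is not None:
                return GeneModel(
                    gene_id=gene_id,
                    genomic=genomic,
                    exons=res,
                    min_intron=min_intron,
                    check_splice=not relax_splice,
                )
    covered, exons = best_partial[0]
    raise ValueError(
        f"no full-coverage exon chain for {gene_id}: best partial covers "
        f"{covered}/{n} CDS bases with exons {exons}"
    )


# ---------------------------------------------------------------------------
# genome-of-origin assignment
# ---------------------------------------------------------------------------


def _aligned_pdistance(a: str, b: str, moltype: str) -> float:
    row_a, row_b, _ = global_align(a, b, moltype=moltype)
    total = mism = 0
    for x, y in zip(row_a, row_b):
        if x == "-" or y == "-":
            continue
        total += 1
        if x != y:
            mism += 1
    if total == 0:
        raise ValueError("sequences share no aligned columns")
    return mism / total


def assign_genome_origin(
    query: str,
    ortholog_a: str,
    ortholog_d: str,
    moltype: str = "dna",
    gene_id: str = "query",
    ambiguity_margin: float = 0.005,
) -> GenomeOrigin:
    """Origin = genome of the closer diploid ortholog (p-distance).

    A margin below ``ambiguity_margin`` yields "ambiguous" rather than an
    arbitrary pick.
    """
    da = _aligned_pdistance(query, ortholog_a, moltype)
    dd = _aligned_pdistance(query, ortholog_d, moltype)
    if abs(da - dd) < ambiguity_margin:
        origin = "ambiguous"
    else:
        origin = "A" if da < dd else "D"
    return GenomeOrigin(gene_id=gene_id, origin=origin, dist_a=da, dist_d=dd)


# ---------------------------------------------------------------------------
# indels
# ---------------------------------------------------------------------------


def detect_indels(
    cds_a: str, cds_b: str, model_a: GeneModel | None = None
) -> list[Indel]:
    """Maximal gap runs in the global nucleotide alignment of two CDSs.

    Coordinates are reported on both sequences' CDS rulers; the exon
    ordinal refers to the first gene's model when provided.
    """
    if cds_a == cds_b:
        return []
    row_a, row_b, _ = global_align(cds_a, cds_b, moltype="dna")
    out: list[Indel] = []
    pos_a = pos_b = 0
    i = 0
    L = len(row_a)
    while i < L:
        if row_a[i] == "-" or row_b[i] == "-":
            gap_in_a = row_a[i] == "-"
            start_a, start_b = pos_a, pos_b
            length = 0
            while i < L and (row_a[i] == "-") == gap_in_a and (
                row_a[i] == "-" or row_b[i] == "-"
            ):
                if gap_in_a:
                    pos_b += 1
                else:
                    pos_a += 1
                length += 1
                i += 1
            exon = None
            if model_a is not None:
                exon = model_a.exon_of_cds_position(max(start_a - 1, 0) if gap_in_a else start_a)
            out.append(
                Indel(
                    position=start_a,
                    position_other=start_b,
                    length=length,
                    deleted_in="a" if gap_in_a else "b",
                    in_frame=length % 3 == 0,
                    exon=exon,
                )
            )
        else:
            pos_a += 1
            pos_b += 1
            i += 1
    return out


# ---------------------------------------------------------------------------
# SSR tracts
# ---------------------------------------------------------------------------


def find_ssr(seq: str, unit: str, min_copies: int = 4) -> list[tuple[int, int]]:
    """Maximal perfect tandem runs of ``unit``: list of (start, copies)."""
    if not unit:
        raise ValueError("empty SSR unit")
    k = len(unit)
    out: list[tuple[int, int]] = []
    i = 0
    n = len(seq)
    while i + k <= n:
        if seq[i : i + k] == unit:
            j = i
            while j + k <= n and seq[j : j + k] == unit:
                j += k
            copies = (j - i) // k
            # maximality: not an interior phase of a longer run
            if (i < k or seq[i - k : i] != unit) and copies >= min_copies:
                out.append((i, copies))
            i = j
        else:
            i += 1
    return out


def ssr_difference(
    seq_a: str, seq_b: str, unit: str, min_copies: int = 4
) -> SSRDifference | None:
    """Copy-number difference of the longest run of ``unit`` in each sequence."""
    runs_a = find_ssr(seq_a, unit, min_copies=1)
    runs_b = find_ssr(seq_b, unit, min_copies=1)
    ca = max((c for _, c in runs_a), default=0)
    cb = max((c for _, c in runs_b), default=0)
    if max(ca, cb) < min_copies:
        return None
    return SSRDifference(unit=unit, copies_a=ca, copies_b=cb)


# ---------------------------------------------------------------------------
# LTR-like insertions
# ---------------------------------------------------------------------------


def _best_terminal_repeat(segment: str, min_len: int) -> tuple[int, float] | None:
    arr = np.frombuffer(segment.encode(), dtype=np.uint8)
    D = len(arr)
    best: tuple[float, int] | None = None
    for L in range(min_len, D // 2 + 1):
        identity = float((arr[:L] == arr[D - L :]).mean())
        if best is None or (identity, L) > best:
            best = (identity, L)
    if best is None:
        return None
    return best[1], best[0]


def detect_ltr_insertion(
    intron_a: str,
    intron_b: str,
    min_insertion: int = 500,
    min_tr_len: int = 100,
    min_tr_identity: float = 0.85,
) -> InsertionRecord | None:
    """Find a large insertion in one of two orthologous introns.

    A length difference of at least ``min_insertion`` is modelled as one
    insertion event: the split point minimising flank mismatches locates
    it. The placement is ambiguous up to shifts where flanking bases
    repeat; among the equivalent placements the one maximising direct
    terminal-repeat identity is kept, and a repeat pair of at least
    ``min_tr_len`` at identity >= ``min_tr_identity`` marks the insertion
    as LTR-retrotransposon-like.
    """
    if intron_a == intron_b:
        return None
    D = len(intron_b) - len(intron_a)
    if abs(D) < min_insertion:
        return None
    # single-insertion split model: the shorter intron's prefix aligns to
    # the longer one's prefix and its suffix to the longer one's suffix;
    # the split point minimising total flank mismatches places the insert.
    # Substitution-level flank divergence is tolerated exactly.
    host_name = "b" if D > 0 else "a"
    host = intron_b if D > 0 else intron_a
    short = intron_a if D > 0 else intron_b
    D = abs(D)
    s_arr = np.frombuffer(short.encode(), dtype=np.uint8)
    h_arr = np.frombuffer(host.encode(), dtype=np.uint8)
    n = len(s_arr)
    prefix = np.concatenate(([0], np.cumsum(s_arr != h_arr[:n])))
    suffix = np.concatenate(([0], np.cumsum(s_arr[::-1] != h_arr[len(h_arr) - n:][::-1])))
    totals = prefix[np.arange(n + 1)] + suffix[n - np.arange(n + 1)]
    start = int(np.argmin(totals))
    # equivalence range of placements (rotation where flanks repeat)
    left = start
    while left > 0 and host[left - 1] == host[left - 1 + D]:
        left -= 1
    right = start
    while right + D < len(host) and host[right] == host[right + D]:
        right += 1
    placements = range(left, min(right, left + 100) + 1)
    best_place = start
    best_tr: tuple[int, float] | None = None
    for p in placements:
        tr = _best_terminal_repeat(host[p : p + D], min_tr_len)
        if tr is not None and (best_tr is None or (tr[1], tr[0]) > (best_tr[1], best_tr[0])):
            best_tr = tr
            best_place = p
    if best_tr is not None and best_tr[1] < min_tr_identity:
        best_tr = None
    return InsertionRecord(
        host=host_name, start=best_place, length=D, terminal_repeat=best_tr
    )


# ---------------------------------------------------------------------------
# structure comparison
# ---------------------------------------------------------------------------


def compare_structures(
    models: list[GeneModel], junction_tolerance: int = 10
) -> dict:
    """Cross-ortholog exon/intron structure diff.

    Junction positions (cumulative CDS coordinates of intron sites) are
    clustered across genes with a small tolerance; introns present in some
    orthologs but absent in others are reported as lost, keyed by the
    1-based consensus intron ordinal.
    """
    if len(models) < 2:
        raise ValueError("need at least two gene models to compare")
    all_junctions: list[int] = []
    for m in models:
        all_junctions.extend(m.junctions())
    consensus: list[int] = []
    for j in sorted(all_junctions):
        if not consensus or j - consensus[-1] > junction_tolerance:
            consensus.append(j)
    presence: dict[str, list[bool]] = {}
    for m in models:
        js = m.junctions()
        presence[m.gene_id] = [
            any(abs(j - c) <= junction_tolerance for j in js) for c in consensus
        ]
    lost: dict[int, list[str]] = {}
    for idx in range(len(consensus)):
        absent = [g for g, pres in presence.items() if not pres[idx]]
        if absent and len(absent) < len(models):
            lost[idx + 1] = sorted(absent)
    return {
        "exon_counts": {m.gene_id: len(m.exons) for m in models},
        "exon_lengths": {m.gene_id: m.exon_lengths() for m in models},
        "consensus_junctions": consensus,
        "lost_introns": lost,
    }


def compare_pair(
    model_a: GeneModel,
    model_b: GeneModel,
    ssr_unit: str = "GAA",
    min_copies: int = 4,
    **ltr_kwargs,
) -> VariantReport:
    """Full variant report between two orthologous gene models."""
    report = VariantReport(gene_a=model_a.gene_id, gene_b=model_b.gene_id)
    report.indels = detect_indels(model_a.cds, model_b.cds, model_a)
    # SSR per exon pair (matched by ordinal)
    for k in range(min(len(model_a.exons), len(model_b.exons))):
        sa, ea = model_a.exons[k]
        sb, eb = model_b.exons[k]
        diff = ssr_difference(
            model_a.genomic[sa:ea], model_b.genomic[sb:eb], ssr_unit, min_copies
        )
        if diff is not None and diff.copies_a != diff.copies_b:
            diff.exon = k + 1
            report.ssr.append(diff)
    # insertions per intron pair
    if len(model_a.exons) == len(model_b.exons):
        for k in range(1, len(model_a.exons)):
            rec = detect_ltr_insertion(
                model_a.intron_seq(k), model_b.intron_seq(k), **ltr_kwargs
            )
            if rec is not None:
                rec.intron = k
                report.insertions.append(rec)
    return report
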