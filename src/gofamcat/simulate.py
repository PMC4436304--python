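"""Synthetic families, genes, variants and Ct tables with planted truth.

Every pipeline stage can be exercised offline against fixtures whose
ground truth is known exactly: subfamily-structured protein families whose
pairwise divergences respect the allele (<0.03), ortholog (0.03–0.15) and
paralog (>0.15) branch-length bands; multi-source FASTA sets with dropout
(no sequencing project annotates every gene); exon/intron gene structures
with planted in-frame deletions, SSR copy-number differences and
terminal-repeat-flanked insertions; and Ct tables with two reference genes
and technical replicates. All randomness flows through explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .domains import ConsensusProfile
from .expression import CtTable, DEFAULT_REFERENCES
from .probes import ProbeSet
from .seqio import SequenceRecord, Source
from .variants import GeneModel

__all__ = [
    "FamilyTruth",
    "VariantTruth",
    "mutate",
    "make_family",
    "emulate_sources",
    "make_proteome",
    "make_gene",
    "plant_variants",
    "simulate_ct",
]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_DNA4 = "ACGT"

DEFAULT_SUBFAMILIES = ("S5a", "S5b", "S9", "S13", "S15", "S18")


@dataclass
class FamilyTruth:
    """Planted ground truth for a synthetic protein family."""

    gene_of: dict[str, str]  # record id -> true gene id
    subfamily_of: dict[str, str]  # gene id -> subfamily name
    genome_of: dict[str, str]  # record id -> "A" or "D"
    domain_span: dict[str, tuple[int, int]]  # record id -> domain span
    founder_domain: dict[str, str]  # subfamily -> anchor/probe domain
    dropout: dict[str, list[str]] = field(default_factory=dict)  # source -> dropped genes

    def genes(self) -> list[str]:
        return sorted(set(self.gene_of.values()))

    def relationship(self, a: str, b: str) -> str:
        if self.gene_of[a] == self.gene_of[b]:
            return "allele" if self.genome_of[a] == self.genome_of[b] else "ortholog"
        return "paralog"

    def partition(self, ids: list[str]) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for rid in ids:
            out.setdefault(self.gene_of[rid], []).append(rid)
        return out


@dataclass
class VariantTruth:
    """Planted variant features for an ortholog gene pair."""

    deletion: tuple[int, int, int] | None = None  # (exon 1-based, offset, length)
    ssr: tuple[str, int, int, int] | None = None  # (unit, copies_a, copies_b, exon)
    insertion: tuple[int, int, int] | None = None  # (intron 1-based, length, tr_len)


def _rand_seq(rng: np.random.Generator, n: int, alphabet: str) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=n))


def mutate(
    seq: str,
    rate: float,
    seed: int | np.random.Generator,
    moltype: str = "protein",
    protect: set[int] | None = None,
) -> str:
    """I.i.d. substitutions at the per-site rate, uniform over alternatives."""
    if not (0 <= rate < 1):
        raise ValueError("rate must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    alphabet = _AA20 if moltype == "protein" else _DNA4
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        if protect and int(i) in protect:
            continue
        alternatives = alphabet.replace(out[i], "") if out[i] in alphabet else alphabet
        out[i] = alternatives[rng.integers(0, len(alternatives))]
    return "".join(out)


def _rate_for_pairwise(q: float, n_states: int = 20) -> float:
    """Per-copy substitution rate giving expected pairwise p-distance q.

    Two copies mutated independently from one ancestor at rate r differ at
    a site with probability ~ 2r - r^2 * n/(n-1); invert for r.
    """
    a = n_states / (n_states - 1)
    disc = 1 - a * q
    if disc <= 0:
        raise ValueError(f"pairwise divergence {q} unreachable")
    return (1 - np.sqrt(disc)) / a


def make_family(
    n_subfam: int = 6,
    genes_per_subfam: int = 4,
    allele_div: float = 0.01,
    ortholog_div: float = 0.08,
    paralog_div: float = 0.4,
    profile: ConsensusProfile | None = None,
    seed: int = 0,
    protein_length: int = 250,
    subfamily_names: tuple[str, ...] = DEFAULT_SUBFAMILIES,
    check_bands: bool = True,
) -> tuple[list[SequenceRecord], FamilyTruth]:
    """Generate a subfamily-structured family with planted relationships.

    Each gene carries an A-genome copy, a D-genome copy (ortholog band) and
    an allele copy of A (allele band); genes within a subfamily are
    paralogs. Consensus domain columns are shielded from paralog-level
    divergence so every planted domain remains a valid bHLH. Realised
    divergences are verified post hoc against the requested bands.
    """
    if not (allele_div < 0.03 < ortholog_div < 0.15 < paralog_div):
        raise ValueError(
            "divergence bands must satisfy allele < 0.03 < ortholog < 0.15 < paralog"
        )
    profile = profile or ConsensusProfile.default()
    rng = np.random.default_rng(seed)
    if n_subfam > len(subfamily_names):
        subfamily_names = tuple(
            list(subfamily_names) + [f"S{90 + i}" for i in range(n_subfam)]
        )
    ncols = profile.ncols
    n_flank = (protein_length - ncols) // 2
    c_flank = protein_length - ncols - n_flank
    domain_start = n_flank
    consensus_abs = {domain_start + c for c in profile.consensus_columns}
    variable_domain = [c for c in range(ncols) if c not in profile.consensus]

    records: list[SequenceRecord] = []
    gene_of: dict[str, str] = {}
    subfamily_of: dict[str, str] = {}
    genome_of: dict[str, str] = {}
    domain_span: dict[str, tuple[int, int]] = {}
    founder_domain: dict[str, str] = {}

    n_sites = protein_length
    unprotected = n_sites - len(consensus_abs)
    scale = n_sites / unprotected
    r_paralog = _rate_for_pairwise(min(paralog_div * scale, 0.92))
    r_ortholog = _rate_for_pairwise(ortholog_div * scale)
    r_allele = allele_div * scale  # one copy mutated from the other

    for s in range(n_subfam):
        name = subfamily_names[s]
        # subfamily signature: distinct variable-column residues and flanks
        domain = list(profile.representative)
        for c in variable_domain:
            if rng.random() < 0.5:
                domain[c] = _AA20[rng.integers(0, 20)]
        domain = "".join(domain)
        founder_domain[name] = domain
        subfam_founder = (
            _rand_seq(rng, n_flank, _AA20) + domain + _rand_seq(rng, c_flank, _AA20)
        )
        for g in range(genes_per_subfam):
            gene = f"{name}g{g + 1}"
            subfamily_of[gene] = name
            base = mutate(
                subfam_founder, r_paralog, rng, protect=consensus_abs
            )
            copy_a = mutate(base, r_ortholog, rng, protect=consensus_abs)
            copy_d = mutate(base, r_ortholog, rng, protect=consensus_abs)
            copy_aa = mutate(copy_a, r_allele, rng, protect=consensus_abs)
            for label, seq, genome in (
                ("A", copy_a, "A"),
                ("D", copy_d, "D"),
                ("Aa", copy_aa, "A"),
            ):
                rid = f"{gene}_{label}"
                records.append(
                    SequenceRecord(id=rid, residues=seq, moltype="protein")
                )
                gene_of[rid] = gene
                genome_of[rid] = genome
                domain_span[rid] = (domain_start, domain_start + ncols)

    truth = FamilyTruth(
        gene_of=gene_of,
        subfamily_of=subfamily_of,
        genome_of=genome_of,
        domain_span=domain_span,
        founder_domain=founder_domain,
    )
    if check_bands:
        _verify_bands(records, truth, allele_div, ortholog_div, paralog_div)
    return records, truth


def _hamming_p(a: str, b: str) -> float:
    return sum(x != y for x, y in zip(a, b)) / len(a)


def _verify_bands(records, truth, allele_div, ortholog_div, paralog_div) -> None:
    by_id = {r.id: r.residues for r in records}
    sums = {"allele": [], "ortholog": [], "paralog": []}
    ids = sorted(by_id)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            rel = truth.relationship(a, b)
            if rel == "paralog" and truth.subfamily_of[truth.gene_of[a]] != truth.subfamily_of[truth.gene_of[b]]:
                continue  # cross-subfamily pairs exceed the paralog target by design
            sums[rel].append(_hamming_p(by_id[a], by_id[b]))
    targets = {"allele": allele_div, "ortholog": ortholog_div, "paralog": paralog_div}
    length = len(records[0].residues)
    for rel, target in targets.items():
        if not sums[rel]:
            continue
        mean = float(np.mean(sums[rel]))
        # ±30% of the target, widened to 3 standard errors of the mean for
        # small families where binomial noise dominates
        se = np.sqrt(target * (1 - target) / (length * len(sums[rel])))
        tol = max(0.3 * target, 3 * se)
        if rel == "paralog":
            if mean < target - tol:
                raise ValueError(
                    f"realised mean {rel} divergence {mean:.3f} below band for target {target}"
                )
        elif abs(mean - target) > tol:
            raise ValueError(
                f"realised mean {rel} divergence {mean:.3f} outside tolerance of {target}"
            )
    # hard sanity for the grouping threshold: within-gene pairs must stay
    # below the ortholog cut, cross-gene pairs above it
    within = sums["allele"] + sums["ortholog"]
    if within and max(within) > 0.15:
        raise ValueError("a within-gene pair exceeded the ortholog threshold")
    if sums["paralog"] and min(sums["paralog"]) <= 0.15:
        raise ValueError("a paralog pair fell inside the ortholog band")


_SOURCE_COPY = {
    Source.GrJGI: "D",
    Source.GrCGP: "D",
    Source.GaCGP: "A",
    Source.GhUni: "Aa",
    Source.GoCon: "any",
    Source.mRNA: "any",
}


def emulate_sources(
    records: list[SequenceRecord],
    truth: FamilyTruth,
    dropout: float = 0.1,
    seed: int = 0,
    sources: tuple[Source, ...] = (
        Source.GrJGI,
        Source.GrCGP,
        Source.GaCGP,
        Source.GhUni,
        Source.GoCon,
        Source.mRNA,
    ),
) -> dict[Source, list[SequenceRecord]]:
    """Distribute gene copies over annotation sources with dropout.

    The two *G. raimondii* projects both see the D copy (their shared genes
    land in the allele band), the *G. arboreum* project sees the A copy,
    and transcript-derived sources draw either genome. Each gene is kept in
    at least one source (masks are redrawn otherwise). Emitted record ids
    are suffixed ``@source`` and registered in the truth tables.
    """
    if not (0 <= dropout < 1):
        raise ValueError("dropout must be in [0, 1)")
    rng = np.random.default_rng(seed)
    by_copy: dict[tuple[str, str], SequenceRecord] = {}
    for rec in records:
        gene = truth.gene_of[rec.id]
        label = rec.id.rsplit("_", 1)[1]
        by_copy[(gene, label)] = rec
    genes = truth.genes()
    for _attempt in range(1000):
        mask = rng.random((len(sources), len(genes))) >= dropout
        if mask.any(axis=0).all():
            break
    else:
        raise RuntimeError("could not satisfy every-gene-covered constraint")
    out: dict[Source, list[SequenceRecord]] = {}
    for si, src in enumerate(sources):
        kept: list[SequenceRecord] = []
        dropped: list[str] = []
        for gi, gene in enumerate(genes):
            if not mask[si, gi]:
                dropped.append(gene)
                continue
            want = _SOURCE_COPY.get(src, "any")
            if want == "any":
                want = ("A", "D")[rng.integers(0, 2)]
            rec = by_copy.get((gene, want)) or by_copy.get((gene, "A"))
            new_id = f"{rec.id}@{src.value}"
            kept.append(
                SequenceRecord(
                    id=new_id,
                    residues=rec.residues,
                    moltype="protein",
                    source=src,
                    description=f"copy_of:{rec.id}",
                )
            )
            truth.gene_of[new_id] = gene
            truth.genome_of[new_id] = truth.genome_of[rec.id]
            truth.domain_span[new_id] = truth.domain_span[rec.id]
        truth.dropout[src.value] = dropped
        out[src] = kept
    return out


def make_proteome(
    n_proteins: int = 50,
    n_planted: int = 12,
    seed: int = 0,
    profile: ConsensusProfile | None = None,
    mutation_rate: float = 0.0,
) -> tuple[list[SequenceRecord], dict[str, tuple[int, int]], ProbeSet]:
    """Random proteome with domains planted at known spans, plus probes."""
    if n_planted > n_proteins:
        raise ValueError("cannot plant more domains than proteins")
    profile = profile or ConsensusProfile.default()
    rng = np.random.default_rng(seed)
    n_probes = max(4, min(8, n_planted))
    variable = [c for c in range(profile.ncols) if c not in profile.consensus]
    probes: list[SequenceRecord] = []
    for k in range(n_probes):
        domain = list(profile.representative)
        for c in variable:
            if rng.random() < 0.5:
                domain[c] = _AA20[rng.integers(0, 20)]
        probes.append(
            SequenceRecord(id=f"probe{k + 1}", residues="".join(domain))
        )
    probe_set = ProbeSet(
        records=probes,
        subfamily={p.id: f"S{k + 1}" for k, p in enumerate(probes)},
    )
    planted_idx = set(rng.choice(n_proteins, size=n_planted, replace=False).tolist())
    proteome: list[SequenceRecord] = []
    spans: dict[str, tuple[int, int]] = {}
    for i in range(n_proteins):
        length = int(rng.integers(150, 300))
        seq = _rand_seq(rng, length, _AA20)
        pid = f"prot{i + 1:03d}"
        if i in planted_idx:
            probe = probes[int(rng.integers(0, n_probes))]
            domain = mutate(probe.residues, mutation_rate, rng) if mutation_rate else probe.residues
            start = int(rng.integers(10, length - len(domain) - 10))
            seq = seq[:start] + domain + seq[start + len(domain):]
            spans[pid] = (start, start + len(domain))
        proteome.append(SequenceRecord(id=pid, residues=seq))
    return proteome, spans, probe_set


# ---------------------------------------------------------------------------
# gene structures and variants
# ---------------------------------------------------------------------------


def make_gene(
    cds_length: int = 630,
    n_introns: int = 6,
    intron_lengths: list[int] | None = None,
    seed: int = 0,
    min_intron: int = 40,
    min_exon: int = 30,
    gene_id: str = "gene",
) -> GeneModel:
    """Random gene with GT..AG introns at unambiguous exon boundaries."""
    rng = np.random.default_rng(seed)
    if intron_lengths is None:
        intron_lengths = [int(rng.integers(80, 301)) for _ in range(n_introns)]
    if len(intron_lengths) != n_introns:
        raise ValueError("intron_lengths length != n_introns")
    for L in intron_lengths:
        if L < min_intron:
            raise ValueError(f"intron length {L} below minimum {min_intron}")
    if cds_length < (n_introns + 1) * min_exon:
        raise ValueError("CDS too short for the requested exon count")
    cds = _rand_seq(rng, cds_length, _DNA4)
    # junction positions: roughly evenly spaced with jitter, and cds[j] != 'G'
    # so the exon/intron boundary cannot slide into the GT donor
    positions: list[int] = []
    for k in range(1, n_introns + 1):
        target = round(k * cds_length / (n_introns + 1)) + int(rng.integers(-10, 11))
        target = min(max(target, min_exon), cds_length - min_exon)
        for delta in range(cds_length):
            for j in (target + delta, target - delta):
                if (
                    min_exon <= j <= cds_length - min_exon
                    and cds[j] != "G"
                    and all(abs(j - p) >= min_exon for p in positions)
                ):
                    positions.append(j)
                    break
            else:
                continue
            break
        else:
            raise RuntimeError("could not place introns; relax constraints")
    positions.sort()
    segments: list[str] = []
    exons: list[tuple[int, int]] = []
    prev = 0
    offset = 0
    for j, L in zip(positions, intron_lengths):
        exon = cds[prev:j]
        segments.append(exon)
        exons.append((offset, offset + len(exon)))
        offset += len(exon)
        intron = "GT" + _rand_seq(rng, L - 4, _DNA4) + "AG"
        segments.append(intron)
        offset += len(intron)
        prev = j
    segments.append(cds[prev:])
    exons.append((offset, offset + cds_length - prev))
    genomic = "".join(segments)
    return GeneModel(
        gene_id=gene_id, genomic=genomic, exons=exons, min_intron=min_intron
    )


def _segments(model: GeneModel) -> tuple[list[str], list[str]]:
    exon_seqs = [model.genomic[s:e] for s, e in model.exons]
    intron_seqs = [model.genomic[s:e] for s, e in model.introns]
    return exon_seqs, intron_seqs


def _assemble(gene_id: str, exon_seqs: list[str], intron_seqs: list[str], min_intron: int) -> GeneModel:
    parts: list[str] = []
    exons: list[tuple[int, int]] = []
    offset = 0
    for k, ex in enumerate(exon_seqs):
        parts.append(ex)
        exons.append((offset, offset + len(ex)))
        offset += len(ex)
        if k < len(intron_seqs):
            parts.append(intron_seqs[k])
            offset += len(intron_seqs[k])
    return GeneModel(
        gene_id=gene_id, genomic="".join(parts), exons=exons, min_intron=min_intron
    )


def _safe_insertion_offset(
    exon: str, insert: str, rng: np.random.Generator, margin: int = 5
) -> int:
    """Offset such that the inserted block's boundaries cannot slide."""
    for _ in range(200):
        off = int(rng.integers(margin, len(exon) - margin))
        left_ok = insert[-1] != exon[off] if insert else True
        right_ok = insert[0] != exon[off - 1] if insert else True
        if left_ok and right_ok:
            return off
    return len(exon) // 2


def plant_variants(
    model: GeneModel,
    spec: VariantTruth,
    seed: int = 0,
    divergence: float = 0.005,
) -> tuple[GeneModel, GeneModel, VariantTruth]:
    """Derive an ortholog pair (A, B) from one gene, planting variants in B.

    The SSR tract is written into both copies (with different copy
    numbers); the deletion and the terminal-repeat-flanked insertion go
    into B only. Background substitutions at ``divergence`` are applied to
    B outside all planted windows and splice sites, so planted features
    stay byte-exact.
    """
    rng = np.random.default_rng(seed)
    exons_a, introns_a = _segments(model)
    exons_a, introns_a = list(exons_a), list(introns_a)
    exons_b = list(exons_a)
    introns_b = list(introns_a)
    protected_a: dict[int, set[int]] = {}
    protected_b: dict[int, set[int]] = {}

    ssr_window: tuple[int, int, int, int] | None = None  # (exon idx, off, len_a, len_b)
    if spec.ssr is not None:
        unit, copies_a, copies_b, exon_no = spec.ssr
        k = exon_no - 1
        if k >= len(exons_a):
            raise ValueError(f"SSR exon {exon_no} out of range")
        exon = exons_a[k]
        run_a, run_b = unit * copies_a, unit * copies_b
        off = _safe_insertion_offset(exon, run_a, rng)
        # flanks must not extend the repeat run
        while exon[max(0, off - len(unit)):off] == unit or exon[off:off + len(unit)] == unit:
            off += 1
        exons_a[k] = exon[:off] + run_a + exon[off:]
        exons_b[k] = exon[:off] + run_b + exon[off:]
        ssr_window = (k, off, len(run_a), len(run_b))
        protected_a.setdefault(k, set()).update(range(off - 3, off + len(run_a) + 3))
        protected_b.setdefault(k, set()).update(range(off - 3, off + len(run_b) + 3))

    if spec.deletion is not None:
        exon_no, offset, length = spec.deletion
        k = exon_no - 1
        exon = exons_b[k]
        if length >= len(exon) - 2:
            raise ValueError("deletion does not fit in exon")
        # candidate sites: scan forward from the requested offset, wrapping
        # around. The block must sit well clear (>= 15 nt) of other planted
        # features so the aligner cannot merge adjacent gap runs, and its
        # boundaries must not slide in the alignment.
        protected = protected_b.get(k, set())
        candidates = list(range(max(offset, 1), len(exon) - length - 1)) + list(
            range(1, max(offset, 1))
        )
        for cand in candidates:
            block = set(range(cand - 15, cand + length + 15))
            if protected & block:
                continue
            if exon[cand] != exon[cand + length] and exon[cand - 1] != exon[cand + length - 1]:
                offset = cand
                break
        else:
            raise ValueError("no unambiguous deletion site in exon")
        exons_b[k] = exon[:offset] + exon[offset + length:]
        # shift existing protected coordinates past the deleted block
        if protected:
            protected_b[k] = {
                p if p < offset else p - length for p in protected if not (offset <= p < offset + length)
            }
        # record the offset on the A-copy ruler (the copy keeping the bases)
        a_offset = offset
        if ssr_window is not None and ssr_window[0] == k and offset > ssr_window[1]:
            a_offset = offset - (ssr_window[3] - ssr_window[2])
        spec = VariantTruth(
            deletion=(exon_no, a_offset, length), ssr=spec.ssr, insertion=spec.insertion
        )
        protected_b.setdefault(k, set()).update(range(offset - 3, offset + 3))
        protected_a.setdefault(k, set()).update(range(a_offset - 3, a_offset + length + 3))

    ins_window: tuple[int, int, int] | None = None  # (intron idx, start, end)
    if spec.insertion is not None:
        intron_no, length, tr_len = spec.insertion
        j = intron_no - 1
        if j >= len(introns_b):
            raise ValueError(f"intron {intron_no} out of range")
        if length < 2 * tr_len:
            raise ValueError("insertion shorter than two terminal repeats")
        tr = _rand_seq(rng, tr_len, _DNA4)
        element = tr + _rand_seq(rng, length - 2 * tr_len, _DNA4) + tr
        intron = introns_b[j]
        off = _safe_insertion_offset(intron, element, rng, margin=10)
        introns_b[j] = intron[:off] + element + intron[off:]
        ins_window = (j, off, off + length)

    # background divergence in B outside planted windows and splice motifs
    if divergence > 0:
        for k, exon in enumerate(exons_b):
            protect = protected_b.get(k, set())
            exons_b[k] = mutate(exon, divergence, rng, moltype="dna", protect=protect)
        for j, intron in enumerate(introns_b):
            protect = set(range(0, 2)) | set(range(len(intron) - 2, len(intron)))
            if ins_window is not None and ins_window[0] == j:
                protect |= set(range(ins_window[1] - 3, ins_window[2] + 3))
            introns_b[j] = mutate(intron, divergence, rng, moltype="dna", protect=protect)

    model_a = _assemble(model.gene_id + "_A", exons_a, introns_a, model.min_intron)
    model_b = _assemble(model.gene_id + "_B", exons_b, introns_b, model.min_intron)
    return model_a, model_b, spec


# ---------------------------------------------------------------------------
# Ct tables
# ---------------------------------------------------------------------------


def simulate_ct(
    levels: pd.DataFrame,
    ref_ct: float = 20.0,
    noise_sd: float = 0.15,
    replicates: int = 3,
    seed: int = 0,
    references: tuple[str, ...] = DEFAULT_REFERENCES,
) -> CtTable:
    """Ct table from a genes x samples matrix of true relative levels.

    Ct(g, s, r) = ref_ct - log2(level) + N(0, noise_sd); NaN levels become
    undetected replicates. Both reference genes receive the same jitter
    model around ``ref_ct``.
    """
    if (levels.fillna(1) < 0).any().any():
        raise ValueError("levels must be >= 0 or NaN (undetectable)")
    rng = np.random.default_rng(seed)
    rows = []
    for sample in levels.columns:
        for r in range(1, replicates + 1):
            for ref in references:
                rows.append((ref, sample, r, ref_ct + rng.normal(0, noise_sd)))
            for gene in levels.index:
                level = levels.loc[gene, sample]
                if pd.isna(level) or level <= 0:
                    rows.append((gene, sample, r, np.nan))
                else:
                    ct = ref_ct - np.log2(level) + rng.normal(0, noise_sd)
                    rows.append((gene, sample, r, ct))
    df = pd.DataFrame(rows, columns=["gene", "sample", "replicate", "ct"])
    return CtTable(data=df, references=references)
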