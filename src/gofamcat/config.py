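"""Pipeline configuration and the end-to-end runner.

One YAML config drives every stage (probe search -> domain validation ->
reference building -> classification, plus optional expression). All
numeric thresholds live here with their documented defaults: the allele /
ortholog branch-length cuts (0.03 / 0.15), the consensus-residue fraction
(>0.60), the NJ bootstrap support cut (>88) with 1000 replicates, and the
local-search score floor. Seeds are mandatory — a config without a seed is
an error, never a silent clock seed. Every run writes a manifest with the
resolved config and output checksums so reruns are verifiable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .align import align_progressive
from .domains import ConsensusProfile, validate_domain
from .phylo import bootstrap_support, call_subfamilies, ml_tree_poisson, mp_tree
from .probes import ProbeSet, search_proteome
from .reference import (
    assign_codes,
    build_guide_tree,
    collapse_identical_tandem,
    group_by_thresholds,
    overlap_matrix,
    select_representative,
)
from .seqio import SequenceRecord, Source, read_fasta, write_fasta

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class Thresholds:
    allele: float = 0.03
    ortholog: float = 0.15
    consensus_fraction: float = 0.60
    min_support: float = 88.0
    bootstrap_reps: int = 1000
    min_score: float = 60.0
    min_intron: int = 40
    min_tr_len: int = 100
    min_tr_identity: float = 0.85

    def validate(self) -> None:
        if not (0 < self.allele < self.ortholog):
            raise ValueError("need 0 < allele threshold < ortholog threshold")
        if not (0 < self.consensus_fraction < 1):
            raise ValueError("consensus_fraction must be in (0, 1)")
        if not (0 <= self.min_support <= 100):
            raise ValueError("min_support must be in [0, 100]")
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")
        if self.min_intron < 1 or self.min_tr_len < 1:
            raise ValueError("length thresholds must be positive")
        if not (0 < self.min_tr_identity <= 1):
            raise ValueError("min_tr_identity must be in (0, 1]")


@dataclass
class SimulateBlock:
    n_subfam: int = 6
    genes_per_subfam: int = 4
    allele_div: float = 0.01
    ortholog_div: float = 0.08
    paralog_div: float = 0.4
    dropout: float = 0.1


@dataclass
class PipelineConfig:
    seed: int | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    sources: dict[str, str] = field(default_factory=dict)  # source name -> FASTA
    simulate: SimulateBlock | None = None
    probes: str | None = None  # FASTA of probe domains (id -> subfamily via anchors)
    anchors: dict[str, str] = field(default_factory=dict)  # seq id -> subfamily
    profile: str | None = None  # consensus profile YAML; default shipped profile
    code_prefix: str = "GobHLH"
    ct_table: str | None = None
    references: tuple[str, ...] = ("histone3", "UBQ14")

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("config must set an explicit seed")
        self.thresholds.validate()
        if not self.sources and self.simulate is None:
            raise ValueError("config needs input sources or a simulate block")
        for name in self.sources:
            if name not in Source.__members__:
                raise ValueError(f"unknown source {name!r}")

    # -- serialisation ---------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        thr = Thresholds(**(data.pop("thresholds", {}) or {}))
        sim = data.pop("simulate", None)
        sim_block = SimulateBlock(**sim) if isinstance(sim, dict) else (
            SimulateBlock() if sim else None
        )
        refs = tuple(data.pop("references", ("histone3", "UBQ14")))
        cfg = cls(thresholds=thr, simulate=sim_block, references=refs, **data)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["references"] = list(self.references)
        return d

    def resolved_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.resolved_yaml().encode()).hexdigest()


def _load_inputs(cfg: PipelineConfig):
    """Per-source records plus (for simulated runs) the planted truth."""
    if cfg.simulate is not None:
        from .simulate import emulate_sources, make_family

        sim = cfg.simulate
        records, truth = make_family(
            n_subfam=sim.n_subfam,
            genes_per_subfam=sim.genes_per_subfam,
            allele_div=sim.allele_div,
            ortholog_div=sim.ortholog_div,
            paralog_div=sim.paralog_div,
            seed=cfg.seed,
        )
        by_source = emulate_sources(records, truth, dropout=sim.dropout, seed=cfg.seed)
        probe_records = [
            SequenceRecord(id=f"anchor_{name}", residues=dom)
            for name, dom in sorted(truth.founder_domain.items())
        ]
        anchors = {f"anchor_{name}": name for name in truth.founder_domain}
        probes = ProbeSet(records=probe_records, subfamily=dict(anchors))
        return by_source, probes, anchors, truth
    by_source = {
        Source[name]: read_fasta(path, moltype="protein", source=Source[name])
        for name, path in cfg.sources.items()
    }
    if cfg.probes is None:
        raise ValueError("probe FASTA required for non-simulated runs")
    probe_records = read_fasta(cfg.probes, moltype="protein")
    probes = ProbeSet(
        records=probe_records,
        subfamily={r.id: cfg.anchors.get(r.id, r.id) for r in probe_records},
    )
    return by_source, probes, dict(cfg.anchors), None


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Execute search -> validate -> build-reference -> classify.

    Writes stage outputs and a manifest into ``outdir`` and returns a
    summary dict (group count, subfamily roster, and — for simulated
    inputs — recovery against the planted truth).
    """
    cfg.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    thr = cfg.thresholds
    profile = (
        ConsensusProfile.from_yaml(cfg.profile) if cfg.profile else ConsensusProfile.default()
    )
    by_source, probes, anchors, truth = _load_inputs(cfg)

    # --- search + validate ---------------------------------------------
    validated: dict[Source, list[SequenceRecord]] = {}
    domain_of: dict[str, str] = {}
    n_candidates = 0
    for source, records in by_source.items():
        cands = search_proteome(probes, records, min_score=thr.min_score)
        n_candidates += len(cands)
        keep = []
        by_id = {r.id: r for r in records}
        for cand in cands:
            call = validate_domain(cand, profile, min_fraction=thr.consensus_fraction)
            if call.verdict:
                keep.append(by_id[cand.subject_id])
                domain_of[cand.subject_id] = cand.residues
        validated[source] = keep

    # --- reference set ---------------------------------------------------
    collapsed = collapse_identical_tandem(validated)
    pooled = [r for records in collapsed.values() for r in records]
    if len(pooled) < 2:
        raise ValueError("fewer than two validated proteins; nothing to group")
    guide = build_guide_tree(pooled)
    groups = group_by_thresholds(
        guide, pooled, allele_thr=thr.allele, ortholog_thr=thr.ortholog
    )
    for g in groups:
        select_representative(g)
    groups = assign_codes(groups, prefix=cfg.code_prefix)
    ov = overlap_matrix(groups)

    write_fasta(
        [next(r for r in g.members if r.id == g.representative) for g in groups],
        out / "reference.faa",
    )
    with open(out / "groups.tsv", "w") as fh:
        fh.write("code\trepresentative\tmembers\tpair_labels\n")
        for g in groups:
            labels = ";".join(
                f"{'|'.join(sorted(p))}={l}" for p, l in sorted(
                    g.pair_labels.items(), key=lambda kv: sorted(kv[0])
                )
            )
            fh.write(
                f"{g.code}\t{g.representative}\t{','.join(g.member_ids)}\t{labels}\n"
            )
    ov.table.to_csv(out / "overlap_matrix.tsv", sep="\t")
    if guide.tree is not None:
        from .trees import write_newick

        write_newick(guide.tree, out / "guide_tree.nwk")

    # --- classification --------------------------------------------------
    domain_records = []
    for g in groups:
        dom = domain_of.get(g.representative)
        if dom:
            domain_records.append(SequenceRecord(id=g.code, residues=dom))
    code_of_gene: dict[str, str] = {}
    if truth is not None:
        for g in groups:
            code_of_gene[g.code] = truth.gene_of[g.representative]
    for rec in probes.records:
        if rec.id in anchors:
            domain_records.append(rec)
    aln = align_progressive(domain_records)
    nj = bootstrap_support(aln, reps=thr.bootstrap_reps, seed=cfg.seed)
    mp = mp_tree(aln, seed=cfg.seed)
    ml, _ll = ml_tree_poisson(aln)
    assignment = call_subfamilies(nj, mp, ml, anchors, min_support=thr.min_support)

    from .trees import write_newick

    write_newick(nj.tree, out / "nj_tree.nwk")
    write_newick(mp, out / "mp_tree.nwk")
    write_newick(ml, out / "ml_tree.nwk")
    with open(out / "subfamilies.tsv", "w") as fh:
        fh.write("id\tsubfamily\n")
        for leaf in sorted(assignment.assignments):
            fh.write(f"{leaf}\t{assignment.assignments[leaf]}\n")
    counts: dict[str, int] = {}
    for leaf, name in assignment.assignments.items():
        if leaf not in anchors:
            counts[name] = counts.get(name, 0) + 1
    with open(out / "subfamily_counts.tsv", "w") as fh:
        fh.write("subfamily\tmembers\n")
        for name in sorted(counts):
            fh.write(f"{name}\t{counts[name]}\n")

    # --- optional expression ---------------------------------------------
    if cfg.ct_table:
        from .expression import CtTable, profile_matrix, relative_expression

        ct = CtTable.from_tsv(cfg.ct_table, references=cfg.references)
        prof = relative_expression(ct)
        profile_matrix(prof).to_csv(out / "expression.tsv", sep="\t")
        profile_matrix(prof, normalize=True).to_csv(
            out / "expression_normalized.tsv", sep="\t"
        )

    summary = {
        "n_candidates": n_candidates,
        "n_validated": sum(len(v) for v in validated.values()),
        "n_groups": len(groups),
        "subfamily_counts": counts,
        "unresolved_subfamilies": sorted(assignment.unresolved),
    }
    if truth is not None:
        true_genes = truth.genes()
        pred = {frozenset(g.member_ids) for g in groups}
        true_sets = {
            frozenset(ids)
            for ids in truth.partition(
                [r.id for r in pooled]
            ).values()
        }
        correct_subfam = sum(
            1
            for code, gene in code_of_gene.items()
            if assignment.assignments.get(code) == truth.subfamily_of[gene]
        )
        summary["truth"] = {
            "n_true_genes": len(true_genes),
            "partition_exact": pred == true_sets,
            "subfamilies_correct": correct_subfam,
            "subfamilies_total": len(code_of_gene),
        }

    # --- manifest ---------------------------------------------------------
    outputs = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    digests = {
        name: hashlib.sha256((out / name).read_bytes()).hexdigest()
        for name in outputs
    }
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "outputs": digests,
    }
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    summary["manifest_hash"] = manifest["manifest_hash"]
    return summary
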