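"""Probe-based proteome search for candidate bHLH domains.

Each probe is a representative domain of one subfamily (the study design
uses 32 subfamily representatives plus three orphans). Every proteome
entry is scored against every probe by exact Smith–Waterman; the best hit
above the score floor yields at most one candidate domain per protein,
cut from the subject over the hit footprint and padded out to the probe's
full domain width when the local alignment is end-truncated.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import LocalAlignment, smith_waterman
from .seqio import SequenceRecord, Source

__all__ = ["ProbeSet", "CandidateDomain", "search_proteome"]


@dataclass
class ProbeSet:
    """Representative domain per subfamily used as search probes."""

    records: list[SequenceRecord]
    subfamily: dict[str, str]  # probe id -> subfamily label

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("probe set is empty")
        ids = {r.id for r in self.records}
        unknown = set(self.subfamily) - ids
        if unknown:
            raise ValueError(f"subfamily labels for unknown probes: {sorted(unknown)}")


@dataclass
class CandidateDomain:
    """A putative domain cut from a proteome entry."""

    subject_id: str
    source: Source
    residues: str
    span: tuple[int, int]  # 0-based half-open on the subject
    best_probe: str
    best_score: float


def _padded_span(
    hit: LocalAlignment, probe_len: int, subject_len: int
) -> tuple[int, int]:
    """Extend a truncated hit footprint to the probe's full domain frame."""
    q0, q1 = hit.query_span
    s0, s1 = hit.subject_span
    start = max(0, s0 - q0)  # missing probe prefix
    end = min(subject_len, s1 + (probe_len - q1))  # missing probe suffix
    return start, end


def search_proteome(
    probes: ProbeSet,
    proteome: list[SequenceRecord],
    min_score: float = 60.0,
) -> list[CandidateDomain]:
    """Best-probe candidate domain per protein, score-filtered and deduplicated.

    At most one candidate per subject (the best-scoring probe wins; equal
    scores break toward the lexicographically smallest probe id); output is
    sorted by subject id.
    """
    ids = [r.id for r in proteome]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids in proteome")
    out: list[CandidateDomain] = []
    probe_recs = sorted(probes.records, key=lambda r: r.id)
    for subject in proteome:
        best: tuple[float, str, LocalAlignment, int] | None = None
        for probe in probe_recs:
            hit = smith_waterman(probe, subject)
            if best is None or hit.score > best[0]:
                best = (hit.score, probe.id, hit, len(probe.residues))
        score, probe_id, hit, probe_len = best
        if score < min_score or hit.is_empty:
            continue
        span = _padded_span(hit, probe_len, len(subject.residues))
        out.append(
            CandidateDomain(
                subject_id=subject.id,
                source=subject.source,
                residues=subject.residues[span[0] : span[1]],
                span=span,
                best_probe=probe_id,
                best_score=score,
            )
        )
    out.sort(key=lambda c: c.subject_id)
    return out
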