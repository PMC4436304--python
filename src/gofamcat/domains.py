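"""Consensus-profile construction and bHLH domain validation.

A candidate domain is accepted when it (1) retains at least two of the
three structural sub-regions (basic, helix1, helix2) and (2) matches more
than 60% of the consensus residues over the columns it covers. The
consensus itself comes either from the profile configuration shipped with
the package or is rebuilt from any reference domain alignment at the 60%
and 80% conservation tiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .align import global_align
from .seqio import Alignment

__all__ = ["ConsensusProfile", "DomainCall", "build_profile", "map_candidate", "validate_domain"]

SUBREGION_ORDER = ("basic", "helix1", "loop", "helix2")
#: sub-regions that count toward the two-sub-region rule
STRUCTURAL_SUBREGIONS = ("basic", "helix1", "helix2")


@dataclass
class ConsensusProfile:
    """Aligned consensus positions, conservation tiers and sub-region spans."""

    ncols: int
    consensus: dict[int, frozenset]  # column -> allowed residues (may be absent)
    tier: dict[int, int]  # column -> 60 or 80
    subregions: list[tuple[str, tuple[int, int]]]  # ordered (name, [start, end))
    representative: str  # one residue per column, used for mapping

    def __post_init__(self) -> None:
        if len(self.representative) != self.ncols:
            raise ValueError("representative length != ncols")
        for col, residues in self.consensus.items():
            if not (0 <= col < self.ncols):
                raise ValueError(f"consensus column {col} outside profile")
            if not residues:
                raise ValueError(f"empty consensus set at column {col}")
        last = -1
        order = [n for n, _ in self.subregions]
        if order != [n for n in SUBREGION_ORDER if n in order]:
            raise ValueError("sub-regions out of order")
        for name, (start, end) in self.subregions:
            if not (0 <= start < end <= self.ncols):
                raise ValueError(f"sub-region {name} span outside profile")
            if start < last:
                raise ValueError("overlapping sub-regions")
            last = end

    @property
    def consensus_columns(self) -> list[int]:
        return sorted(self.consensus)

    def span(self, name: str) -> tuple[int, int]:
        for n, s in self.subregions:
            if n == name:
                return s
        raise KeyError(name)

    # -- serialisation ---------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "ConsensusProfile":
        data = yaml.safe_load(Path(path).read_text())
        return cls._from_dict(data)

    @classmethod
    def default(cls) -> "ConsensusProfile":
        text = (
            resources.files("gofamcat").joinpath("data/domain_profile.yaml").read_text()
        )
        return cls._from_dict(yaml.safe_load(text))

    @classmethod
    def _from_dict(cls, data: dict) -> "ConsensusProfile":
        return cls(
            ncols=int(data["ncols"]),
            consensus={
                int(c["col"]): frozenset(c["residues"]) for c in data["columns"]
            },
            tier={int(c["col"]): int(c["tier"]) for c in data["columns"]},
            subregions=[
                (s["name"], (int(s["start"]), int(s["end"])))
                for s in data["subregions"]
            ],
            representative=str(data["representative"]),
        )

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "ncols": self.ncols,
            "representative": self.representative,
            "subregions": [
                {"name": n, "start": s, "end": e} for n, (s, e) in self.subregions
            ],
            "columns": [
                {
                    "col": c,
                    "residues": sorted(self.consensus[c]),
                    "tier": self.tier[c],
                }
                for c in self.consensus_columns
            ],
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass
class DomainCall:
    """Verdict of the two-rule domain validation for one candidate."""

    candidate_id: str
    consensus_fraction: float
    subregions_present: frozenset
    verdict: bool
    column_map: dict[int, str] = field(default_factory=dict)


def build_profile(
    reference_alignment: Alignment,
    tier_thresholds: tuple[float, float] = (0.60, 0.80),
    subregion_spans: list[tuple[str, tuple[int, int]]] | None = None,
) -> ConsensusProfile:
    """Derive the consensus profile from a reference domain alignment.

    A column's consensus set holds the residues reaching the lower tier
    threshold among non-gap rows; columns where no residue reaches it have
    no consensus and are excluded from the validation denominator.
    """
    lo, hi = tier_thresholds
    ncols = reference_alignment.length
    if subregion_spans:
        for name, (s, e) in subregion_spans:
            if not (0 <= s < e <= ncols):
                raise ValueError(f"sub-region {name} span outside alignment")
    consensus: dict[int, frozenset] = {}
    tier: dict[int, int] = {}
    representative = []
    for c in range(ncols):
        col = [ch for ch in reference_alignment.column(c) if ch != "-"]
        if not col:
            representative.append("X")
            continue
        counts: dict[str, int] = {}
        for ch in col:
            counts[ch] = counts.get(ch, 0) + 1
        best = max(sorted(counts), key=lambda ch: counts[ch])
        representative.append(best)
        allowed = frozenset(ch for ch, k in counts.items() if k / len(col) >= lo)
        if allowed:
            consensus[c] = allowed
            tier[c] = 80 if max(counts.values()) / len(col) >= hi else 60
    return ConsensusProfile(
        ncols=ncols,
        consensus=consensus,
        tier=tier,
        subregions=subregion_spans or [],
        representative="".join(representative),
    )


def map_candidate(candidate_residues: str, profile: ConsensusProfile) -> dict[int, str]:
    """Align a candidate to the profile and map columns to its residues.

    Semi-global alignment (free end gaps) against the profile's
    representative sequence; returns profile column -> candidate residue,
    or '-' where the candidate is gapped at that column. Candidate
    insertions between profile columns are not represented.
    """
    if not candidate_residues:
        raise ValueError("empty candidate")
    ref_row, cand_row, _score = global_align(
        profile.representative, candidate_residues, moltype="protein",
        free_end_gaps=True,
    )
    out: dict[int, str] = {}
    col = 0
    for r, c in zip(ref_row, cand_row):
        if r != "-":
            out[col] = c
            col += 1
    return out


def validate_domain(
    candidate,
    profile: ConsensusProfile,
    min_fraction: float = 0.60,
    min_occupancy: float = 0.80,
    max_gap_run: int = 2,
) -> DomainCall:
    """Apply the two validation rules to a candidate domain.

    The consensus fraction is counted over the consensus columns inside the
    candidate's aligned footprint (truncated candidates are judged on the
    columns they cover). A sub-region is present when at least
    ``min_occupancy`` of its columns carry candidate residues with no
    internal gap run longer than ``max_gap_run``. The verdict requires a
    fraction strictly above ``min_fraction`` and at least two structural
    sub-regions.
    """
    if not profile.consensus:
        raise ValueError("profile has no consensus columns")
    cid = getattr(candidate, "subject_id", None) or getattr(candidate, "id", "")
    residues = getattr(candidate, "residues", candidate)
    colmap = map_candidate(residues, profile)
    occupied = [c for c, ch in colmap.items() if ch != "-"]
    if not occupied:
        return DomainCall(cid, 0.0, frozenset(), False, colmap)
    lo, hi = min(occupied), max(occupied) + 1

    cols = [c for c in profile.consensus_columns if lo <= c < hi]
    matches = sum(1 for c in cols if colmap.get(c, "-") in profile.consensus[c])
    fraction = matches / len(cols) if cols else 0.0

    present = set()
    for name in STRUCTURAL_SUBREGIONS:
        try:
            start, end = profile.span(name)
        except KeyError:
            continue
        span_cols = range(start, end)
        occ = [colmap.get(c, "-") != "-" for c in span_cols]
        if sum(occ) < min_occupancy * len(occ):
            continue
        # internal gap runs: False-runs bounded by covered columns both sides
        covered_idx = [i for i, o in enumerate(occ) if o]
        longest_internal = 0
        for a, b in zip(covered_idx, covered_idx[1:]):
            longest_internal = max(longest_internal, b - a - 1)
        if longest_internal <= max_gap_run:
            present.add(name)
    verdict = fraction > min_fraction and len(present) >= 2
    return DomainCall(cid, fraction, frozenset(present), verdict, colmap)
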