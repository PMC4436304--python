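"""Relative qRT-PCR quantification with two internal-standard genes.

The model is the classic ΔCt: per technical replicate the reference Ct is
the arithmetic mean of the two standards' Ct values (equivalent to the
geometric mean of their expression levels), and the target's relative
level is 2^-(Ct_target - Ct_ref), assuming amplification efficiency 2 per
cycle. Replicates are averaged and their SEM reported; a replicate with no
detectable amplification (missing Ct or Ct above the cutoff) is excluded,
and a gene is called undetectable in a sample only when every replicate is
undetected — never imputed as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CtTable", "ExpressionProfile", "relative_expression", "profile_matrix"]

DEFAULT_REFERENCES = ("histone3", "UBQ14")


@dataclass
class CtTable:
    """Long-format Ct data: one row per (gene, sample, replicate)."""

    data: pd.DataFrame  # columns: gene, sample, replicate, ct (NaN = undetected)
    references: tuple[str, ...] = DEFAULT_REFERENCES
    undetected_ct: float = 40.0

    def __post_init__(self) -> None:
        required = {"gene", "sample", "replicate", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table missing columns: {sorted(missing)}")
        ct = self.data["ct"]
        bad = ct.notna() & ((ct <= 0) | (ct > 45))
        if bad.any():
            raise ValueError("Ct values must lie in (0, 45] or be undetected")
        if len(self.references) < 1:
            raise ValueError("at least one reference gene required")

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "CtTable":
        df = pd.read_csv(path, sep="\t")
        df["ct"] = pd.to_numeric(df["ct"], errors="coerce")
        return cls(data=df, **kwargs)


@dataclass
class ExpressionProfile:
    """(gene, sample) -> relative level with replicate SEM, or undetectable."""

    levels: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: gene, sample, level (NaN if undetectable), sem, n_replicates


def relative_expression(ct: CtTable) -> ExpressionProfile:
    """ΔCt quantification against the mean of the reference genes."""
    df = ct.data.copy()
    df.loc[df["ct"] > ct.undetected_ct, "ct"] = np.nan
    refs = df[df["gene"].isin(ct.references)]
    ref_ct = (
        refs.groupby(["sample", "replicate"])["ct"].mean().rename("ref_ct")
    )
    for sample in df["sample"].unique():
        have = refs[refs["sample"] == sample]["gene"].unique()
        if len(have) == 0:
            raise ValueError(f"sample {sample!r} has no reference gene Ct values")
    targets = df[~df["gene"].isin(ct.references)].merge(
        ref_ct, on=["sample", "replicate"], how="left"
    )
    targets["level"] = 2.0 ** -(targets["ct"] - targets["ref_ct"])
    rows = []
    for (gene, sample), grp in targets.groupby(["gene", "sample"], sort=True):
        values = grp["level"].dropna().to_numpy()
        if values.size == 0:
            rows.append((gene, sample, np.nan, np.nan, 0))
            continue
        level = float(values.mean())
        sem = (
            float(values.std(ddof=1) / np.sqrt(values.size))
            if values.size >= 2
            else np.nan
        )
        rows.append((gene, sample, level, sem, int(values.size)))
    return ExpressionProfile(
        levels=pd.DataFrame(
            rows, columns=["gene", "sample", "level", "sem", "n_replicates"]
        )
    )


def profile_matrix(
    profile: ExpressionProfile,
    genes: list[str] | None = None,
    samples: list[str] | None = None,
    normalize: bool = False,
) -> pd.DataFrame:
    """Genes x samples matrix of levels (with SEM columns).

    Undetectable cells render as "ND". With ``normalize`` each gene's
    maximum sample is scaled to 1.0 (plotting parity with per-gene bar
    charts).
    """
    df = profile.levels
    if genes is None:
        genes = sorted(df["gene"].unique())
    if samples is None:
        samples = list(pd.unique(df["sample"]))
    lv = df.pivot(index="gene", columns="sample", values="level").reindex(
        index=genes, columns=samples
    )
    sem = df.pivot(index="gene", columns="sample", values="sem").reindex(
        index=genes, columns=samples
    )
    if normalize:
        mx = lv.max(axis=1)
        lv = lv.div(mx.replace(0, np.nan), axis=0)
        sem = sem.div(mx.replace(0, np.nan), axis=0)
    out = pd.DataFrame(index=genes)
    for s in samples:
        out[s] = lv[s].map(lambda v: "ND" if pd.isna(v) else v)
        out[f"{s}_sem"] = sem[s]
    return out
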