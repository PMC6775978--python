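"""Assembly and genome statistics: contig filtering, N50, GC content,
completeness-based genome-size extrapolation, and count proportions.

The N50 convention is the common descending-cumulative one: the smallest
contig length L such that contigs of length >= L together contain at least
half the assembly's bases. Ambiguous bases (N) are excluded from the GC
denominator. Complete-genome size is extrapolated from a partial assembly
as assembly_size / (completeness/100), the standard first-order correction
for single-copy-marker completeness estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "AssemblyRecord",
    "filter_contigs",
    "n50",
    "gc_content",
    "estimate_complete_size",
    "proportion",
    "read_contig_fasta",
    "read_genome_table",
    "extrapolation_table",
]

_GC_BASES = set("GC")
_COUNTED_BASES = set("ACGT")
_ALLOWED_BASES = set("ACGTN")


@dataclass(frozen=True)
class AssemblyRecord:
    """Per-genome assembly characteristics (as reported or recomputed)."""

    genome_id: str
    assembly_size: float  # bp
    completeness: float  # percent
    contamination: float = 0.0  # percent; may exceed 100 in pathological bins
    contig_lengths: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.completeness <= 100.0):
            raise ValueError(f"{self.genome_id}: completeness out of [0,100]")
        if self.contamination < 0.0:
            raise ValueError(f"{self.genome_id}: negative contamination")
        if self.contig_lengths and sum(self.contig_lengths) != self.assembly_size:
            raise ValueError(
                f"{self.genome_id}: assembly_size != sum of contig lengths"
            )


def filter_contigs(
    lengths: Sequence[int], min_length: int, strict: bool = True
) -> list[int]:
    """Retain contigs above a length cutoff, preserving order.

    ``strict=True`` keeps lengths strictly greater than ``min_length`` (the
    ">2 kbp" submission rule); ``strict=False`` keeps >=.
    """
    if any(l <= 0 for l in lengths):
        raise ValueError("contig lengths must be positive")
    if strict:
        return [l for l in lengths if l > min_length]
    return [l for l in lengths if l >= min_length]


def n50(lengths: Sequence[int]) -> int:
    """Smallest length L with contigs >= L summing to at least half the total."""
    if not lengths:
        raise ValueError("n50 of an empty assembly")
    if any(l <= 0 for l in lengths):
        raise ValueError("contig lengths must be positive")
    half = sum(lengths) / 2.0
    running = 0
    for l in sorted(lengths, reverse=True):
        running += l
        if running >= half:
            return l
    raise AssertionError("unreachable")  # pragma: no cover


def gc_content(sequences: Iterable[str]) -> float:
    """Percent G+C over A/C/G/T bases; N excluded from the denominator."""
    gc = 0
    counted = 0
    for seq in sequences:
        for base in seq.upper():
            if base not in _ALLOWED_BASES:
                raise ValueError(f"unexpected base {base!r}")
            if base in _COUNTED_BASES:
                counted += 1
                if base in _GC_BASES:
                    gc += 1
    if counted == 0:
        raise ValueError("no unambiguous bases to compute GC content")
    return 100.0 * gc / counted


def estimate_complete_size(assembly_size: float, completeness: float) -> float:
    """Extrapolated complete-genome size: assembly_size / (completeness/100)."""
    if completeness <= 0:
        raise ValueError("completeness must be > 0 to extrapolate")
    return assembly_size / (completeness / 100.0)


def proportion(count: int, total: int) -> float:
    """Percentage 100*count/total (unrounded; reports round half away from zero)."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not (0 <= count <= total):
        raise ValueError("count must be in [0, total]")
    return 100.0 * count / total


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (report convention)."""
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def read_contig_fasta(path: str | Path) -> tuple[list[int], list[str]]:
    """Read contigs from FASTA; return (lengths, sequences)."""
    lengths: list[int] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs.append(str(rec.seq))
        lengths.append(len(rec.seq))
    if not lengths:
        raise ValueError(f"{path}: no FASTA records")
    return lengths, seqs


def read_genome_table(path: str | Path | None = None) -> pd.DataFrame:
    """Read a genome-characteristics TSV (the shipped study table when None).

    Required columns: genome_id, assembly_size_mbp, completeness_pct;
    other columns pass through.
    """
    if path is None:
        from importlib import resources

        with resources.files("crustbio.data").joinpath("table1.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    required = {"genome_id", "assembly_size_mbp", "completeness_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"genome table missing columns {sorted(missing)}")
    return df


def extrapolation_table(table: pd.DataFrame, genome_type: str | None = "SAG") -> pd.DataFrame:
    """Per-genome complete-size extrapolations plus mean/median rows.

    ``genome_type`` restricts to one type ("SAG"/"MAG") when the table has
    a genome_type column; None uses all rows. Sizes are in Mbp.
    """
    df = table
    if genome_type is not None and "genome_type" in df.columns:
        df = df[df["genome_type"] == genome_type]
    if df.empty:
        raise ValueError("no genomes selected for extrapolation")
    est = [
        estimate_complete_size(row.assembly_size_mbp, row.completeness_pct)
        for row in df.itertuples(index=False)
    ]
    out = pd.DataFrame(
        {
            "genome_id": list(df["genome_id"]),
            "assembly_size_mbp": list(df["assembly_size_mbp"]),
            "completeness_pct": list(df["completeness_pct"]),
            "estimated_complete_size_mbp": est,
        }
    )
    summary = pd.DataFrame(
        {
            "genome_id": ["mean", "median"],
            "assembly_size_mbp": [float("nan")] * 2,
            "completeness_pct": [float("nan")] * 2,
            "estimated_complete_size_mbp": [
                out["estimated_complete_size_mbp"].mean(),
                out["estimated_complete_size_mbp"].median(),
            ],
        }
    )
    return pd.concat([out, summary], ignore_index=True)
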