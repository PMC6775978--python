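"""Relative abundance of motility genes (COG category N) across environments.

Compares genomes and metagenomes from different marine settings (sediment,
hydrothermal vent, crustal aquifer, water column) by the fraction of their
COG-annotated genes assigned to functional category N (cell motility).
Partial genomes are filtered by an inclusive completeness threshold
(metagenomes carry no completeness and always pass), and per-environment
distributions are summarized by quartiles.

The denominator is the number of genes carrying at least one COG category
letter; genes annotated with several category letters count once in the
denominator and once per category in the numerators. Quartiles use the
inclusive-median (Tukey hinge) convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .markers import GeneAnnotation

__all__ = [
    "ENVIRONMENTS",
    "GenomeProfile",
    "GroupSummary",
    "motility_relative_abundance",
    "filter_by_completeness",
    "group_quartiles",
    "profile_from_annotations",
    "tukey_quartiles",
]

ENVIRONMENTS = ("sediment", "hydrothermal_vent", "crustal_aquifer", "water_column")
MOTILITY_CATEGORY = "N"


@dataclass(frozen=True)
class GenomeProfile:
    """Per-sample COG functional-category tallies.

    ``completeness`` (percent) is required for genomes and ignored for
    metagenomes; ``total_annotated`` is the number of genes with at least
    one COG category letter.
    """

    sample_id: str
    sample_type: str  # "genome" | "metagenome"
    environment: str
    counts: Mapping[str, int] = field(default_factory=dict)
    total_annotated: int = 0
    completeness: float | None = None

    def __post_init__(self) -> None:
        if self.sample_type not in ("genome", "metagenome"):
            raise ValueError(f"unknown sample_type {self.sample_type!r}")
        if self.environment not in ENVIRONMENTS:
            raise ValueError(f"unknown environment {self.environment!r}")
        if self.sample_type == "genome":
            if self.completeness is None:
                raise ValueError(f"{self.sample_id}: genome needs completeness")
            if not (0.0 <= self.completeness <= 100.0):
                raise ValueError(f"{self.sample_id}: completeness out of [0,100]")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError(f"{self.sample_id}: negative category count")


@dataclass(frozen=True)
class GroupSummary:
    """Five-number summary of motility relative abundance in one environment."""

    environment: str
    n: int
    min: float
    q1: float
    median: float
    q3: float
    max: float


def motility_relative_abundance(profile: GenomeProfile) -> float:
    """Fraction of COG-annotated genes in category N (cell motility)."""
    if profile.total_annotated <= 0:
        raise ValueError(f"{profile.sample_id}: no annotated genes")
    return profile.counts.get(MOTILITY_CATEGORY, 0) / profile.total_annotated


def filter_by_completeness(
    profiles: Sequence[GenomeProfile], min_completeness: float
) -> list[GenomeProfile]:
    """Keep genomes with completeness >= threshold; metagenomes always pass."""
    if not (0.0 <= min_completeness <= 100.0):
        raise ValueError("min_completeness must be in [0, 100]")
    return [
        p
        for p in profiles
        if p.sample_type == "metagenome" or p.completeness >= min_completeness
    ]


def _median(sorted_vals: Sequence[float]) -> float:
    n = len(sorted_vals)
    mid = n // 2
    if n % 2:
        return float(sorted_vals[mid])
    return (sorted_vals[mid - 1] + sorted_vals[mid]) / 2.0


def tukey_quartiles(values: Sequence[float]) -> tuple[float, float, float]:
    """(q1, median, q3) by the inclusive-median (Tukey hinge) method.

    Each half includes the middle observation when n is odd, so e.g.
    ``[1, 2, 3, 4]`` gives hinges 1.5 and 3.5 about a median of 2.5.
    """
    if not values:
        raise ValueError("no values")
    v = sorted(values)
    n = len(v)
    lower = v[: (n + 1) // 2]
    upper = v[n // 2:]
    return _median(lower), _median(v), _median(upper)


def group_quartiles(profiles: Sequence[GenomeProfile]) -> list[GroupSummary]:
    """Per-environment quartile summaries, environment-sorted."""
    groups: dict[str, list[float]] = {}
    for p in profiles:
        groups.setdefault(p.environment, []).append(motility_relative_abundance(p))
    out = []
    for env in sorted(groups):
        vals = sorted(groups[env])
        q1, med, q3 = tukey_quartiles(vals)
        out.append(
            GroupSummary(
                environment=env,
                n=len(vals),
                min=vals[0],
                q1=q1,
                median=med,
                q3=q3,
                max=vals[-1],
            )
        )
    return out


def profile_from_annotations(
    annotations: Iterable[GeneAnnotation],
    sample_id: str,
    sample_type: str,
    environment: str,
    completeness: float | None = None,
) -> GenomeProfile:
    """Tally COG category counts from a gene annotation list.

    Genes with several category letters increment each category and count
    once in the denominator; genes without any COG category are excluded
    from the denominator.
    """
    counts: dict[str, int] = {}
    total = 0
    for ann in annotations:
        if not ann.cog_category:
            continue
        total += 1
        for letter in ann.cog_category:
            counts[letter] = counts.get(letter, 0) + 1
    return GenomeProfile(
        sample_id=sample_id,
        sample_type=sample_type,
        environment=environment,
        counts=counts,
        total_annotated=total,
        completeness=completeness,
    )


def abundance_table(
    profiles: Sequence[GenomeProfile], normalize_by_completeness: bool = False
) -> pd.DataFrame:
    """Per-sample motility relative abundance as a DataFrame.

    ``normalize_by_completeness=True`` adds an experimental column dividing
    the raw fraction by completeness/100 (genomes only) — an attempt to put
    partial genomes of different completeness on a common footing; the raw
    fraction is always reported alongside.
    """
    rows = []
    for p in profiles:
        ra = motility_relative_abundance(p)
        row = {
            "sample_id": p.sample_id,
            "sample_type": p.sample_type,
            "environment": p.environment,
            "completeness_pct": p.completeness,
            "motility_relative_abundance": ra,
        }
        if normalize_by_completeness:
            row["motility_ra_per_completeness"] = (
                ra / (p.completeness / 100.0)
                if p.sample_type == "genome" and p.completeness
                else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)
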