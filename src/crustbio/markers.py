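"""Marker-set scoring of per-genome gene annotation tables.

Partial genomes (SAGs and MAGs) are scored against named pathway marker
sets — lists of gene symbols and/or KO identifiers with a presence rule
(any / all / fraction>=theta). The result is a genomes x markers boolean
presence matrix, per-pathway completeness fractions, and a collective
lineage summary (the union of presence over all genomes), which is how a
lineage's metabolic potential is reported when every individual genome is
incomplete.

Marker sets with ``expectation="absent"`` encode negative assertions, e.g.
the absence of methyl-coenzyme M reductase (*mcr*) that rules out
methanogenesis: their rule is satisfied when no member is found.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "GeneAnnotation",
    "MarkerSet",
    "PresenceMatrix",
    "expand_members",
    "load_marker_sets",
    "evaluate_presence",
    "lineage_summary",
    "pathway_report",
    "read_annotations",
]

_KO_RE = re.compile(r"^K\d{5}$")
_GROUP_RE = re.compile(r"^([a-z][A-Za-z0-9]*?)([A-Z]{2,})$")


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene's functional labels from an annotation pipeline export."""

    genome_id: str
    gene_id: str
    cog_id: str | None = None
    cog_category: frozenset[str] = frozenset()
    ko_id: str | None = None
    symbol: str | None = None

    @property
    def is_annotated(self) -> bool:
        return bool(self.cog_id or self.cog_category or self.ko_id or self.symbol)


@dataclass(frozen=True)
class MarkerSet:
    """A named pathway with member markers and a satisfaction rule.

    ``rule`` is one of ``"any"``, ``"all"`` or ``"fraction"`` (with
    ``threshold`` in (0, 1]); ``expectation`` is ``"present"`` for ordinary
    pathways and ``"absent"`` for negative assertions.
    """

    name: str
    members: tuple[str, ...]
    rule: str = "any"
    threshold: float | None = None
    expectation: str = "present"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"marker set {self.name!r}: no members")
        if self.rule not in ("any", "all", "fraction"):
            raise ValueError(f"marker set {self.name!r}: unknown rule {self.rule!r}")
        if self.rule == "fraction":
            if self.threshold is None or not (0.0 < self.threshold <= 1.0):
                raise ValueError(
                    f"marker set {self.name!r}: fraction rule needs threshold in (0,1]"
                )
        if self.expectation not in ("present", "absent"):
            raise ValueError(
                f"marker set {self.name!r}: unknown expectation {self.expectation!r}"
            )

    def satisfied(self, n_present: int) -> bool:
        """Apply the rule (and expectation) to a count of present members."""
        n = len(self.members)
        if self.rule == "any":
            ok = n_present >= 1
        elif self.rule == "all":
            ok = n_present == n
        else:
            ok = (n_present / n) >= self.threshold
        return (not ok) if self.expectation == "absent" else ok


@dataclass
class PresenceMatrix:
    """Genomes x markers boolean presence plus per-pathway completeness."""

    genomes: list[str]
    markers: list[str]
    cells: pd.DataFrame  # bool, index=genomes, columns=markers
    marker_sets: list[MarkerSet] = field(default_factory=list)
    pathway_completeness: dict[tuple[str, str], float] = field(default_factory=dict)


def expand_members(member: str) -> list[str]:
    """Expand a grouped-subunit symbol into per-subunit symbols.

    ``"fwdABCDEFG"`` -> ``["fwdA", ..., "fwdG"]``; symbols without a
    trailing run of two or more capital subunit letters (``"ftr"``,
    ``"mtrA"``, ``"K00200"``) pass through unchanged.
    """
    if _KO_RE.match(member):
        return [member]
    m = _GROUP_RE.match(member)
    if m is None:
        return [member]
    stem, letters = m.groups()
    return [stem + letter for letter in letters]


def load_marker_sets(path: str | Path | None = None) -> list[MarkerSet]:
    """Load marker sets from YAML, expanding grouped subunit symbols.

    With ``path=None`` the shipped set (the Hydrothermarchaeota pathway
    inventory) is loaded. Duplicate set names are an error.
    """
    if path is None:
        text = resources.files("crustbio.data").joinpath("marker_sets.yaml").read_text()
    else:
        text = Path(path).read_text()
    docs = yaml.safe_load(text)
    sets: list[MarkerSet] = []
    seen: set[str] = set()
    for doc in docs:
        members: list[str] = []
        for member in doc["members"]:
            members.extend(expand_members(str(member)))
        ms = MarkerSet(
            name=doc["name"],
            members=tuple(members),
            rule=doc.get("rule", "any"),
            threshold=doc.get("threshold"),
            expectation=doc.get("expectation", "present"),
        )
        if ms.name in seen:
            raise ValueError(f"duplicate marker-set name {ms.name!r}")
        seen.add(ms.name)
        sets.append(ms)
    return sets


def _marker_matches(marker: str, ann: GeneAnnotation) -> bool:
    # symbol match first (case-insensitive), KO match second (exact)
    if ann.symbol is not None and ann.symbol.lower() == marker.lower():
        return True
    if _KO_RE.match(marker) and ann.ko_id == marker:
        return True
    return False


def evaluate_presence(
    annotations: Iterable[GeneAnnotation],
    marker_sets: Sequence[MarkerSet],
    genomes: Sequence[str] | None = None,
) -> PresenceMatrix:
    """Score genomes against marker sets.

    A marker is present in a genome iff at least one of the genome's
    annotations matches it by symbol (case-insensitive) or KO id (exact).
    Row order follows first appearance in the annotations (or the explicit
    ``genomes`` list, which may include all-absent empty genomes); column
    order follows the marker sets.
    """
    names = [ms.name for ms in marker_sets]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate marker-set names: {', '.join(dupes)}")

    by_genome: dict[str, list[GeneAnnotation]] = {}
    if genomes is not None:
        for g in genomes:
            by_genome[g] = []
    for ann in annotations:
        by_genome.setdefault(ann.genome_id, []).append(ann)

    markers: list[str] = []
    for ms in marker_sets:
        for m in ms.members:
            if m not in markers:
                markers.append(m)

    genome_ids = list(by_genome)
    # symbol/KO lookup per genome for O(genes + markers) scoring
    rows = []
    for g in genome_ids:
        symbols = {a.symbol.lower() for a in by_genome[g] if a.symbol}
        kos = {a.ko_id for a in by_genome[g] if a.ko_id}
        rows.append(
            [m.lower() in symbols or (_KO_RE.match(m) is not None and m in kos)
             for m in markers]
        )
    cells = pd.DataFrame(rows, index=genome_ids, columns=markers, dtype=bool)

    completeness: dict[tuple[str, str], float] = {}
    for g in genome_ids:
        for ms in marker_sets:
            present = int(cells.loc[g, list(ms.members)].sum())
            completeness[(g, ms.name)] = present / len(ms.members)
    return PresenceMatrix(
        genomes=genome_ids,
        markers=markers,
        cells=cells,
        marker_sets=list(marker_sets),
        pathway_completeness=completeness,
    )


def lineage_summary(matrix: PresenceMatrix) -> dict:
    """Collective (union-over-genomes) presence of each marker.

    Returns ``{"markers": {marker: bool}, "n_present": int,
    "expectations": {set_name: bool}}`` where expectations reports, for
    each marker set, whether its rule (including absence expectations) is
    satisfied by the union genome.
    """
    if not matrix.genomes:
        raise ValueError("empty presence matrix")
    union = matrix.cells.any(axis=0)
    marker_presence = {m: bool(union[m]) for m in matrix.markers}
    expectations = {}
    for ms in matrix.marker_sets:
        n_present = sum(marker_presence[m] for m in ms.members)
        expectations[ms.name] = ms.satisfied(n_present)
    return {
        "markers": marker_presence,
        "n_present": int(sum(marker_presence.values())),
        "expectations": expectations,
    }


def pathway_report(matrix: PresenceMatrix) -> pd.DataFrame:
    """One row per genome x marker set: completeness and rule satisfaction.

    For absence-expectation sets the completeness column is NaN — absence
    is an assertion, not a pathway fraction.
    """
    records = []
    for g in matrix.genomes:
        for ms in matrix.marker_sets:
            n_present = int(matrix.cells.loc[g, list(ms.members)].sum())
            records.append(
                {
                    "genome_id": g,
                    "pathway": ms.name,
                    "completeness": (
                        float("nan")
                        if ms.expectation == "absent"
                        else matrix.pathway_completeness[(g, ms.name)]
                    ),
                    "rule_satisfied": ms.satisfied(n_present),
                }
            )
    return pd.DataFrame.from_records(
        records, columns=["genome_id", "pathway", "completeness", "rule_satisfied"]
    )


def read_annotations(path: str | Path) -> list[GeneAnnotation]:
    """Read a gene-annotation TSV (IMG-style per-genome export).

    Expected columns: genome_id, gene_id, cog_id, cog_category, ko_id,
    symbol; empty cells become None / empty category sets.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"genome_id", "gene_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        cat = getattr(row, "cog_category", "")
        out.append(
            GeneAnnotation(
                genome_id=row.genome_id,
                gene_id=row.gene_id,
                cog_id=getattr(row, "cog_id", "") or None,
                cog_category=frozenset(cat) if cat else frozenset(),
                ko_id=getattr(row, "ko_id", "") or None,
                symbol=getattr(row, "symbol", "") or None,
            )
        )
    return out
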