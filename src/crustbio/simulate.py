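"""Synthetic inputs for every pipeline stage: annotation tables with planted
marker inventories and controlled motility-gene fractions, contig sets with
controlled length and GC distributions, and fluid-chemistry profiles.

The generators emulate IMG-style per-genome annotation exports and assembly
FASTA so that recovery can be tested against known truth: each run emits a
machine-readable truth record (planted marker sets, true motility fraction
per genome) alongside the data, and tests compare against that record
rather than re-deriving it.

Determinism: everything is a pure function of (spec, seed). A single root
seed is split into per-genome streams with ``numpy.random.SeedSequence``
spawn keys, so adding a genome to a spec does not perturb the genomes
already generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .energetics import FluidConditions, load_conditions
from .markers import load_marker_sets

__all__ = [
    "SimulationSpec",
    "gen_annotations",
    "gen_contigs",
    "gen_fluid_profile",
]

# background COG categories (anything but N, which is motility) with a toy
# COG id per letter; relative weights roughly mimic a genome's breakdown
_BACKGROUND_CATEGORIES = "CEFGHIJKLMOPRSTU"
_COG_BASE = 1000


@dataclass(frozen=True)
class SimulationSpec:
    """Controls for the annotation-table generator.

    Defaults encode the comparison conditions used throughout: 30 genomes
    per environment, 1000 COG-annotated genes per genome, motility-gene
    fraction 0.03 in crustal aquifers vs 0.005 in sediments, and genome
    completeness drawn uniformly within a per-environment range.
    """

    seed: int = 0
    n_genomes: Mapping[str, int] = field(
        default_factory=lambda: {"crustal_aquifer": 30, "sediment": 30}
    )
    genes_per_genome: int = 1000
    motility_fraction: Mapping[str, float] = field(
        default_factory=lambda: {
            "crustal_aquifer": 0.03,
            "sediment": 0.005,
            "hydrothermal_vent": 0.02,
            "water_column": 0.02,
        }
    )
    marker_inventory: Mapping[str, Sequence[str]] = field(default_factory=dict)
    completeness_range: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "crustal_aquifer": (20.0, 100.0),
            "sediment": (20.0, 100.0),
            "hydrothermal_vent": (20.0, 100.0),
            "water_column": (20.0, 100.0),
        }
    )

    def __post_init__(self) -> None:
        for env, p in self.motility_fraction.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"motility fraction for {env} out of [0,1]: {p}")
        for env, n in self.n_genomes.items():
            if n < 0:
                raise ValueError(f"negative genome count for {env}")


def _genome_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def gen_annotations(spec: SimulationSpec) -> tuple[pd.DataFrame, dict]:
    """Generate an annotation table and its truth record.

    Each genome receives ``genes_per_genome`` COG-annotated genes, of which
    Binomial(n, p_env) get category N (motility) and the rest background
    categories. Every member symbol of each marker set listed for the
    genome in ``spec.marker_inventory`` is planted exactly once as an
    additional symbol-only gene (no COG category, so planted markers do
    not alter the COG-annotated denominator).

    Returns ``(table, truth)`` where truth maps genome_id to its
    environment, completeness, true motility fraction, realized category-N
    count, and planted marker sets.
    """
    shipped = {ms.name: ms for ms in load_marker_sets()}
    for genome, sets in spec.marker_inventory.items():
        unknown = [s for s in sets if s not in shipped]
        if unknown:
            raise ValueError(
                f"genome {genome!r}: unknown marker set(s) {', '.join(unknown)}"
            )

    rows: list[tuple] = []
    truth: dict[str, dict] = {}
    genome_index = 0
    planned: list[tuple[str, str]] = []  # (genome_id, environment)
    for env in sorted(spec.n_genomes):
        for i in range(spec.n_genomes[env]):
            planned.append((f"{env}_g{i:03d}", env))
    # explicit inventory-only genomes not covered by n_genomes
    for genome in spec.marker_inventory:
        if not any(g == genome for g, _ in planned):
            planned.append((genome, "crustal_aquifer"))

    for genome_id, env in planned:
        rng = _genome_rng(spec.seed, genome_index)
        genome_index += 1
        p = spec.motility_fraction.get(env, 0.0)
        n_genes = spec.genes_per_genome
        n_motility = int(rng.binomial(n_genes, p)) if p > 0 else 0
        lo, hi = spec.completeness_range.get(env, (20.0, 100.0))
        completeness = float(np.round(rng.uniform(lo, hi), 1))

        categories = ["N"] * n_motility + [
            _BACKGROUND_CATEGORIES[k]
            for k in rng.integers(0, len(_BACKGROUND_CATEGORIES), n_genes - n_motility)
        ]
        rng.shuffle(categories)
        for j, cat in enumerate(categories):
            cog_id = f"COG{_COG_BASE + (ord(cat) - 65):04d}"
            rows.append((genome_id, f"{genome_id}_{j:05d}", cog_id, cat, "", ""))

        planted = list(spec.marker_inventory.get(genome_id, ()))
        j = len(categories)
        for set_name in planted:
            for symbol in shipped[set_name].members:
                rows.append((genome_id, f"{genome_id}_{j:05d}", "", "", "", symbol))
                j += 1

        truth[genome_id] = {
            "environment": env,
            "completeness": completeness,
            "motility_fraction_true": p,
            "motility_genes": n_motility,
            "annotated_genes": n_genes,
            "marker_sets": planted,
        }

    table = pd.DataFrame(
        rows,
        columns=["genome_id", "gene_id", "cog_id", "cog_category", "ko_id", "symbol"],
    )
    return table, {"seed": spec.seed, "genomes": truth}


def gen_contigs(
    seed: int,
    n: int,
    length_law: tuple[float, float] = (9.0, 1.0),
    gc_target: float = 50.0,
    fixed_length: int | None = None,
):
    """Generate ``n`` contigs with log-normal lengths and a target GC.

    ``length_law`` is (mu, sigma) of the log-normal on natural-log scale;
    ``fixed_length`` overrides the law with a constant length. Bases are
    drawn i.i.d. with P(G or C) = gc_target/100, so the realized GC of a
    >=100 kb batch concentrates within 1% of the target. Headers carry the
    true length. Returns a list of Biopython SeqRecords.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    if n <= 0:
        raise ValueError("n must be positive")
    if not (0.0 <= gc_target <= 100.0):
        raise ValueError("gc_target out of [0,100]")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0xC0171,)))
    if fixed_length is not None:
        lengths = np.full(n, int(fixed_length))
    else:
        mu, sigma = length_law
        lengths = np.maximum(1, rng.lognormal(mu, sigma, n).astype(int))
    p_gc = gc_target / 100.0
    probs = [p_gc / 2, p_gc / 2, (1 - p_gc) / 2, (1 - p_gc) / 2]
    alphabet = np.array(list("GCAT"))
    records = []
    for i, length in enumerate(lengths):
        seq = "".join(rng.choice(alphabet, size=int(length), p=probs))
        records.append(
            SeqRecord(
                Seq(seq),
                id=f"contig_{i:05d}",
                description=f"length={int(length)}",
            )
        )
    return records


def gen_fluid_profile(name: str = "jdfr", **overrides) -> FluidConditions:
    """A named fluid-chemistry profile with optional field overrides.

    ``"jdfr"`` is the warm (337.15 K), sulfate-rich (18 mmol/kg) ridge-flank
    crustal-fluid profile; unknown names raise with the list of known
    profiles. ``overrides`` may replace any scalar field or individual
    concentrations (``concentrations={"SO4": 0.028}`` merges per species).
    """
    return load_conditions(name, **overrides)
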