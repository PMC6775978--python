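"""Catabolic Gibbs-energy calculations for crustal-fluid metabolisms.

Evaluates the in situ energy yield of catabolic reactions — here, sulfate
reduction coupled to CO, H2, CH4 or acetate oxidation — from tabulated
standard-state formation properties and a fluid-chemistry profile:

    dG_r(T) = dG0_r(T) + R*T*ln(Q)

with Q the reaction quotient over solute activities. Standard reaction
energies at temperature are obtained from 298.15 K formation properties by
the Gibbs–Helmholtz relation with constant reaction enthalpy (van 't Hoff
approximation), adequate for the <70 degC window of warm ridge-flank fluids.
Energies are normalized per mole of electrons transferred so that reactions
of different stoichiometry can be compared on one axis.

The shipped species table, reaction set and "jdfr" (Juan de Fuca Ridge
flank) condition profile live under ``crustbio/data`` and are plain data:
users may override any of them from files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "R_KJ",
    "T_REF",
    "Species",
    "Reaction",
    "FluidConditions",
    "EnergyResult",
    "SweepResult",
    "UnknownSpeciesError",
    "validate_reaction",
    "standard_gibbs",
    "activity_coefficient",
    "reaction_quotient",
    "gibbs_energy",
    "sweep_donor",
    "rank_donors",
    "load_species_table",
    "load_reactions",
    "load_conditions",
]

#: Gas constant, kJ mol^-1 K^-1.
R_KJ = 8.314462618e-3
#: Reference temperature of the formation-property tables, K.
T_REF = 298.15
#: Debye–Hückel A parameter at 298.15 K (held constant; see docs/methods.md).
DAVIES_A = 0.509

_SOLVENT_PHASE = "liquid-water"


class UnknownSpeciesError(KeyError):
    """A reaction or condition profile references a species not in the table."""


@dataclass(frozen=True)
class Species:
    """A chemical species with standard-state formation properties.

    Parameters
    ----------
    name : short identifier, e.g. ``"SO4"``.
    formula : element symbol -> count, e.g. ``{"S": 1, "O": 4}``.
    charge : signed integer charge.
    phase : ``"aqueous"`` or ``"liquid-water"`` (solvent only).
    dGf0, dHf0 : standard Gibbs energy / enthalpy of formation at
        298.15 K, kJ/mol (1 molal standard state for aqueous solutes).
    source : free-text provenance of the property values.
    """

    name: str
    formula: Mapping[str, int]
    charge: int
    phase: str = "aqueous"
    dGf0: float = 0.0
    dHf0: float = 0.0
    source: str = ""

    def __post_init__(self) -> None:
        if not self.formula:
            raise ValueError(f"species {self.name!r}: empty formula")
        for elem, count in self.formula.items():
            if not (isinstance(count, int) and count >= 0):
                raise ValueError(
                    f"species {self.name!r}: element {elem} count {count!r} "
                    "must be a non-negative integer"
                )
        if self.phase not in ("aqueous", _SOLVENT_PHASE):
            raise ValueError(f"species {self.name!r}: unknown phase {self.phase!r}")

    @property
    def is_solvent(self) -> bool:
        return self.phase == _SOLVENT_PHASE


@dataclass(frozen=True)
class Reaction:
    """Signed stoichiometry over species names plus electrons transferred.

    Negative coefficients are reactants, positive are products. ``donor``
    and ``acceptor`` name the electron donor/acceptor species, both of
    which must appear as reactants.
    """

    id: str
    stoichiometry: Mapping[str, float]
    n_electrons: int
    donor: str
    acceptor: str

    def __post_init__(self) -> None:
        if self.n_electrons <= 0:
            raise ValueError(f"reaction {self.id!r}: n_electrons must be positive")

    def scaled(self, k: int) -> "Reaction":
        """The same reaction with all coefficients and electrons times ``k``."""
        return replace(
            self,
            stoichiometry={s: k * v for s, v in self.stoichiometry.items()},
            n_electrons=k * self.n_electrons,
        )


@dataclass(frozen=True)
class FluidConditions:
    """Temperature and composition defining the reaction quotient.

    Concentrations are molalities (mol/kg water) and must be strictly
    positive. H+ activity is ``10**-pH``; the solvent activity is 1.
    """

    temperature: float
    concentrations: Mapping[str, float]
    ionic_strength: float = 0.0
    pH: float = 7.0
    activity_model: str = "ideal"
    name: str = ""

    def __post_init__(self) -> None:
        if self.temperature <= 273.0:
            raise ValueError("temperature must exceed 273 K")
        if self.ionic_strength < 0:
            raise ValueError("ionic strength must be >= 0")
        if self.activity_model not in ("ideal", "davies"):
            raise ValueError(f"unknown activity model {self.activity_model!r}")
        for name, m in self.concentrations.items():
            if m <= 0:
                raise ValueError(f"concentration of {name!r} must be > 0 (got {m})")

    def with_concentration(self, species: str, molality: float) -> "FluidConditions":
        conc = dict(self.concentrations)
        conc[species] = molality
        return replace(self, concentrations=conc)


@dataclass(frozen=True)
class EnergyResult:
    """Standard and in situ reaction energies for one reaction/condition pair."""

    reaction_id: str
    temperature: float
    dG0_T: float  # kJ/mol
    lnQ: float
    dG: float  # kJ/mol
    dG_per_electron: float  # kJ/(mol e-)


@dataclass(frozen=True)
class SweepResult:
    """Per-electron energy yield across a donor-concentration grid."""

    reaction_id: str
    donor: str
    grid: tuple[float, ...]
    values: tuple[float, ...]  # dG per electron, kJ/(mol e-)
    results: tuple[EnergyResult, ...] = field(default=(), repr=False)


# ---------------------------------------------------------------------------
# validation

def validate_reaction(
    reaction: Reaction, species_table: Mapping[str, Species]
) -> list[str]:
    """Check element and charge balance; return a list of violations.

    An empty list means the reaction is balanced. Unknown species names
    raise :class:`UnknownSpeciesError` (they make balance undecidable).
    """
    unknown = [s for s in reaction.stoichiometry if s not in species_table]
    if unknown:
        raise UnknownSpeciesError(
            f"reaction {reaction.id!r}: unknown species {', '.join(sorted(unknown))}"
        )
    violations: list[str] = []
    if not reaction.stoichiometry:
        return ["no species in stoichiometry"]

    balance: dict[str, float] = {}
    charge = 0.0
    for name, coeff in reaction.stoichiometry.items():
        sp = species_table[name]
        for elem, count in sp.formula.items():
            balance[elem] = balance.get(elem, 0.0) + coeff * count
        charge += coeff * sp.charge
    for elem in sorted(balance):
        if abs(balance[elem]) > 1e-9:
            violations.append(f"element {elem} unbalanced by {balance[elem]:g}")
    if abs(charge) > 1e-9:
        violations.append(f"charge unbalanced by {charge:g}")
    for role, name in (("donor", reaction.donor), ("acceptor", reaction.acceptor)):
        if reaction.stoichiometry.get(name, 0) >= 0:
            violations.append(f"{role} {name!r} is not a reactant")
    return violations


def _require_valid(reaction: Reaction, species_table: Mapping[str, Species]) -> None:
    violations = validate_reaction(reaction, species_table)
    if violations:
        raise ValueError(f"reaction {reaction.id!r} invalid: {'; '.join(violations)}")


# ---------------------------------------------------------------------------
# thermodynamics

def standard_gibbs(
    reaction: Reaction, species_table: Mapping[str, Species], T: float
) -> float:
    """Standard Gibbs energy of reaction at temperature ``T`` (kJ/mol).

    At 298.15 K this is the plain linear combination of formation energies.
    At other temperatures the Gibbs–Helmholtz relation with constant
    reaction enthalpy is applied:

        dG0(T) = (T/Tref) * dG0(Tref) + (1 - T/Tref) * dH0(Tref)
    """
    if T <= 273.0:
        raise ValueError("temperature must exceed 273 K")
    dG_ref = 0.0
    dH_ref = 0.0
    for name, coeff in reaction.stoichiometry.items():
        try:
            sp = species_table[name]
        except KeyError:
            raise UnknownSpeciesError(
                f"reaction {reaction.id!r}: unknown species {name!r}"
            ) from None
        dG_ref += coeff * sp.dGf0
        dH_ref += coeff * sp.dHf0
    ratio = T / T_REF
    return ratio * dG_ref + (1.0 - ratio) * dH_ref


def activity_coefficient(
    charge: int,
    ionic_strength: float,
    T: float = T_REF,
    model: str = "ideal",
) -> float:
    """Molal activity coefficient for a solute of the given charge.

    ``model="ideal"`` returns 1. ``model="davies"`` evaluates the Davies
    equation ``log10(gamma) = -A z^2 (sqrt(I)/(1+sqrt(I)) - 0.3 I)`` with
    A fixed at its 298.15 K value of 0.509; neutral species and zero ionic
    strength give gamma = 1.
    """
    if ionic_strength < 0:
        raise ValueError("ionic strength must be >= 0")
    if model == "ideal":
        return 1.0
    if model != "davies":
        raise ValueError(f"unknown activity model {model!r}")
    if charge == 0 or ionic_strength == 0:
        return 1.0
    sqrt_i = math.sqrt(ionic_strength)
    log10_gamma = -DAVIES_A * charge**2 * (sqrt_i / (1.0 + sqrt_i) - 0.3 * ionic_strength)
    return 10.0**log10_gamma


def _ln_activity(
    sp: Species, conditions: FluidConditions, reaction_id: str
) -> float:
    if sp.is_solvent:
        return 0.0  # a(H2O) = 1
    if sp.name == "H+":
        return -conditions.pH * math.log(10.0)
    try:
        m = conditions.concentrations[sp.name]
    except KeyError:
        raise KeyError(
            f"reaction {reaction_id!r}: no concentration for species "
            f"{sp.name!r} in conditions"
        ) from None
    gamma = activity_coefficient(
        sp.charge,
        conditions.ionic_strength,
        conditions.temperature,
        conditions.activity_model,
    )
    return math.log(gamma * m)


def reaction_quotient(
    reaction: Reaction,
    conditions: FluidConditions,
    species_table: Mapping[str, Species],
) -> float:
    """ln(Q) = sum over participants of nu_i * ln(a_i).

    Solute activities are gamma*m; the solvent contributes 1 and H+
    contributes ``10**-pH``.
    """
    ln_q = 0.0
    for name, coeff in reaction.stoichiometry.items():
        try:
            sp = species_table[name]
        except KeyError:
            raise UnknownSpeciesError(
                f"reaction {reaction.id!r}: unknown species {name!r}"
            ) from None
        ln_q += coeff * _ln_activity(sp, conditions, reaction.id)
    return ln_q


def gibbs_energy(
    reaction: Reaction,
    conditions: FluidConditions,
    species_table: Mapping[str, Species],
) -> EnergyResult:
    """In situ Gibbs energy of reaction: dG = dG0(T) + R*T*ln(Q)."""
    _require_valid(reaction, species_table)
    T = conditions.temperature
    dg0 = standard_gibbs(reaction, species_table, T)
    ln_q = reaction_quotient(reaction, conditions, species_table)
    dg = dg0 + R_KJ * T * ln_q
    return EnergyResult(
        reaction_id=reaction.id,
        temperature=T,
        dG0_T=dg0,
        lnQ=ln_q,
        dG=dg,
        dG_per_electron=dg / reaction.n_electrons,
    )


def sweep_donor(
    reaction: Reaction,
    conditions: FluidConditions,
    species_table: Mapping[str, Species],
    grid: Sequence[float],
) -> SweepResult:
    """Per-electron energy yield with the donor concentration swept over ``grid``.

    All other conditions are held fixed. The grid must be strictly positive
    and strictly increasing; the yield strictly decreases (becomes more
    exergonic) along it.
    """
    if len(grid) == 0:
        raise ValueError("empty donor grid")
    if any(g <= 0 for g in grid):
        raise ValueError("donor grid must be strictly positive")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("donor grid must be strictly increasing")
    results = tuple(
        gibbs_energy(reaction, conditions.with_concentration(reaction.donor, g),
                     species_table)
        for g in grid
    )
    return SweepResult(
        reaction_id=reaction.id,
        donor=reaction.donor,
        grid=tuple(grid),
        values=tuple(r.dG_per_electron for r in results),
        results=results,
    )


def rank_donors(
    reactions: Iterable[Reaction],
    conditions: FluidConditions,
    species_table: Mapping[str, Species],
    donor_concentration: float,
) -> list[tuple[str, float]]:
    """Rank reactions by per-electron yield at a matched donor concentration.

    Every reaction's donor is set to ``donor_concentration``; the result is
    ordered most exergonic (most negative) first, ties broken by reaction id.
    """
    rows = []
    for rxn in reactions:
        cond = conditions.with_concentration(rxn.donor, donor_concentration)
        res = gibbs_energy(rxn, cond, species_table)
        rows.append((rxn.id, res.dG_per_electron))
    return sorted(rows, key=lambda t: (t[1], t[0]))


# ---------------------------------------------------------------------------
# data loading

def _data_path(*parts: str):
    node = resources.files("crustbio.data")
    for part in parts:
        node = node.joinpath(part)
    return node


def parse_formula(text: str) -> dict[str, int]:
    """Parse the TSV formula encoding ``"C:1,O:2"`` into a dict."""
    out: dict[str, int] = {}
    for token in text.split(","):
        elem, _, count = token.partition(":")
        out[elem.strip()] = int(count)
    return out


def load_species_table(path: str | Path | None = None) -> dict[str, Species]:
    """Load a species table TSV (the shipped one when ``path`` is None)."""
    import pandas as pd

    if path is None:
        with _data_path("species.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    table: dict[str, Species] = {}
    for row in df.itertuples(index=False):
        table[row.name] = Species(
            name=row.name,
            formula=parse_formula(row.formula),
            charge=int(row.charge),
            phase=row.phase,
            dGf0=float(row.dGf0_kJ_mol),
            dHf0=float(row.dHf0_kJ_mol),
            source=str(row.source),
        )
    return table


def load_reactions(path: str | Path | None = None) -> dict[str, Reaction]:
    """Load reaction definitions from YAML (shipped set when ``path`` is None)."""
    src = _data_path("reactions.yaml") if path is None else Path(path)
    docs = yaml.safe_load(src.read_text())
    out: dict[str, Reaction] = {}
    for doc in docs:
        rxn = Reaction(
            id=doc["id"],
            stoichiometry={str(k): float(v) for k, v in doc["stoichiometry"].items()},
            n_electrons=int(doc["n_electrons"]),
            donor=doc["donor"],
            acceptor=doc["acceptor"],
        )
        if rxn.id in out:
            raise ValueError(f"duplicate reaction id {rxn.id!r}")
        out[rxn.id] = rxn
    return out


def load_conditions(profile: str | Path = "jdfr", **overrides) -> FluidConditions:
    """Load a fluid-condition profile by shipped name or from a YAML file.

    Keyword overrides replace top-level fields; ``concentrations`` overrides
    merge per species.
    """
    path = Path(profile)
    if not path.suffix:  # a shipped profile name
        res = _data_path("profiles", f"{profile}.yaml")
        if not res.is_file():
            known = sorted(
                p.name.removesuffix(".yaml")
                for p in _data_path("profiles").iterdir()
            )
            raise KeyError(
                f"unknown profile {profile!r}; known profiles: {', '.join(known)}"
            )
        doc = yaml.safe_load(res.read_text())
    else:
        doc = yaml.safe_load(path.read_text())
    conc = {str(k): float(v) for k, v in doc["concentrations"].items()}
    conc.update(overrides.pop("concentrations", {}))
    return FluidConditions(
        temperature=float(overrides.pop("temperature", doc["temperature_K"])),
        concentrations=conc,
        ionic_strength=float(overrides.pop("ionic_strength", doc["ionic_strength"])),
        pH=float(overrides.pop("pH", doc["pH"])),
        activity_model=overrides.pop("activity_model", doc["activity_model"]),
        name=doc.get("name", ""),
        **overrides,
    )
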