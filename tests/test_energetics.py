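"""Gibbs-energy engine: balances, temperature correction, activities,
reaction quotients, sweeps and donor ranking."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crustbio import energetics as en

R = en.R_KJ


# ---------------------------------------------------------------- oracles

def oracle_standard_gibbs_298(reaction, table):
    """Independent spreadsheet-style sum of formation energies."""
    total = 0.0
    for name in reaction.stoichiometry:
        total += reaction.stoichiometry[name] * table[name].dGf0
    return total


def oracle_ln_q_ideal(reaction, conditions, table):
    """Brute-force sum of nu*ln(m) with explicit solvent/proton handling."""
    total = 0.0
    for name, coeff in reaction.stoichiometry.items():
        if table[name].phase == "liquid-water":
            a = 1.0
        elif name == "H+":
            a = 10.0 ** (-conditions.pH)
        else:
            a = conditions.concentrations[name]
        total += coeff * math.log(a)
    return total


# ------------------------------------------------------------- validation

class TestValidateReaction:
    def test_balanced_co_sulfate(self, species_table):
        rxn = en.Reaction(
            "co", {"CO": -4, "SO4": -1, "H2O": -4, "HCO3": 4, "HS": 1, "H+": 3},
            n_electrons=8, donor="CO", acceptor="SO4",
        )
        assert en.validate_reaction(rxn, species_table) == []

    def test_unbalanced_reports_each_element(self, species_table):
        # CO + SO4 -> HCO3 + HS: H off by +2, O by -2; charge balances (-2/-2)
        rxn = en.Reaction(
            "bad", {"CO": -1, "SO4": -1, "HCO3": 1, "HS": 1},
            n_electrons=8, donor="CO", acceptor="SO4",
        )
        violations = en.validate_reaction(rxn, species_table)
        assert violations == ["element H unbalanced by 2",
                              "element O unbalanced by -2"]

    def test_unbalanced_charge_reported(self, species_table):
        rxn = en.Reaction(
            "bad2", {"H2": -1, "SO4": -1, "HS": 1},
            n_electrons=8, donor="H2", acceptor="SO4",
        )
        violations = en.validate_reaction(rxn, species_table)
        assert any("charge" in v for v in violations)

    def test_empty_stoichiometry(self, species_table):
        rxn = en.Reaction("empty", {}, n_electrons=1, donor="CO", acceptor="SO4")
        assert en.validate_reaction(rxn, species_table) == ["no species in stoichiometry"]

    def test_unknown_species_named_in_error(self, species_table):
        rxn = en.Reaction("x", {"unobtainium": -1}, n_electrons=1,
                          donor="unobtainium", acceptor="unobtainium")
        with pytest.raises(en.UnknownSpeciesError, match="unobtainium"):
            en.validate_reaction(rxn, species_table)

    def test_all_shipped_reactions_balanced(self, reactions, species_table):
        for rxn in reactions.values():
            assert en.validate_reaction(rxn, species_table) == []


# ---------------------------------------------------------- standard_gibbs

class TestStandardGibbs:
    def test_reference_temperature_is_linear_combination(
        self, toy_species, toy_reaction
    ):
        assert en.standard_gibbs(toy_reaction, toy_species, 298.15) == pytest.approx(
            -10.0, abs=1e-12
        )

    def test_gibbs_helmholtz_with_zero_reaction_enthalpy(
        self, toy_species, toy_reaction
    ):
        # equal dHf0 cancel, so dG0 scales as T/Tref
        got = en.standard_gibbs(toy_reaction, toy_species, 337.15)
        assert got == pytest.approx(337.15 / 298.15 * -10.0, abs=1e-9)
        assert got == pytest.approx(-11.308, abs=5e-4)

    def test_matches_summation_oracle_on_shipped_reactions(
        self, reactions, species_table
    ):
        for rxn in reactions.values():
            assert en.standard_gibbs(rxn, species_table, 298.15) == pytest.approx(
                oracle_standard_gibbs_298(rxn, species_table), abs=1e-9
            )

    def test_missing_species_raises_with_name(self, toy_reaction):
        table = {"A": en.Species("A", {"X": 1}, 0)}
        with pytest.raises(en.UnknownSpeciesError, match="'B'"):
            en.standard_gibbs(toy_reaction, table, 298.15)


# ---------------------------------------------------- activity_coefficient

class TestActivityCoefficient:
    @pytest.mark.parametrize(
        "charge,ionic_strength,expected",
        [
            (0, 0.7, 1.0),  # neutral species
            (-2, 0.0, 1.0),  # zero ionic strength
            # hand evaluation of the Davies closed form at z=-1, I=0.1:
            # log10(g) = -0.509*(sqrt(.1)/(1+sqrt(.1)) - 0.03) = -0.509*0.210253
            (-1, 0.1, 0.7815939439),
        ],
    )
    def test_davies_closed_form(self, charge, ionic_strength, expected):
        got = en.activity_coefficient(charge, ionic_strength, model="davies")
        assert got == pytest.approx(expected, abs=1e-9)

    def test_ideal_is_unity(self):
        assert en.activity_coefficient(-2, 0.7, model="ideal") == 1.0

    def test_negative_ionic_strength_rejected(self):
        with pytest.raises(ValueError):
            en.activity_coefficient(1, -0.1, model="davies")


# -------------------------------------------------------- reaction_quotient

class TestReactionQuotient:
    def test_unit_activities_give_zero(self, species_table):
        rxn = en.Reaction("h2", {"H2": -4, "SO4": -1, "H+": -1, "HS": 1, "H2O": 4},
                          n_electrons=8, donor="H2", acceptor="SO4")
        cond = en.FluidConditions(
            temperature=298.15, pH=0.0,
            concentrations={"H2": 1.0, "SO4": 1.0, "HS": 1.0},
        )
        assert en.reaction_quotient(rxn, cond, species_table) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_single_term_log(self, toy_species, toy_reaction):
        cond = en.FluidConditions(
            temperature=298.15, concentrations={"A": 1.0, "B": math.e}
        )
        assert en.reaction_quotient(toy_reaction, cond, toy_species) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_matches_brute_force_oracle_under_jdfr(
        self, reactions, species_table, jdfr
    ):
        for rxn in reactions.values():
            assert en.reaction_quotient(rxn, jdfr, species_table) == pytest.approx(
                oracle_ln_q_ideal(rxn, jdfr, species_table), abs=1e-9
            )

    def test_missing_concentration_names_species(self, species_table, jdfr):
        rxn = en.Reaction("co", {"CO": -4, "SO4": -1, "H2O": -4,
                                 "HCO3": 4, "HS": 1, "H+": 3},
                          n_electrons=8, donor="CO", acceptor="SO4")
        conc = {k: v for k, v in jdfr.concentrations.items() if k != "HS"}
        cond = en.FluidConditions(temperature=jdfr.temperature, pH=jdfr.pH,
                                  concentrations=conc)
        with pytest.raises(KeyError, match="HS"):
            en.reaction_quotient(rxn, cond, species_table)


# ------------------------------------------------------------ gibbs_energy

class TestGibbsEnergy:
    def test_equilibrium_lnq_zeroes_dG(self, reactions, species_table, jdfr):
        """dG vanishes when activities are tuned to the equilibrium quotient."""
        for rxn in reactions.values():
            T = jdfr.temperature
            dg0 = en.standard_gibbs(rxn, species_table, T)
            ln_q_eq = -dg0 / (R * T)
            dg = dg0 + R * T * ln_q_eq
            assert abs(dg) < 1e-9

    def test_unit_activities_reduce_to_standard(self, species_table):
        rxn = en.Reaction("ch4", {"CH4": -1, "SO4": -1, "HCO3": 1, "HS": 1, "H2O": 1},
                          n_electrons=8, donor="CH4", acceptor="SO4")
        cond = en.FluidConditions(
            temperature=310.0, pH=0.0,
            concentrations={"CH4": 1.0, "SO4": 1.0, "HCO3": 1.0, "HS": 1.0},
        )
        res = en.gibbs_energy(rxn, cond, species_table)
        assert res.lnQ == pytest.approx(0.0, abs=1e-12)
        assert res.dG == pytest.approx(res.dG0_T, abs=1e-12)

    @given(k=st.integers(min_value=1, max_value=6))
    @settings(deadline=None, max_examples=6)
    def test_scale_invariance_per_electron(self, k):
        """Doubling (k-fold) the written reaction leaves dG/e- unchanged."""
        species = en.load_species_table()
        jdfr = en.load_conditions("jdfr")
        rxn = en.load_reactions()["sulfate_co"]
        base = en.gibbs_energy(rxn, jdfr, species)
        scaled = en.gibbs_energy(rxn.scaled(k), jdfr, species)
        assert scaled.dG == pytest.approx(k * base.dG, abs=1e-9 * k)
        assert scaled.dG_per_electron == pytest.approx(
            base.dG_per_electron, abs=1e-9
        )

    def test_additivity_of_subreactions(self, species_table, jdfr):
        """dG of a summed reaction equals the sum of its parts' dG values."""
        rx = en.load_reactions()
        co, ch4 = rx["sulfate_co"], rx["sulfate_ch4"]
        combined_stoich = dict(co.stoichiometry)
        for name, coeff in ch4.stoichiometry.items():
            combined_stoich[name] = combined_stoich.get(name, 0) + coeff
        combined = en.Reaction("combined", combined_stoich, n_electrons=16,
                               donor="CO", acceptor="SO4")
        total = en.gibbs_energy(combined, jdfr, species_table)
        parts = (en.gibbs_energy(co, jdfr, species_table).dG
                 + en.gibbs_energy(ch4, jdfr, species_table).dG)
        assert total.dG == pytest.approx(parts, abs=1e-9)

    def test_energy_result_identity(self, reactions, species_table, jdfr):
        for rxn in reactions.values():
            res = en.gibbs_energy(rxn, jdfr, species_table)
            assert res.dG == pytest.approx(
                res.dG0_T + R * jdfr.temperature * res.lnQ, abs=1e-12
            )
            assert res.dG_per_electron == pytest.approx(
                res.dG / rxn.n_electrons, abs=1e-12
            )


# ------------------------------------------------------------- sweep_donor

class TestSweepDonor:
    def test_closed_form_decrement_over_four_decades(
        self, reactions, species_table, jdfr
    ):
        """CO sweep 10 nM -> 100 uM drops by -nu_d*R*T*ln(1e4)/n_e."""
        rxn = reactions["sulfate_co"]
        sweep = en.sweep_donor(rxn, jdfr, species_table, [1e-8, 1e-4])
        expected = -(4 * R * 337.15 * math.log(1e4)) / 8
        assert expected == pytest.approx(-12.909310, abs=1e-6)
        assert sweep.values[1] - sweep.values[0] == pytest.approx(expected, abs=1e-6)

    def test_single_point_consistent_with_gibbs_energy(
        self, reactions, species_table, jdfr
    ):
        rxn = reactions["sulfate_h2"]
        base = jdfr.concentrations["H2"]
        sweep = en.sweep_donor(rxn, jdfr, species_table, [base])
        direct = en.gibbs_energy(rxn, jdfr, species_table)
        assert sweep.values[0] == pytest.approx(direct.dG_per_electron, abs=1e-12)

    @given(
        g1=st.floats(min_value=1e-9, max_value=1e-3),
        ratio=st.floats(min_value=1.01, max_value=1e4),
    )
    @settings(deadline=None, max_examples=25)
    def test_strictly_decreasing_in_donor_concentration(self, g1, ratio):
        species = en.load_species_table()
        jdfr = en.load_conditions("jdfr")
        rxn = en.load_reactions()["sulfate_acetate"]
        sweep = en.sweep_donor(rxn, jdfr, species, [g1, g1 * ratio])
        assert sweep.values[1] < sweep.values[0]

    def test_empty_and_bad_grids_rejected(self, reactions, species_table, jdfr):
        rxn = reactions["sulfate_co"]
        with pytest.raises(ValueError):
            en.sweep_donor(rxn, jdfr, species_table, [])
        with pytest.raises(ValueError):
            en.sweep_donor(rxn, jdfr, species_table, [1e-6, 1e-7])


# ------------------------------------------------------------- rank_donors

class TestRankDonors:
    def test_co_most_exergonic_across_sweep_range(
        self, reactions, species_table, jdfr
    ):
        """CO-driven sulfate reduction wins per electron at every matched
        donor concentration across the in situ sweep range."""
        for conc in np.geomspace(1e-8, 1e-4, 9):
            ranking = en.rank_donors(
                reactions.values(), jdfr, species_table, float(conc)
            )
            assert ranking[0][0] == "sulfate_co"

    def test_singleton_list(self, reactions, species_table, jdfr):
        ranking = en.rank_donors(
            [reactions["sulfate_ch4"]], jdfr, species_table, 1e-6
        )
        assert [r for r, _ in ranking] == ["sulfate_ch4"]

    def test_tie_broken_lexicographically(self, reactions, species_table, jdfr):
        import dataclasses

        rxn = reactions["sulfate_co"]
        a = dataclasses.replace(rxn, id="a")
        b = dataclasses.replace(rxn, id="b")
        ranking = en.rank_donors([b, a], jdfr, species_table, 1e-6)
        assert [r for r, _ in ranking] == ["a", "b"]


# ------------------------------------------------------------ data loading

class TestDataLoading:
    def test_jdfr_profile_fields(self, jdfr):
        assert jdfr.temperature == pytest.approx(337.15)
        assert jdfr.concentrations["SO4"] == pytest.approx(0.018)
        assert jdfr.activity_model == "ideal"

    def test_unknown_profile_lists_known(self):
        with pytest.raises(KeyError, match="jdfr"):
            en.load_conditions("atlantis_massif")

    def test_override_merges_concentrations(self):
        cond = en.load_conditions("jdfr", concentrations={"SO4": 0.028})
        assert cond.concentrations["SO4"] == pytest.approx(0.028)
        assert "HS" in cond.concentrations

    def test_species_invariants_enforced(self):
        with pytest.raises(ValueError):
            en.Species("bad", {}, 0)
        with pytest.raises(ValueError):
            en.Species("bad", {"C": -1}, 0)

    def test_conditions_invariants_enforced(self):
        with pytest.raises(ValueError):
            en.FluidConditions(temperature=270.0, concentrations={"SO4": 1.0})
        with pytest.raises(ValueError):
            en.FluidConditions(temperature=300.0, concentrations={"SO4": 0.0})
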