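"""Reaction algebra, thermodynamic conversions and the derived constant chain."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from aurox.constants import DEFAULT
from aurox.db import load_database
from aurox.derivation import gold_oxidation_chain
from aurox.formula import FormulaError, parse_formula
from aurox.thermo import (
    Reaction,
    ThermoError,
    check_balance,
    combine_reactions,
    delta_g_from_hs,
    delta_g_from_logk,
    gibbs_from_potential,
    half_reaction_split,
    logk_from_delta_g,
    nernst_boundary,
    potential_from_gibbs,
)


class TestFormula:
    @pytest.mark.parametrize(
        "formula, expected",
        [
            ("Au(OH)4", {"Au": 1, "O": 4, "H": 4}),
            ("H2O", {"H": 2, "O": 1}),
            ("S2O3", {"S": 2, "O": 3}),
            ("", {}),
            ("CH4", {"C": 1, "H": 4}),
        ],
    )
    def test_parse(self, formula, expected):
        assert parse_formula(formula) == expected

    def test_rejects_garbage(self):
        with pytest.raises(FormulaError):
            parse_formula("Au(OH")


class TestBalance:
    def test_superoxide_reaction_balances(self, db):
        rxn = Reaction.from_equation("Au(s) + O2- + 4 H+ = Au3+ + 2 H2O(l)")
        report = check_balance(rxn, db.species)
        assert report.ok
        assert report.charge_delta == 0

    def test_empty_reaction_is_balanced(self, db):
        report = check_balance(Reaction({}), db.species)
        assert report.ok and not report.element_deltas

    def test_missing_proton_detected(self, db):
        rxn = Reaction.from_equation("Au(s) + O2- + 3 H+ = Au3+ + 2 H2O(l)")
        report = check_balance(rxn, db.species)
        assert not report.ok
        assert report.element_deltas["H"] == 1  # products have one extra H
        assert report.charge_delta == 1

    def test_unknown_species_raises(self, db):
        with pytest.raises(ThermoError, match="unknown species"):
            check_balance(Reaction.from_equation("Xx = Au(s)"), db.species)

    def test_whole_database_balances(self, db):
        reports = db.validate()
        bad = {rid for rid, rep in reports.items() if not rep.ok}
        assert not bad

    def test_half_reactions_balance_via_electron(self, db):
        # half reactions only balance because e- carries charge -1
        assert check_balance(db.reaction("R7"), db.species).ok
        assert check_balance(db.reaction("R8"), db.species).ok


class TestConversions:
    @pytest.mark.parametrize(
        "dH, dS, T, expected",
        [
            (-122.82, -359.74, 298.0, -15.62),  # published reaction-level sums
            (-50.0, 0.0, 298.0, -50.0),
            (0.0, -100.0, 298.0, 29.80),
        ],
    )
    def test_gibbs_from_enthalpy_entropy(self, dH, dS, T, expected):
        assert delta_g_from_hs(dH, dS, T) == pytest.approx(expected, abs=0.005)

    @pytest.mark.parametrize(
        "dG, expected",
        [(-15.62, 2.74), (0.0, 0.0), (-5.70585, 1.00)],
    )
    def test_logk_from_gibbs(self, dG, expected):
        assert logk_from_delta_g(dG) == pytest.approx(expected, abs=0.005)

    @pytest.mark.parametrize(
        "n, E0, expected",
        [(3, -1.52, 440.0), (2, 0.0, 0.0), (1, 1.0, -96.49)],
    )
    def test_gibbs_from_potential(self, n, E0, expected):
        assert gibbs_from_potential(n, E0) == pytest.approx(expected, abs=0.05)

    @pytest.mark.parametrize(
        "dG, n, expected",
        [(-455.62, 3, 1.57), (0.0, 2, 0.0), (-96.49, 1, 1.00)],
    )
    def test_potential_from_gibbs(self, dG, n, expected):
        assert potential_from_gibbs(dG, n) == pytest.approx(expected, abs=0.005)

    def test_zero_electron_couple_rejected(self):
        with pytest.raises(ThermoError):
            potential_from_gibbs(-100.0, 0)

    @given(st.floats(-500, 500), st.floats(250, 350))
    @settings(max_examples=50, deadline=None)
    def test_logk_gibbs_round_trip(self, dG, T):
        assert delta_g_from_logk(logk_from_delta_g(dG, T), T) == pytest.approx(
            dG, abs=1e-9
        )

    @given(st.floats(-3, 3), st.integers(1, 8))
    @settings(max_examples=50, deadline=None)
    def test_potential_gibbs_round_trip(self, E0, n):
        assert potential_from_gibbs(gibbs_from_potential(n, E0), n) == pytest.approx(
            E0, abs=1e-12
        )


class TestCombination:
    def test_superoxide_route_to_hydroxide_complex(self, db):
        net = combine_reactions(
            [(db.reaction("R3"), 1), (db.reaction("R4"), 1), (db.reaction("R5"), 4)]
        )
        assert net.logK == pytest.approx(-1.91, abs=0.005)
        assert net.stoich == db.reaction("R1").stoich

    def test_dioxygen_route(self, db):
        net = combine_reactions(
            [(db.reaction("R6"), 1), (db.reaction("R4"), 1), (db.reaction("R5"), 4)]
        )
        assert net.logK == pytest.approx(-16.09, abs=0.005)
        assert net.stoich == db.reaction("R2").stoich

    def test_self_cancellation(self, db):
        r5 = db.reaction("R5")
        net = combine_reactions([(r5, 1), (r5, -1)])
        assert net.is_empty()
        assert net.logK == pytest.approx(0.0, abs=1e-12)

    def test_missing_logk_rejected(self, db):
        bare = Reaction.from_equation("H2O(l) = H+ + OH-")
        with pytest.raises(ThermoError, match="no logK"):
            combine_reactions([(bare, 1)])

    @given(st.floats(-50, 50), st.floats(-50, 50))
    @settings(max_examples=30, deadline=None)
    def test_hess_additivity(self, ka, kb):
        a = Reaction.from_equation("Au(s) + O2- + 4 H+ = Au3+ + 2 H2O(l)", logK=ka)
        b = Reaction.from_equation("H2O(l) = H+ + OH-", logK=kb)
        net = combine_reactions([(a, 1), (b, 1), (b, -1)])
        assert net.stoich == a.stoich
        assert net.logK == pytest.approx(ka, abs=1e-12)

    def test_fractional_coefficients_parse_and_scale(self):
        from fractions import Fraction

        r = Reaction.from_equation(
            "Au(s) + 0.75 O2(aq) + 2.5 H2O(l) = Au(OH)4- + H+", logK=-16.09
        )
        assert r.stoich["O2(aq)"] == Fraction(-3, 4)
        quadrupled = combine_reactions([(r, 4)])
        assert quadrupled.stoich["O2(aq)"] == Fraction(-3)
        assert quadrupled.logK == pytest.approx(4 * -16.09)


class TestHalfReactions:
    def test_couple_split_recovers_superoxide_half(self, db):
        dg = half_reaction_split(
            db.reaction("R3"),
            (db.reaction("R7"), db.reaction("R8")),
            dG_rxn=-15.62,
            dG_known=440.00,
        )
        assert dg == pytest.approx(-455.62, abs=0.005)

    def test_zero_known_half_carries_everything(self, db):
        dg = half_reaction_split(
            db.reaction("R3"),
            (db.reaction("R7"), db.reaction("R8")),
            dG_rxn=-15.62,
            dG_known=0.0,
        )
        assert dg == pytest.approx(-15.62)

    def test_mismatched_halves_rejected(self, db):
        with pytest.raises(ThermoError, match="do not sum"):
            half_reaction_split(
                db.reaction("R1"),
                (db.reaction("R7"), db.reaction("R8")),
                dG_rxn=-1.0,
                dG_known=0.0,
            )


class TestNernstBoundary:
    def test_superoxide_water_line_coefficients(self, db):
        line = nernst_boundary(db.reaction("R8"))
        assert line.ph_coeff == pytest.approx(4.0)
        assert line.eh_coeff == pytest.approx(50.7, abs=0.1)
        assert line.rhs == pytest.approx(79.84)

    def test_line_endpoints(self, db):
        line = nernst_boundary(db.reaction("R8"))
        assert float(line.eh_at_ph(0.0)) == pytest.approx(1.57, abs=0.005)
        assert float(line.eh_at_ph(14.0)) == pytest.approx(0.47, abs=0.005)

    def test_slope(self, db):
        line = nernst_boundary(db.reaction("R8"))
        assert line.slope == pytest.approx(-4 / 50.7, abs=1e-3)

    def test_non_redox_reaction_rejected(self, db):
        with pytest.raises(ThermoError, match="not a redox"):
            nernst_boundary(db.reaction("R5"))


class TestDerivationChain:
    """The full derivation reproduces every published intermediate."""

    def test_chain_end_to_end(self, db):
        chain = gold_oxidation_chain(db)
        assert chain["dG_r3"] == pytest.approx(-15.62, abs=0.005)
        assert chain["logK_r3"] == pytest.approx(2.74, abs=0.005)
        assert chain["logK_r1"] == pytest.approx(-1.91, abs=0.005)
        assert chain["logK_r2"] == pytest.approx(-16.09, abs=0.005)
        assert chain["dG_au0_au3"] == pytest.approx(440.00, abs=0.05)
        assert chain["dG_o2m_h2o"] == pytest.approx(-455.62, abs=0.05)
        # rounding of intermediate published values propagates here
        assert chain["logK0_o2m_h2o"] == pytest.approx(79.84, abs=0.1)
        assert chain["E0_o2m_h2o"] == pytest.approx(1.57, abs=0.005)
        assert chain["line_ph_coeff"] == pytest.approx(4.0)
        assert chain["line_eh_coeff"] == pytest.approx(50.7, abs=0.1)
        assert chain["eh_ph0"] == pytest.approx(1.57, abs=0.005)
        assert chain["eh_ph14"] == pytest.approx(0.47, abs=0.005)
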