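"""Equilibrium reaction algebra for gold redox geochemistry.

This module is the engine behind every derived constant in the package: it
models chemical species and reactions, combines reactions under Hess's law
(log K values add with their multipliers), converts between Gibbs energy,
equilibrium constant and standard potential, and turns redox half reactions
into straight boundary lines in (pH, Eh) space via the Nernst relation

    h*pH + n*(F/(2.303*R*T))*Eh = log K

for a half reaction releasing ``h`` protons and ``n`` electrons.

Electrons are carried as an explicit pseudo-species ``e-`` (charge -1, no
elements) so that half reactions pass the same element/charge balance check
as full reactions.  Stoichiometric coefficients are exact rationals, so
combination cancels species exactly rather than to rounding error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from .constants import DEFAULT, ThermoConstants
from .formula import parse_formula

ELECTRON = "e-"

Phase = str
_PHASES = ("solid", "liquid", "gas", "aqueous")


class ThermoError(ValueError):
    """Raised for chemically inconsistent input (unknown species, bad halves...)."""


@dataclass(frozen=True)
class ThermoSpecies:
    """A chemical species with composition and optional standard-state data.

    Parameters
    ----------
    name : str
        Identifier used in reaction equations (e.g. ``"Au(OH)4-"``).
    formula : str
        Elemental formula without charge (e.g. ``"Au(OH)4"``); may be empty
        for the electron pseudo-species.
    charge : int
        Signed electric charge.
    phase : str
        One of ``solid``, ``liquid``, ``gas``, ``aqueous``.
    dHf : float, optional
        Standard formation enthalpy, kJ mol^-1.
    S0 : float, optional
        Standard entropy, J mol^-1 K^-1.
    """

    name: str
    formula: str
    charge: int
    phase: Phase
    dHf: float | None = None
    S0: float | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.phase not in _PHASES:
            raise ThermoError(f"{self.name}: phase {self.phase!r} not in {_PHASES}")

    @property
    def elements(self) -> dict[str, int]:
        return parse_formula(self.formula)


#: The electron pseudo-species: charge -1, no elements.
ELECTRON_SPECIES = ThermoSpecies(ELECTRON, "", -1, "aqueous", note="pseudo-species")


def _as_fraction(x) -> Fraction:
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    if isinstance(x, float):
        return Fraction(x).limit_denominator(10**6)
    if isinstance(x, str):
        return Fraction(x)
    raise TypeError(f"cannot interpret {x!r} as a stoichiometric coefficient")


@dataclass
class Reaction:
    """A reaction as signed stoichiometry over species names.

    ``stoich`` maps species name -> signed rational coefficient; negative
    coefficients are reactants, positive are products.  ``logK`` is the
    decadic equilibrium constant at 298 K (None until known or derived).
    ``n_electrons`` is the number of electron equivalents transferred for
    redox (half) reactions; 0 for non-redox reactions.
    """

    stoich: dict[str, Fraction]
    logK: float | None = None
    n_electrons: Fraction = Fraction(0)
    label: str = ""
    note: str = ""

    def __post_init__(self) -> None:
        self.stoich = {
            name: _as_fraction(c) for name, c in self.stoich.items() if c != 0
        }
        self.n_electrons = _as_fraction(self.n_electrons)

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_sides(
        cls,
        reactants: Mapping[str, object],
        products: Mapping[str, object],
        **kw,
    ) -> "Reaction":
        stoich: dict[str, Fraction] = {}
        for name, c in reactants.items():
            stoich[name] = stoich.get(name, Fraction(0)) - _as_fraction(c)
        for name, c in products.items():
            stoich[name] = stoich.get(name, Fraction(0)) + _as_fraction(c)
        return cls(stoich, **kw)

    @classmethod
    def from_equation(cls, equation: str, **kw) -> "Reaction":
        """Parse ``"Au(s) + O2- + 4 H+ = Au3+ + 2 H2O(l)"`` style strings.

        Coefficients may be integers, decimals (``0.75``) or fractions
        (``3/4``); terms are separated by `` + `` (spaces required, so that
        charge suffixes like ``Au3+`` survive).
        """
        if equation.count("=") != 1:
            raise ThermoError(f"equation needs exactly one '=': {equation!r}")
        lhs, rhs = equation.split("=")
        return cls.from_sides(_parse_side(lhs), _parse_side(rhs), **kw)

    # -- presentation ------------------------------------------------------
    @property
    def reactants(self) -> dict[str, Fraction]:
        return {n: -c for n, c in self.stoich.items() if c < 0}

    @property
    def products(self) -> dict[str, Fraction]:
        return {n: c for n, c in self.stoich.items() if c > 0}

    def equation(self) -> str:
        def side(terms: dict[str, Fraction]) -> str:
            if not terms:
                return "0"
            parts = []
            for name, c in terms.items():
                if c == 1:
                    parts.append(name)
                elif c.denominator == 1:
                    parts.append(f"{c.numerator} {name}")
                else:
                    parts.append(f"{float(c):g} {name}")
            return " + ".join(parts)

        return f"{side(self.reactants)} = {side(self.products)}"

    def is_empty(self) -> bool:
        return not self.stoich

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        k = f", logK={self.logK:g}" if self.logK is not None else ""
        return f"<Reaction {self.label or self.equation()}{k}>"


def _parse_side(side: str) -> dict[str, Fraction]:
    terms: dict[str, Fraction] = {}
    side = side.strip()
    if side in ("", "0"):
        return terms
    for term in side.split(" + "):
        term = term.strip()
        if not term:
            continue
        tokens = term.split(None, 1)
        coeff = Fraction(1)
        name = term
        if len(tokens) == 2:
            try:
                coeff = _as_fraction(
                    Fraction(tokens[0]) if "/" in tokens[0] else float(tokens[0])
                )
                name = tokens[1].strip()
            except ValueError:
                pass
        terms[name] = terms.get(name, Fraction(0)) + coeff
    return terms


# ---------------------------------------------------------------------------
# balance checking
# ---------------------------------------------------------------------------

@dataclass
class BalanceReport:
    element_deltas: dict[str, Fraction]
    charge_delta: Fraction
    ok: bool

    def __bool__(self) -> bool:
        return self.ok


def check_balance(
    rxn: Reaction, species: Mapping[str, ThermoSpecies]
) -> BalanceReport:
    """Element and charge balance of ``rxn`` (products minus reactants).

    The electron pseudo-species contributes charge -1 and no elements, so
    half reactions balance too.  Unknown species raise :class:`ThermoError`.
    """
    elements: dict[str, Fraction] = {}
    charge = Fraction(0)
    for name, coeff in rxn.stoich.items():
        if name == ELECTRON:
            sp = ELECTRON_SPECIES
        elif name in species:
            sp = species[name]
        else:
            raise ThermoError(f"unknown species {name!r} in reaction {rxn.label or rxn.equation()!r}")
        charge += coeff * sp.charge
        for el, n in sp.elements.items():
            elements[el] = elements.get(el, Fraction(0)) + coeff * n
    elements = {el: d for el, d in elements.items() if d != 0}
    ok = not elements and charge == 0
    return BalanceReport(elements, charge, ok)


# ---------------------------------------------------------------------------
# thermodynamic conversions
# ---------------------------------------------------------------------------

def delta_g_from_hs(
    dH: float, dS: float, T: float | None = None, constants: ThermoConstants = DEFAULT
) -> float:
    """Gibbs energy of reaction from enthalpy and entropy: dG = dH - T*dS.

    ``dH`` in kJ mol^-1, ``dS`` in J mol^-1 K^-1; result in kJ mol^-1.
    """
    T = constants.T if T is None else T
    if T <= 0:
        raise ThermoError("temperature must be positive")
    return dH - T * dS / 1000.0


def logk_from_delta_g(
    dG: float, T: float | None = None, constants: ThermoConstants = DEFAULT
) -> float:
    """log10 K from Gibbs energy (kJ mol^-1): dG = -2.303*R*T*logK."""
    T = constants.T if T is None else T
    if T <= 0:
        raise ThermoError("temperature must be positive")
    return -dG * 1000.0 / (constants.ln10 * constants.R * T)


def delta_g_from_logk(
    logK: float, T: float | None = None, constants: ThermoConstants = DEFAULT
) -> float:
    """Inverse of :func:`logk_from_delta_g`; result in kJ mol^-1."""
    T = constants.T if T is None else T
    return -logK * (constants.ln10 * constants.R * T) / 1000.0


def gibbs_from_potential(
    n: float, E0: float, constants: ThermoConstants = DEFAULT
) -> float:
    """dG0 = -n*F*E0 for a couple transferring ``n`` equivalents (kJ mol^-1)."""
    if n <= 0:
        raise ThermoError("electron count must be positive")
    return -n * constants.F * E0


def potential_from_gibbs(
    dG: float, n: float, constants: ThermoConstants = DEFAULT
) -> float:
    """E0 = -dG/(n*F); inverse of :func:`gibbs_from_potential`."""
    if n <= 0:
        raise ThermoError("electron count must be positive")
    return -dG / (n * constants.F)


# ---------------------------------------------------------------------------
# Hess-law combination and half-reaction arithmetic
# ---------------------------------------------------------------------------

def combine_reactions(
    terms: Sequence[tuple[Reaction, object]], label: str = ""
) -> Reaction:
    """Linear combination of reactions: stoichiometries and log K values add.

    Each term is ``(reaction, multiplier)`` with a rational multiplier (may
    be negative to reverse a reaction).  Species that cancel are dropped
    exactly.  Every input must carry a ``logK``.
    """
    stoich: dict[str, Fraction] = {}
    logk = 0.0
    n_el = Fraction(0)
    for rxn, mult in terms:
        if rxn.logK is None:
            raise ThermoError(
                f"reaction {rxn.label or rxn.equation()!r} has no logK; cannot combine"
            )
        m = _as_fraction(mult)
        for name, c in rxn.stoich.items():
            stoich[name] = stoich.get(name, Fraction(0)) + m * c
        logk += float(m) * rxn.logK
        n_el += m * rxn.n_electrons
    out = Reaction(stoich, logK=logk, label=label)
    # electron count of a combination is meaningful only if electrons appear
    # explicitly; fall back to the explicit e- coefficient.
    out.n_electrons = abs(out.stoich.get(ELECTRON, Fraction(0)))
    return out


def half_reaction_split(
    rxn: Reaction,
    halves: tuple[Reaction, Reaction],
    dG_rxn: float,
    dG_known: float,
    known: int = 0,
) -> float:
    """Gibbs energy of the unknown half of a redox couple.

    ``halves`` must sum (with electron cancellation) to ``rxn``; ``dG_known``
    is the Gibbs energy of ``halves[known]``.  Returns dG of the other half
    as ``dG_rxn - dG_known`` after validating the decomposition.
    """
    a, b = halves
    total: dict[str, Fraction] = {}
    for h in (a, b):
        for name, c in h.stoich.items():
            total[name] = total.get(name, Fraction(0)) + c
    total = {n: c for n, c in total.items() if c != 0}
    if total != rxn.stoich:
        raise ThermoError(
            "half reactions do not sum to the full reaction: "
            f"{Reaction(total).equation()} != {rxn.equation()}"
        )
    if known not in (0, 1):
        raise ThermoError("known must be 0 or 1")
    return dG_rxn - dG_known


# ---------------------------------------------------------------------------
# Nernst boundary lines
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoundaryLine:
    """The straight line ``ph_coeff*pH + eh_coeff*Eh = rhs`` in (pH, Eh).

    For a reduction half reaction consuming ``h`` protons and ``n``
    electrons, ``ph_coeff = h``, ``eh_coeff = n*F/(2.303*R*T)`` (in V^-1)
    and ``rhs = logK``.
    """

    ph_coeff: float
    eh_coeff: float
    rhs: float

    def eh_at_ph(self, ph):
        if self.eh_coeff == 0:
            raise ThermoError("line has no Eh dependence (eh_coeff = 0)")
        import numpy as _np

        return (self.rhs - self.ph_coeff * _np.asarray(ph)) / self.eh_coeff

    @property
    def slope(self) -> float:
        """dEh/dpH in V per pH unit."""
        return -self.ph_coeff / self.eh_coeff


def nernst_boundary(
    half: Reaction, constants: ThermoConstants = DEFAULT
) -> BoundaryLine:
    """Boundary line of a redox half reaction written as a reduction.

    Uses the half reaction's explicit stoichiometry: ``h`` is the number of
    protons consumed, ``n`` the electrons consumed, and ``logK`` its
    equilibrium constant, giving ``h*pH + n*(F/(2.303RT))*Eh = logK`` at
    unit activity of the redox partners.
    """
    if half.logK is None:
        raise ThermoError("half reaction needs a logK")
    n = -half.stoich.get(ELECTRON, Fraction(0))
    if n <= 0:
        n = half.n_electrons
    if n <= 0:
        raise ThermoError("not a redox boundary: no electrons transferred")
    h = -half.stoich.get("H+", Fraction(0))
    return BoundaryLine(float(h), float(n) * constants.eh_factor, half.logK)
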