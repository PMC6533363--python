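"""End-to-end derivation of the superoxide gold-oxidation constant chain.

Starting only from the reaction-level inputs stored in the database —
the enthalpy/entropy sums of the low-pH superoxide reaction (R3), the
Au(III) hydroxide complexation constant (R4), water autoionization (R5),
the dioxygen analogue (R6) and the standard potential of the Au0/Au3+
couple (R7) — this derives, in order:

* dG and log K of R3 (dG = dH - T dS, then dG = -2.303 R T log K),
* log K of the superoxide and dioxygen routes to Au(OH)4- (Hess
  combinations R3+R4+4*R5 and R6+R4+4*R5),
* the Gibbs energy of each half couple (dG0 = -nFE0 for Au0/Au3+, the
  remainder for superoxide/water),
* log K0 and E0 of the superoxide/water couple, and
* its Nernst boundary line in (pH, Eh) with the endpoints at pH 0 and 14.

The same arithmetic route is exercised by the validation suite against the
independently published values of every intermediate.
"""

from __future__ import annotations

from dataclasses import replace

from .constants import DEFAULT, ThermoConstants
from .db import Database, load_database
from .thermo import (
    combine_reactions,
    delta_g_from_hs,
    gibbs_from_potential,
    half_reaction_split,
    logk_from_delta_g,
    nernst_boundary,
)


def gold_oxidation_chain(
    db: Database | None = None, constants: ThermoConstants = DEFAULT
) -> dict[str, float]:
    """Derive the full constant chain; returns a name -> value mapping.

    Keys (units): ``dG_r3`` (kJ/mol), ``logK_r3``, ``logK_r1``, ``logK_r2``,
    ``dG_au0_au3`` (kJ/mol), ``dG_o2m_h2o`` (kJ/mol), ``logK0_o2m_h2o``,
    ``E0_o2m_h2o`` (V), ``line_ph_coeff``, ``line_eh_coeff`` (V^-1),
    ``eh_ph0`` and ``eh_ph14`` (V).
    """
    db = load_database() if db is None else db

    rec3 = db.record("R3")
    if rec3.drH is None or rec3.drS is None:
        raise ValueError("R3 record must carry reaction-level drH and drS")
    dg3 = delta_g_from_hs(rec3.drH, rec3.drS, constants=constants)
    logk3 = logk_from_delta_g(dg3, constants=constants)

    r3 = replace(rec3.reaction, logK=logk3)
    r4 = db.reaction("R4")
    r5 = db.reaction("R5")
    r6 = db.reaction("R6")
    r1 = combine_reactions([(r3, 1), (r4, 1), (r5, 4)], label="R1")
    r2 = combine_reactions([(r6, 1), (r4, 1), (r5, 4)], label="R2")

    rec7 = db.record("R7")
    if rec7.E0 is None:
        raise ValueError("R7 record must carry the couple's E0")
    # E0 is stored for the oxidation as written; dG0 = -n F E0 gives +440 kJ.
    n = float(rec7.reaction.n_electrons)
    dg_au = gibbs_from_potential(n, rec7.E0, constants=constants)
    dg_o2 = half_reaction_split(
        r3, (db.reaction("R7"), db.reaction("R8")), dg3, dg_au, known=0
    )
    logk0 = logk_from_delta_g(dg_o2, constants=constants)
    e0 = -dg_o2 / (n * constants.F)

    r8 = replace(db.reaction("R8"), logK=logk0)
    line = nernst_boundary(r8, constants=constants)

    return {
        "dG_r3": dg3,
        "logK_r3": logk3,
        "logK_r1": r1.logK,
        "logK_r2": r2.logK,
        "dG_au0_au3": dg_au,
        "dG_o2m_h2o": dg_o2,
        "logK0_o2m_h2o": logk0,
        "E0_o2m_h2o": e0,
        "line_ph_coeff": line.ph_coeff,
        "line_eh_coeff": line.eh_coeff,
        "eh_ph0": float(line.eh_at_ph(0.0)),
        "eh_ph14": float(line.eh_at_ph(14.0)),
    }
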