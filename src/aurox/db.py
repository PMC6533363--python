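"""Species/reaction database: tab-separated text, shipped defaults, round trips.

The database is two TSV tables: one species per row (name, formula, charge,
phase, dHf, S0, note) and one reaction per row (id, equation string, logK,
n_electrons, drH, drS, E0, note).  Equation strings use `` + ``-separated
terms with optional rational coefficients (``0.75 O2(aq)``), and an explicit
``e-`` pseudo-species for half reactions.

The shipped default database contains the printed reaction chain for
superoxide-driven gold oxidation (ids ``R1``..``R8``) plus editable
formation reactions (ids ``F:<species>``) used by the Eh-pH predominance
module.  Formation reactions produce one mole of the target species from the
anchor species of its subsystem (bicarbonate, thiosulfate or metallic gold)
plus H+, e- and water.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .thermo import Reaction, ThermoError, ThermoSpecies, check_balance

_SPECIES_COLS = ["name", "formula", "charge", "phase", "dHf", "S0", "note"]
_REACTION_COLS = ["id", "equation", "logK", "n_electrons", "drH", "drS", "E0", "note"]


@dataclass
class ReactionRecord:
    """A database reaction plus optional reaction-level thermodynamic sums."""

    reaction: Reaction
    drH: float | None = None  # kJ/mol
    drS: float | None = None  # J/mol/K
    E0: float | None = None  # V; sign convention recorded in the note


@dataclass
class Database:
    species: dict[str, ThermoSpecies] = field(default_factory=dict)
    reactions: dict[str, ReactionRecord] = field(default_factory=dict)

    def reaction(self, rid: str) -> Reaction:
        try:
            return self.reactions[rid].reaction
        except KeyError:
            raise ThermoError(f"no reaction {rid!r} in database") from None

    def record(self, rid: str) -> ReactionRecord:
        try:
            return self.reactions[rid]
        except KeyError:
            raise ThermoError(f"no reaction {rid!r} in database") from None

    def formation_reaction(self, species_name: str) -> Reaction:
        """Formation reaction (id ``F:<name>``) of a species, for speciation."""
        return self.reaction(f"F:{species_name}")

    def validate(self) -> dict[str, object]:
        """Balance-check every reaction; returns {id: BalanceReport}."""
        return {
            rid: check_balance(rec.reaction, self.species)
            for rid, rec in self.reactions.items()
        }


def _opt_float(value: str | None) -> float | None:
    if value is None or value.strip() == "":
        return None
    return float(value)


def read_species(text: str) -> dict[str, ThermoSpecies]:
    out: dict[str, ThermoSpecies] = {}
    for row in csv.DictReader(io.StringIO(text), delimiter="\t"):
        sp = ThermoSpecies(
            name=row["name"].strip(),
            formula=row.get("formula", "").strip(),
            charge=int(row["charge"]),
            phase=row["phase"].strip(),
            dHf=_opt_float(row.get("dHf")),
            S0=_opt_float(row.get("S0")),
            note=row.get("note", "").strip(),
        )
        out[sp.name] = sp
    return out


def read_reactions(text: str) -> dict[str, ReactionRecord]:
    out: dict[str, ReactionRecord] = {}
    for row in csv.DictReader(io.StringIO(text), delimiter="\t"):
        rid = row["id"].strip()
        logk = _opt_float(row.get("logK"))
        n_el = row.get("n_electrons", "").strip() or "0"
        rxn = Reaction.from_equation(
            row["equation"], logK=logk, n_electrons=n_el, label=rid,
            note=row.get("note", "").strip(),
        )
        out[rid] = ReactionRecord(
            rxn,
            drH=_opt_float(row.get("drH")),
            drS=_opt_float(row.get("drS")),
            E0=_opt_float(row.get("E0")),
        )
    return out


def load_database(
    species_path: str | Path | None = None,
    reactions_path: str | Path | None = None,
) -> Database:
    """Load a database from TSV files; defaults to the shipped tables."""
    data_dir = resources.files("aurox") / "data"
    if species_path is None:
        sp_text = (data_dir / "species.tsv").read_text()
    else:
        sp_text = Path(species_path).read_text()
    if reactions_path is None:
        rx_text = (data_dir / "reactions.tsv").read_text()
    else:
        rx_text = Path(reactions_path).read_text()
    return Database(read_species(sp_text), read_reactions(rx_text))


def write_species(species: dict[str, ThermoSpecies], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_SPECIES_COLS)
        for sp in species.values():
            w.writerow(
                [sp.name, sp.formula, sp.charge, sp.phase,
                 "" if sp.dHf is None else sp.dHf,
                 "" if sp.S0 is None else sp.S0, sp.note]
            )


def write_reactions(reactions: dict[str, ReactionRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_REACTION_COLS)
        for rid, rec in reactions.items():
            r = rec.reaction
            w.writerow(
                [rid, r.equation(),
                 "" if r.logK is None else r.logK,
                 r.n_electrons,
                 "" if rec.drH is None else rec.drH,
                 "" if rec.drS is None else rec.drS,
                 "" if rec.E0 is None else rec.E0,
                 r.note]
            )
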