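"""Eh-pH (Pourbaix) predominance diagrams for gold in C- and S-rich systems.

The diagram is built in two stages, mirroring how mosaic predominance
diagrams are drawn in geochemical modelling practice:

1. *Ligand subsystem*: the predominant carbon species (CH4, C(s), CO2(aq),
   HCO3-, CO3--) or sulfur species (H2S, HS-, S(s), HSO4-, SO4--, S2O3--)
   is resolved at every (pH, Eh) cell, with the subsystem anchored at a
   total ligand activity of 0.01.
2. *Gold speciation*: with the predominant ligand fixed (and rescaled to
   the anchor activity), the dissolved gold species in equilibrium with
   metallic gold are evaluated; a cell belongs to Au(s) when no dissolved
   species reaches the requested activity level (solubility contour logic
   at 1 ppm / 1 ppb / 1 ppt), otherwise to the most active dissolved
   species.

Stability is compared per mole of the subsystem element using the
equal-activity convention: dissolved species are assigned the anchor
activity, solids and water unit activity, and the species whose equilibrium
activity (per element atom) is highest predominates.  Ionic-strength
corrections are deliberately omitted.  All equilibrium constants come from
the formation reactions (``F:<species>``) of the reaction database and are
editable there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import DEFAULT, ThermoConstants
from .db import Database, load_database
from .derivation import gold_oxidation_chain
from .formula import parse_formula
from .thermo import ELECTRON, BoundaryLine, Reaction, ThermoError

AU_MOLAR_MASS = 196.97  # g/mol

#: Mass-fraction solubility levels in water (density 1 kg/L): grams of Au
#: per gram of solution.
_LEVELS = {"ppm": 1e-6, "ppb": 1e-9, "ppt": 1e-12}

#: Decade log-activities conventionally attached to the levels.
_LEVEL_DECADES = {"ppm": -6.0, "ppb": -9.0, "ppt": -12.0}

LIGAND_SETS = {
    "carbon": {
        "anchor": "HCO3-",
        "element": "C",
        "species": ["CH4(aq)", "C(s)", "CO2(aq)", "HCO3-", "CO3--"],
        "au_species": ["Au3+", "Au+", "AuOH(aq)", "Au(OH)2-", "Au(OH)4-"],
    },
    "sulfur": {
        "anchor": "S2O3--",
        "element": "S",
        "species": ["H2S(aq)", "HS-", "S(s)", "HSO4-", "SO4--", "S2O3--"],
        "au_species": [
            "Au3+", "Au+", "AuOH(aq)", "Au(OH)2-", "Au(OH)4-",
            "AuHS(aq)", "Au(HS)2-",
        ],
    },
}


def mass_fraction_to_log_activity(level: str | float) -> float:
    """log10 molal activity of dissolved Au at a named mass-fraction level.

    ``level`` may be ``"ppt"``/``"ppb"``/``"ppm"`` (converted through the Au
    molar mass, e.g. 1 ppb -> log a = -8.29) or a direct numeric activity
    (e.g. ``1e-6`` -> -6.0 exactly).
    """
    if isinstance(level, str):
        key = level.strip().lower()
        if key not in _LEVELS:
            raise ValueError(f"unknown level {level!r}; use ppt/ppb/ppm or a number")
        grams_per_kg = _LEVELS[key] * 1000.0
        return float(np.log10(grams_per_kg / AU_MOLAR_MASS))
    if level <= 0:
        raise ValueError("activity override must be positive")
    return float(np.log10(level))


@dataclass
class PourbaixSystem:
    """Configuration of one diagram (ligand chemistry, activities, grid)."""

    ligand_system: str = "carbon"
    ligand_log_activity: float = -2.0
    #: activity levels as {name: log10 activity}, ordered ppm -> ppt
    au_activity_levels: dict[str, float] = field(
        default_factory=lambda: dict(_LEVEL_DECADES)
    )
    ph_range: tuple[float, float] = (0.0, 14.0)
    eh_range: tuple[float, float] = (-0.8, 1.6)
    ph_step: float = 0.05
    eh_step: float = 0.005
    constants: ThermoConstants = DEFAULT

    def __post_init__(self) -> None:
        if self.ligand_system not in LIGAND_SETS:
            raise ValueError(f"ligand_system must be one of {sorted(LIGAND_SETS)}")
        if self.ph_step <= 0 or self.eh_step <= 0:
            raise ValueError("grid steps must be positive")
        levels = list(self.au_activity_levels.values())
        if any(b >= a for a, b in zip(levels, levels[1:])):
            raise ValueError("activity levels must be strictly decreasing (ppm->ppt)")

    @property
    def config(self) -> dict:
        return LIGAND_SETS[self.ligand_system]

    def ph_axis(self) -> np.ndarray:
        lo, hi = self.ph_range
        n = int(round((hi - lo) / self.ph_step)) + 1
        return lo + self.ph_step * np.arange(n)

    def eh_axis(self) -> np.ndarray:
        lo, hi = self.eh_range
        n = int(round((hi - lo) / self.eh_step)) + 1
        return lo + self.eh_step * np.arange(n)


@dataclass
class PredominanceField:
    """Labeled (pH, Eh) grid: ligand stage plus Au stage per activity level."""

    system: PourbaixSystem
    ph: np.ndarray              # (n_ph,)
    eh: np.ndarray              # (n_eh,)
    ligand_labels: np.ndarray   # (n_eh, n_ph) array of species names
    au_labels: dict[str, np.ndarray]  # level name -> (n_eh, n_ph)
    overlay_lines: dict[str, BoundaryLine]

    def boundaries(self) -> pd.DataFrame:
        """Midpoints between unequal-label neighbours, per stage, as a table."""
        rows = []
        stages = {"ligand": self.ligand_labels}
        stages.update({f"au_{lvl}": lab for lvl, lab in self.au_labels.items()})
        for stage, lab in stages.items():
            dif = lab[:, :-1] != lab[:, 1:]
            jj, ii = np.nonzero(dif)
            for j, i in zip(jj, ii):
                rows.append(
                    (stage, (self.ph[i] + self.ph[i + 1]) / 2, self.eh[j],
                     lab[j, i], lab[j, i + 1])
                )
            dif = lab[:-1, :] != lab[1:, :]
            jj, ii = np.nonzero(dif)
            for j, i in zip(jj, ii):
                rows.append(
                    (stage, self.ph[i], (self.eh[j] + self.eh[j + 1]) / 2,
                     lab[j, i], lab[j + 1, i])
                )
        return pd.DataFrame(rows, columns=["stage", "ph", "eh", "label_a", "label_b"])

    def to_frame(self) -> pd.DataFrame:
        """Long-format grid table: one row per cell."""
        PH, EH = np.meshgrid(self.ph, self.eh)
        data = {"ph": PH.ravel(), "eh": EH.ravel(),
                "ligand": self.ligand_labels.ravel()}
        for lvl, lab in self.au_labels.items():
            data[f"au_{lvl}"] = lab.ravel()
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# equilibrium activity evaluation
# ---------------------------------------------------------------------------

def _formation_terms(
    db: Database, name: str, anchors: dict[str, float]
) -> tuple[float, float, float, float, float]:
    """Decompose ``F:name`` into (logK, cH, cE, anchor_part, nu_element).

    The equilibrium log activity of the species over a grid is then
    ``(logK + cH*pH + cE*pe - anchor_part) / nu`` where ``nu`` is the
    species' stoichiometric coefficient in its formation reaction.
    """
    rxn = db.formation_reaction(name)
    nu = rxn.stoich.get(name)
    if nu is None or nu <= 0:
        raise ThermoError(f"formation reaction for {name!r} must produce it")
    if rxn.logK is None:
        raise ThermoError(f"formation reaction for {name!r} has no logK")
    c_h = c_e = anchor_part = 0.0
    for sp, coeff in rxn.stoich.items():
        if sp == name:
            continue
        c = float(coeff)
        if sp == "H+":
            c_h += c
        elif sp == ELECTRON:
            c_e += c
        elif sp in anchors:
            anchor_part += c * anchors[sp]
        else:
            sp_rec = db.species.get(sp)
            if sp_rec is None:
                raise ThermoError(f"species {sp!r} missing from database")
            if sp_rec.phase not in ("solid", "liquid"):
                raise ThermoError(
                    f"species {sp!r} in formation of {name!r} has no anchored activity"
                )
    return rxn.logK, c_h, c_e, anchor_part, float(nu)


def _element_count(db: Database, name: str, element: str) -> int:
    return parse_formula(db.species[name].formula).get(element, 0)


class _DiagramEngine:
    """Vectorised two-stage evaluation over a (pe, pH) grid."""

    def __init__(self, system: PourbaixSystem, db: Database | None = None):
        self.system = system
        self.db = load_database() if db is None else db
        self.cfg = system.config

    def ligand_stability(self, PH, PE):
        """Per-atom stability of each ligand species; dict name -> array."""
        db, cfg = self.db, self.cfg
        anchor = cfg["anchor"]
        la = self.system.ligand_log_activity
        anchors = {anchor: la}
        out = {}
        for name in cfg["species"]:
            n_el = _element_count(db, name, cfg["element"])
            if name == anchor:
                log_a = np.broadcast_to(np.float64(la), np.shape(PH))
            else:
                logk, c_h, c_e, anchor_part, nu = _formation_terms(db, name, anchors)
                log_a = (logk + c_h * PH + c_e * PE - anchor_part) / nu
            assigned = 0.0 if db.species[name].phase == "solid" else la
            out[name] = (log_a - assigned) / n_el
        return out

    def ligand_labels(self, PH, PE):
        stab = self.ligand_stability(PH, PE)
        names = list(stab)
        stack = np.stack([stab[n] for n in names])
        idx = np.argmax(stack, axis=0)  # first max wins: database order ties
        return np.asarray(names, dtype=object)[idx], stab

    def au_log_activity(self, PH, PE, delta):
        """Equilibrium log activity of each dissolved Au species vs Au(s)."""
        db, cfg = self.db, self.cfg
        element = cfg["element"]
        anchors = {cfg["anchor"]: self.system.ligand_log_activity}
        # ligand species that may complex gold (currently HS-) are anchored
        # at their stage-one activity plus the predominance shift.
        lig_act = {}
        if self.system.ligand_system == "sulfur":
            stab = self.ligand_stability(PH, PE)
            la = self.system.ligand_log_activity
            lig_act["HS-"] = stab["HS-"] * 1.0 + la + delta  # nu_S = 1
        out = {}
        for name in cfg["au_species"]:
            rxn = db.formation_reaction(name)
            logk, c_h, c_e, anchor_part, nu = _formation_terms(
                db, name, {**anchors, **{k: 0.0 for k in lig_act}}
            )
            log_a = (logk + c_h * PH + c_e * PE - anchor_part) / nu
            for lig, act in lig_act.items():
                c = float(rxn.stoich.get(lig, 0))
                if c:
                    # reactant ligand (c < 0) raises the complex's activity
                    log_a = log_a - c * act / nu
            out[name] = log_a
        return out

    def au_labels(self, PH, PE, delta, log_a_level):
        acts = self.au_log_activity(PH, PE, delta)
        names = list(acts)
        stack = np.stack([np.broadcast_to(a, np.shape(PH)) for a in acts.values()])
        idx = np.argmax(stack, axis=0)
        best = np.take_along_axis(stack, idx[None], axis=0)[0]
        labels = np.asarray(names, dtype=object)[idx]
        return np.where(best < log_a_level, "Au(s)", labels)


def ligand_predominance(
    system: PourbaixSystem, ph: float, eh: float, db: Database | None = None
) -> str:
    """Predominant ligand-subsystem species at one (pH, Eh) point."""
    eng = _DiagramEngine(system, db)
    pe = eh * system.constants.eh_factor
    labels, _ = eng.ligand_labels(np.asarray([ph]), np.asarray([pe]))
    return str(labels[0])


def au_predominance(
    system: PourbaixSystem,
    ph: float,
    eh: float,
    log_a_au: float,
    db: Database | None = None,
) -> str:
    """Predominant Au species at one point and dissolved-activity threshold."""
    eng = _DiagramEngine(system, db)
    pe = np.asarray([eh * system.constants.eh_factor])
    PH = np.asarray([ph])
    labels, stab = eng.ligand_labels(PH, pe)
    names = list(stab)
    stack = np.stack([stab[n] for n in names])
    delta = -np.max(stack, axis=0)
    return str(eng.au_labels(PH, pe, delta, log_a_au)[0])


def build_diagram(
    system: PourbaixSystem, db: Database | None = None
) -> PredominanceField:
    """Evaluate both stages over the full grid and attach overlay lines."""
    db = load_database() if db is None else db
    eng = _DiagramEngine(system, db)
    ph = system.ph_axis()
    eh = system.eh_axis()
    PH, EH = np.meshgrid(ph, eh)
    PE = EH * system.constants.eh_factor

    lig_labels, stab = eng.ligand_labels(PH, PE)
    stack = np.stack([stab[n] for n in stab])
    delta = -np.max(stack, axis=0)

    au = {
        lvl: eng.au_labels(PH, PE, delta, log_a)
        for lvl, log_a in system.au_activity_levels.items()
    }

    chain = gold_oxidation_chain(db, system.constants)
    f = system.constants.eh_factor
    overlays = {
        "O2-/H2O": BoundaryLine(4.0, 3.0 * f, chain["logK0_o2m_h2o"]),
        "O2/H2O": BoundaryLine(4.0, 4.0 * f, 4.0 * f * 1.228),
        "H2O/H2": BoundaryLine(2.0, 2.0 * f, 0.0),
    }
    return PredominanceField(system, ph, eh, lig_labels, au, overlays)


def export_diagram(
    field: PredominanceField, prefix: str | Path, plot: bool = False
) -> list[Path]:
    """Write the grid and boundary tables (TSV); optionally a PNG figure.

    Returns the list of files written.  ``<prefix>_grid.tsv`` re-imports to
    the exact same labels via :func:`pandas.read_csv`.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    files = []
    grid_path = prefix.with_name(prefix.name + "_grid.tsv")
    field.to_frame().to_csv(grid_path, sep="\t", index=False)
    files.append(grid_path)
    b_path = prefix.with_name(prefix.name + "_boundaries.tsv")
    field.boundaries().to_csv(b_path, sep="\t", index=False)
    files.append(b_path)
    if plot:  # pragma: no cover - optional plotting
        files.append(_plot(field, prefix.with_name(prefix.name + ".png")))
    return files


def _plot(field: PredominanceField, path: Path) -> Path:  # pragma: no cover
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    first_level = next(iter(field.au_labels))
    lab = field.au_labels[first_level]
    names = sorted(set(lab.ravel()))
    codes = np.searchsorted(np.asarray(names, dtype=object), lab)
    ax.pcolormesh(field.ph, field.eh, codes, shading="nearest", cmap="Pastel1")
    for name, line in field.overlay_lines.items():
        ax.plot(field.ph, line.eh_at_ph(field.ph), "--", lw=1, label=name)
    ax.set(xlabel="pH", ylabel="Eh (V)",
           xlim=field.system.ph_range, ylim=field.system.eh_range,
           title=f"Au predominance ({field.system.ligand_system} system, "
                 f"{first_level})")
    ax.legend(loc="upper right", fontsize=8)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
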