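"""End-to-end driver: simulate -> analyze -> report for each analysis track.

Tracks: ``thermo`` (the derived constant chain), ``pourbaix`` (both
predominance diagrams), ``kinetics`` (calibration + rate/correlation
analysis of simulated anomaly and reference microcosms), ``ecology``
(diversity, hotspot, correlation and network statistics of a simulated
survey), or ``all``.  Every output file carries a provenance header
(version, config hash, seed) and all randomness is funnelled through the
single configured seed, so a repeated run is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .db import Database, load_database
from .derivation import gold_oxidation_chain
from .ecology import (
    build_network,
    classify_hotspots,
    diversity_gold_correlation,
    diversity_table,
    export_network,
    greedy_modules,
    stress_centrality,
)
from .kinetics import (
    absorbance_to_au3,
    correlate_au3_ph,
    fit_phase_rate,
    fit_standard_curve,
    percent_oxidized,
)
from .pourbaix import PourbaixSystem, build_diagram, export_diagram
from .synthetic import (
    CommunityScenario,
    MicrocosmScenario,
    gen_microcosm,
    gen_otu_table,
    gen_standard_curve,
)

TRACKS = ("thermo", "pourbaix", "kinetics", "ecology")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Declarative run configuration; see ``RunConfig.from_yaml``."""

    track: str = "all"
    seed: int = 0
    outdir: str | Path = "aurox_out"
    species_db: str | None = None
    reactions_db: str | None = None
    pourbaix_grid: tuple[float, float] = (0.05, 0.005)
    kinetics_windows: tuple = ((0.0, 45.0), (191.0, 453.0))
    correlation_window: tuple[float, float] = (45.0, 191.0)
    network_prevalence: int = 7
    network_threshold: float = 0.8
    network_level: str | None = "order"
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.track != "all" and self.track not in TRACKS:
            raise PipelineError(f"track must be one of {TRACKS + ('all',)}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("pourbaix_grid", "correlation_window"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        if "kinetics_windows" in raw:
            raw["kinetics_windows"] = tuple(tuple(w) for w in raw["kinetics_windows"])
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("outdir")
        payload = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _header(config: RunConfig) -> str:
    return (
        f"# aurox {__version__}\n"
        f"# config_hash {config.config_hash()}\n"
        f"# seed {config.seed}\n"
    )


def _write_table(frame: pd.DataFrame, path: Path, config: RunConfig, index=True):
    with open(path, "w") as fh:
        fh.write(_header(config))
        frame.to_csv(fh, sep="\t", index=index)


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------

def run_thermo(config: RunConfig, db: Database, outdir: Path) -> dict:
    chain = gold_oxidation_chain(db)
    frame = pd.Series(chain, name="value").round(4).to_frame()
    _write_table(frame, outdir / "thermo_chain.tsv", config)
    return {"chain": {k: round(v, 4) for k, v in chain.items()}}


def run_pourbaix(config: RunConfig, db: Database, outdir: Path) -> dict:
    out = {}
    ph_step, eh_step = config.pourbaix_grid
    for system_name in ("carbon", "sulfur"):
        system = PourbaixSystem(
            ligand_system=system_name, ph_step=ph_step, eh_step=eh_step
        )
        f = build_diagram(system, db)
        files = export_diagram(f, outdir / f"pourbaix_{system_name}")
        for p in files:  # prepend provenance
            text = p.read_text()
            p.write_text(_header(config) + text)
        counts = {
            lvl: int(np.sum(lab == "Au(s)")) for lvl, lab in f.au_labels.items()
        }
        out[system_name] = {
            "ligand_species": sorted(set(f.ligand_labels.ravel())),
            "au_solid_cells": counts,
            "files": [p.name for p in files],
        }
    return out


def run_kinetics(config: RunConfig, outdir: Path) -> dict:
    curve_tbl = gen_standard_curve(noise_sd=0.005, seed=config.seed)
    curve = fit_standard_curve(
        curve_tbl["concentration_uM"], curve_tbl["absorbance"]
    )
    out = {
        "standard_curve": {
            "slope_AU_per_uM": curve.slope,
            "intercept_AU": curve.intercept,
            "r2": curve.r2,
        }
    }
    scenarios = {
        "anomaly_fungal": MicrocosmScenario(
            condition="anomaly_fungal", noise_sd=config.noise_sd, seed=config.seed
        ),
        "reference_fungal": MicrocosmScenario(
            condition="reference_fungal",
            phase_windows=((0.0, 45.0, 0.07),),
            anchors=((119.0, 5.68), (693.0, 5.68)),
            ph_gain=0.0,
            noise_sd=config.noise_sd,
            seed=config.seed + 1,
        ),
    }
    for name, scenario in scenarios.items():
        res = gen_microcosm(scenario)
        _write_table(
            res.tidy, outdir / f"microcosm_{name}.tsv", config, index=False
        )
        s = res.series
        fits = {
            f"{int(w[0])}-{int(w[1])}h": fit_phase_rate(s, w)
            for w in config.kinetics_windows
            if np.sum((s.times >= w[0]) & (s.times <= w[1])) >= 2
        }
        t_max, pct = percent_oxidized(s)
        entry = {
            "phase_rates_uM_per_h": {k: f.rate for k, f in fits.items()},
            "t_max_h": t_max,
            "percent_oxidized": pct,
        }
        try:
            r, p = correlate_au3_ph(s, config.correlation_window)
            entry["au3_ph_pearson"] = {"r": r, "p": p}
        except Exception:
            entry["au3_ph_pearson"] = None
        out[name] = entry
    return out


def run_ecology(config: RunConfig, outdir: Path) -> dict:
    res = gen_otu_table(CommunityScenario(seed=config.seed))
    table = res.table
    div = diversity_table(table)
    _write_table(div, outdir / "diversity.tsv", config)
    corr = diversity_gold_correlation(table)
    _write_table(corr, outdir / "diversity_gold_correlation.tsv", config)
    hot, thr = classify_hotspots(table.site_meta)
    net = build_network(
        table,
        sites=table.area_sites("anomaly"),
        min_prevalence=config.network_prevalence,
        threshold=config.network_threshold,
        level=config.network_level,
    )
    out = {
        "hotspot_threshold_ng_g": thr,
        "n_hotspots": int(hot.sum()),
        "correlation": {
            g: {"r": row["r"], "p": row["p"], "significant": bool(row["significant"])}
            for g, row in corr.iterrows()
        },
        "network": {
            "n_nodes": net.graph.number_of_nodes(),
            "n_edges": net.graph.number_of_edges(),
        },
    }
    if net.graph.number_of_edges() > 0:
        modules, q = greedy_modules(net)
        cent = stress_centrality(net)
        out["network"]["n_modules"] = len(set(modules.values()))
        out["network"]["modularity"] = q
        out["network"]["max_stress_node"] = max(cent, key=cent.get)
        files = export_network(net, outdir / "network")
        for p in files:
            if p.suffix == ".tsv":
                p.write_text(_header(config) + p.read_text())
        out["network"]["files"] = [p.name for p in files]
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured track(s); returns and writes the report bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    db = load_database(config.species_db, config.reactions_db)
    balance = db.validate()
    bad = [rid for rid, rep in balance.items() if not rep.ok]
    if bad:
        raise PipelineError(f"database reactions fail balance check: {bad}")

    tracks = TRACKS if config.track == "all" else (config.track,)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "tracks": {},
    }
    for track in tracks:
        try:
            if track == "thermo":
                report["tracks"][track] = run_thermo(config, db, outdir)
            elif track == "pourbaix":
                report["tracks"][track] = run_pourbaix(config, db, outdir)
            elif track == "kinetics":
                report["tracks"][track] = run_kinetics(config, outdir)
            elif track == "ecology":
                report["tracks"][track] = run_ecology(config, outdir)
        except Exception as exc:  # noqa: BLE001 - stage name + cause
            raise PipelineError(f"track {track!r} failed: {exc}") from exc

    with open(outdir / "results.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    _write_summary(report, outdir / "summary.txt", config)
    return report


def _write_summary(report: dict, path: Path, config: RunConfig) -> None:
    lines = [_header(config).rstrip()]
    for track, res in report["tracks"].items():
        lines.append(f"\n[{track}]")
        if track == "thermo":
            for k, v in res["chain"].items():
                lines.append(f"  {k:16s} {v:10.4f}")
        elif track == "pourbaix":
            for system_name, r in res.items():
                lines.append(
                    f"  {system_name}: ligand fields {r['ligand_species']}, "
                    f"Au(s) cells {r['au_solid_cells']}"
                )
        elif track == "kinetics":
            for cond, r in res.items():
                if cond == "standard_curve":
                    lines.append(
                        f"  calibration slope {r['slope_AU_per_uM']:.4f} AU/uM "
                        f"(r2 {r['r2']:.4f})"
                    )
                else:
                    rates = ", ".join(
                        f"{k}: {v:.3f}" for k, v in r["phase_rates_uM_per_h"].items()
                    )
                    lines.append(
                        f"  {cond}: rates [{rates}] uM/h; "
                        f"peak {r['percent_oxidized']:.1f}% at {r['t_max_h']:.0f} h"
                    )
        elif track == "ecology":
            for g, c in res["correlation"].items():
                flag = "+" if c["significant"] else "-"
                lines.append(
                    f"  {g}: r={c['r']:.3f} p={c['p']:.4f} [{flag}]"
                )
            lines.append(
                f"  hotspot threshold {res['hotspot_threshold_ng_g']:.2f} ng/g "
                f"({res['n_hotspots']} hotspots); network: {res['network']}"
            )
    path.write_text("\n".join(lines) + "\n")
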