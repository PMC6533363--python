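"""Seeded generators emulating the study's three data streams.

Every generator is a pure function of its scenario and seed and returns the
generated data together with a *truth record* of the parameters that
produced it, so downstream estimators can be validated by parameter
recovery.

* :func:`gen_microcosm` - two-phase piecewise-linear Au(III) trajectories
  sampled at the microcosm sampling times, with Gaussian replicate noise
  (clipped at 0) and a pH profile co-varying with Au(III) inside the rate
  change window.
* :func:`gen_otu_table` - a two-area site x OTU survey: log-normal soil
  gold with a heavier-tailed anomaly area forming hotspots, per-site target
  diversity coupled to gold in the anomaly only, and multinomial counts
  over a geometric rank-abundance profile with Dirichlet overdispersion.
* :func:`gen_standard_curve` - noisy colorimetric calibration points.
* :func:`gen_toy_network` - deterministic small graphs for network oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .ecology import CooccurrenceNetwork, OtuTable
from .kinetics import MicrocosmSeries

#: Sampling schedule of the fungal/sterile microcosms, hours.
MICROCOSM_TIMES = (0.0, 17.0, 45.0, 119.0, 191.0, 310.0, 453.0, 693.0)

#: Standard-curve concentrations, uM.
CURVE_CONCENTRATIONS = (2.0, 3.0, 10.0, 20.0, 30.0)

_ORDERS = [
    ("Hypocreales", "Ascomycota"),
    ("Pleosporales", "Ascomycota"),
    ("Capnodiales", "Ascomycota"),
    ("Chaetothyriales", "Ascomycota"),
    ("Eurotiales", "Ascomycota"),
    ("Helotiales", "Ascomycota"),
    ("Dothideales", "Ascomycota"),
    ("Agaricales", "Basidiomycota"),
    ("Russulales", "Basidiomycota"),
    ("Atheliales", "Basidiomycota"),
]


# ---------------------------------------------------------------------------
# microcosm time series
# ---------------------------------------------------------------------------

@dataclass
class MicrocosmScenario:
    """Generator settings for one microcosm condition.

    ``phase_windows`` are (t_start, t_end, slope uM/h) segments of linear
    Au(III) production; ``anchors`` are extra (t, Au(III)) control points
    (peaks, declines); between control points the trajectory interpolates
    linearly, and it holds the last value ("plateau") where nothing is
    specified.  The default emulates a gold-anomaly fungal microcosm: a
    fast first phase (0.19 uM/h to 45 h), a peak of 13.44 uM at 119 h
    (33.6% of the 40 uM spike), a slow second phase (0.01 uM/h, 191-453 h)
    and a terminal decline toward the reference plateau.
    """

    condition: str = "anomaly_fungal"
    phase_windows: tuple = ((0.0, 45.0, 0.19), (191.0, 453.0, 0.01))
    anchors: tuple = ((119.0, 13.44), (191.0, 9.0), (693.0, 5.68))
    sampling_times: tuple = MICROCOSM_TIMES
    start_au3: float = 0.0
    noise_sd: float = 1.0          # uM, replicate noise
    ph_base: float = 5.0
    ph_gain: float = 0.1           # pH units per uM inside the coupled window
    ph_window: tuple = (45.0, 191.0)
    ph_noise_sd: float = 0.05
    replicates: int = 3
    total_au: float = 40.0         # uM spiked metallic gold
    seed: int = 0

    def __post_init__(self) -> None:
        w = sorted(self.phase_windows)
        for (a0, a1, _), (b0, _, _) in zip(w, w[1:]):
            if b0 < a1:
                raise ValueError("phase windows must be ordered and non-overlapping")
        if self.noise_sd < 0 or self.ph_noise_sd < 0:
            raise ValueError("noise sd must be non-negative")

    def true_au3(self, t) -> np.ndarray:
        """Noise-free Au(III) trajectory at times ``t``."""
        knots: list[tuple[float, float]] = [(min(self.sampling_times), self.start_au3)]
        events = sorted(
            [("window", w) for w in self.phase_windows]
            + [("anchor", a) for a in self.anchors],
            key=lambda e: (e[1][0], e[0] == "window"),
        )
        def value_at(time: float) -> float:
            ts = [k[0] for k in knots]
            vs = [k[1] for k in knots]
            return float(np.interp(time, ts, vs))

        for kind, ev in events:
            if kind == "anchor":
                t0, v = ev
                knots = [k for k in knots if k[0] != t0] + [(t0, v)]
            else:
                t0, t1, slope = ev
                v0 = value_at(t0)
                knots = [k for k in knots if k[0] not in (t0, t1)]
                knots += [(t0, v0), (t1, v0 + slope * (t1 - t0))]
            knots.sort()
        ts = [k[0] for k in knots]
        vs = [k[1] for k in knots]
        return np.interp(np.asarray(t, dtype=float), ts, vs)

    def true_ph(self, t) -> np.ndarray:
        """Noise-free pH: base plus gain x Au(III) inside the coupled window."""
        t = np.asarray(t, dtype=float)
        w0, w1 = self.ph_window
        t_eff = np.clip(t, w0, w1)
        return self.ph_base + self.ph_gain * self.true_au3(t_eff)


@dataclass
class MicrocosmResult:
    series: MicrocosmSeries
    tidy: pd.DataFrame
    truth: dict


def gen_microcosm(scenario: MicrocosmScenario) -> MicrocosmResult:
    """Generate one microcosm condition; deterministic for a fixed seed."""
    rng = np.random.default_rng(scenario.seed)
    t = np.asarray(scenario.sampling_times, dtype=float)
    au_true = scenario.true_au3(t)
    ph_true = scenario.true_ph(t)
    rows = []
    for rep in range(1, scenario.replicates + 1):
        au = np.clip(au_true + rng.normal(0, scenario.noise_sd, t.size), 0, None)
        ph = ph_true + rng.normal(0, scenario.ph_noise_sd, t.size)
        for ti, ai, pi in zip(t, au, ph):
            rows.append((scenario.condition, rep, ti, ai, pi))
    tidy = pd.DataFrame(
        rows, columns=["condition", "replicate", "time_h", "au3_uM", "ph"]
    )
    series = MicrocosmSeries.from_tidy(
        tidy, scenario.condition, total_au=scenario.total_au
    )
    truth = asdict(scenario)
    truth["au3_true"] = au_true.tolist()
    truth["ph_true"] = ph_true.tolist()
    return MicrocosmResult(series, tidy, truth)


# ---------------------------------------------------------------------------
# calibration curves
# ---------------------------------------------------------------------------

def gen_standard_curve(
    slope: float = 0.02,
    intercept: float = 0.01,
    noise_sd: float = 0.0,
    concs=CURVE_CONCENTRATIONS,
    seed: int = 0,
) -> pd.DataFrame:
    """Calibration table: absorbance = slope*c + intercept + N(0, noise_sd)."""
    if noise_sd < 0:
        raise ValueError("noise sd must be non-negative")
    rng = np.random.default_rng(seed)
    c = np.asarray(concs, dtype=float)
    a = slope * c + intercept + rng.normal(0, noise_sd, c.size)
    return pd.DataFrame({"concentration_uM": c, "absorbance": a})


# ---------------------------------------------------------------------------
# two-area OTU survey
# ---------------------------------------------------------------------------

@dataclass
class CommunityScenario:
    """Two-area soil survey generator settings.

    Soil gold is log-normal per area; the anomaly area is heavier-tailed so
    that some sites exceed 1.5x the area median (hotspots).  Per-site
    target inverse Simpson diversity is a log-linear function of
    standardised log-gold with strength ``coupling`` (correlation-like, in
    [-1, 1]) in each area; compositions follow a geometric rank-abundance
    profile solved to hit the target diversity, drawn through a Dirichlet
    (overdispersion) and a multinomial (sampling depth).
    """

    n_sites: dict = field(default_factory=lambda: {"anomaly": 10, "reference": 9})
    n_otus: int = 120
    gold_log_median: dict = field(
        default_factory=lambda: {"anomaly": np.log(3.54), "reference": np.log(1.2)}
    )
    gold_log_sd: dict = field(
        default_factory=lambda: {"anomaly": 1.0, "reference": 0.5}
    )
    coupling: dict = field(default_factory=lambda: {"anomaly": 0.95, "reference": 0.0})
    diversity_log_mean: float = np.log(8.0)
    diversity_log_sd: float = 0.45
    depth: int = 20000
    dispersion: float = 200.0  # Dirichlet concentration; larger = less noise
    ph_mean: float = 5.6
    ph_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_sites.values()):
            raise ValueError("site counts must be positive")
        if not all(-1 <= c <= 1 for c in self.coupling.values()):
            raise ValueError("coupling must lie in [-1, 1]")
        if np.exp(self.diversity_log_mean) >= self.n_otus:
            raise ValueError("mean diversity target exceeds the OTU pool")


def _geometric_profile(n: int, target_d: float) -> np.ndarray:
    """Geometric rank-abundance p_i ~ q^i with inverse Simpson = target_d."""
    target_d = float(np.clip(target_d, 1.0 + 1e-9, n * 0.999))

    def inv_simpson_of_q(q: float) -> float:
        p = q ** np.arange(n)
        p = p / p.sum()
        return 1.0 / np.sum(p**2)

    q = brentq(lambda q: inv_simpson_of_q(q) - target_d, 1e-12, 1 - 1e-12)
    p = q ** np.arange(n)
    return p / p.sum()


@dataclass
class CommunityResult:
    table: OtuTable
    truth: dict


def gen_otu_table(scenario: CommunityScenario) -> CommunityResult:
    """Generate the survey; deterministic for a fixed seed."""
    rng = np.random.default_rng(scenario.seed)
    n_otus = scenario.n_otus
    otus = [f"OTU{i + 1:03d}" for i in range(n_otus)]
    taxonomy = pd.DataFrame(
        {
            "otu": otus,
            "order": [_ORDERS[i % len(_ORDERS)][0] for i in range(n_otus)],
            "phylum": [_ORDERS[i % len(_ORDERS)][1] for i in range(n_otus)],
        }
    ).set_index("otu")

    counts_rows, meta_rows = {}, {}
    truth_sites = {}
    for area, n_sites in scenario.n_sites.items():
        z_gold = rng.standard_normal(n_sites)
        gold = np.exp(
            scenario.gold_log_median[area] + scenario.gold_log_sd[area] * z_gold
        )
        c = scenario.coupling[area]
        latent = c * z_gold + np.sqrt(1 - c**2) * rng.standard_normal(n_sites)
        d_target = np.exp(
            scenario.diversity_log_mean + scenario.diversity_log_sd * latent
        )
        ph = rng.normal(scenario.ph_mean, scenario.ph_sd, n_sites)
        for i in range(n_sites):
            site = f"{area[:3]}{i + 1:02d}"
            base = _geometric_profile(n_otus, d_target[i])
            probs = rng.dirichlet(base * scenario.dispersion * n_otus + 1e-9)
            counts_rows[site] = rng.multinomial(scenario.depth, probs)
            meta_rows[site] = {"area": area, "au": gold[i], "ph": ph[i]}
            truth_sites[site] = {
                "target_inverse_simpson": float(d_target[i]),
                "au": float(gold[i]),
            }
    counts = pd.DataFrame.from_dict(counts_rows, orient="index", columns=otus)
    counts.index.name = "site"
    meta = pd.DataFrame.from_dict(meta_rows, orient="index")
    meta.index.name = "site"
    table = OtuTable(counts, taxonomy, meta)
    truth = {
        "coupling": dict(scenario.coupling),
        "diversity_log_mean": scenario.diversity_log_mean,
        "diversity_log_sd": scenario.diversity_log_sd,
        "sites": truth_sites,
        "seed": scenario.seed,
    }
    return CommunityResult(table, truth)


# ---------------------------------------------------------------------------
# toy graphs
# ---------------------------------------------------------------------------

def gen_toy_network(motif: str, n: int = 3, edges=None) -> CooccurrenceNetwork:
    """Deterministic small graphs for centrality/modularity oracles.

    Motifs: ``path`` (n nodes), ``star`` (n leaves), ``clique`` (n nodes),
    ``two_cliques`` (two disconnected K_n), ``custom`` (explicit edge list).
    """
    if motif == "path":
        g = nx.path_graph(n)
    elif motif == "star":
        g = nx.star_graph(n)  # center 0 plus n leaves
    elif motif == "clique":
        g = nx.complete_graph(n)
    elif motif == "two_cliques":
        g = nx.disjoint_union(nx.complete_graph(n), nx.complete_graph(n))
    elif motif == "custom":
        if edges is None:
            raise ValueError("custom motif needs an edge list")
        g = nx.Graph(edges)
    else:
        raise ValueError(f"unknown motif {motif!r}")
    g = nx.relabel_nodes(g, {v: str(v) for v in g.nodes})
    for u, v in g.edges:
        g[u][v].setdefault("correlation", 1.0)
        g[u][v].setdefault("sign", 1)
    return CooccurrenceNetwork(g, threshold=1.0, method="pearson")
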