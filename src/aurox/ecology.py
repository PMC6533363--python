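"""Community statistics for site x OTU tables with soil geochemistry.

Covers the descriptive ecology of a two-area soil survey (a gold anomaly
and an adjacent reference area): alpha diversity (inverse Simpson,
Berger-Parker dominance, Chao1 richness), the gold-hotspot classification
rule (>= 1.5x the anomaly median), Pearson diversity-gold correlations per
area, and co-occurrence ("molecular ecological") networks built from
correlation-thresholded OTU relative abundances, with greedy-modularity
module detection and stress centrality.

Order-level aggregation before networking is on by default since the
networks of interest connect fungal orders; disable with ``level=None``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

HOTSPOT_FACTOR = 1.5
ALPHA = 0.1  # significance level used throughout the survey analyses


class EcologyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class OtuTable:
    """Site x OTU counts joined to taxonomy and per-site geochemistry.

    ``counts``: DataFrame indexed by site id, columns are OTU ids,
    non-negative integers.  ``taxonomy``: DataFrame indexed by OTU id with
    at least ``phylum`` and ``order`` columns.  ``site_meta``: DataFrame
    indexed by site id with at least ``area`` (``anomaly``/``reference``)
    and ``au`` (ng/g) columns; ``ph`` optional.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    site_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise EcologyError("counts must be non-negative")
        if (self.counts.sum(axis=1) == 0).any():
            raise EcologyError("every analysed site needs a positive total count")
        missing = set(self.counts.columns) - set(self.taxonomy.index)
        if missing:
            raise EcologyError(f"OTUs without taxonomy: {sorted(missing)[:5]}...")
        if not set(self.counts.index) <= set(self.site_meta.index):
            raise EcologyError("sites missing from site_meta")

    def area_sites(self, area: str) -> list[str]:
        meta = self.site_meta.loc[self.counts.index]
        return list(meta.index[meta["area"] == area])

    def aggregate(self, level: str) -> pd.DataFrame:
        """Counts summed by a taxonomy level (e.g. ``order``)."""
        if level not in self.taxonomy.columns:
            raise EcologyError(f"taxonomy has no level {level!r}")
        groups = self.taxonomy.loc[self.counts.columns, level]
        return self.counts.T.groupby(groups).sum().T

    @classmethod
    def from_tsv(
        cls, counts_path, taxonomy_path, meta_path
    ) -> "OtuTable":
        """Read the three TSV tables; accepts a shared-file-style header
        (``label/Group/numOtus`` columns) on the counts table."""
        counts = pd.read_csv(counts_path, sep="\t")
        if {"label", "Group", "numOtus"} <= set(counts.columns):
            counts = counts.drop(columns=["label", "numOtus"]).set_index("Group")
        else:
            counts = counts.set_index(counts.columns[0])
        counts.index.name = "site"
        tax = pd.read_csv(taxonomy_path, sep="\t").set_index("otu")
        meta = pd.read_csv(meta_path, sep="\t").set_index("site")
        return cls(counts.astype(int), tax, meta)


@dataclass
class CooccurrenceNetwork:
    """Correlation-threshold co-occurrence network over taxa."""

    graph: nx.Graph
    threshold: float
    method: str
    modules: dict[str, int] = field(default_factory=dict)
    modularity: float | None = None
    excluded: list[str] = field(default_factory=list)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            (u, v, d["correlation"], d["sign"])
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "correlation", "sign"])


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def _clean_counts(counts) -> np.ndarray:
    x = np.asarray(counts, dtype=float)
    x = x[x > 0]
    if x.size == 0 or x.sum() <= 0:
        raise EcologyError("empty site: no positive counts")
    return x


def inverse_simpson(counts) -> float:
    """Inverse Simpson diversity 1/sum(p_i^2): effective number of taxa."""
    x = _clean_counts(counts)
    p = x / x.sum()
    return float(1.0 / np.sum(p**2))


def berger_parker(counts, reciprocal: bool = False) -> float:
    """Berger-Parker dominance n_max/N (or its reciprocal N/n_max)."""
    x = _clean_counts(counts)
    d = float(x.max() / x.sum())
    return 1.0 / d if reciprocal else d


def chao1(counts) -> float:
    """Chao1 richness: S_obs + f1^2/(2 f2); bias-corrected when f2 = 0."""
    x = _clean_counts(counts)
    s_obs = x.size
    f1 = int(np.sum(x == 1))
    f2 = int(np.sum(x == 2))
    if f2 > 0:
        return s_obs + f1**2 / (2 * f2)
    return s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))


def diversity_table(table: OtuTable) -> pd.DataFrame:
    """Per-site inverse Simpson, Berger-Parker and Chao1, joined to metadata."""
    rows = {
        site: {
            "inverse_simpson": inverse_simpson(row),
            "berger_parker": berger_parker(row),
            "chao1": chao1(row),
        }
        for site, row in table.counts.iterrows()
    }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "site"
    return out.join(table.site_meta[["area", "au"]])


# ---------------------------------------------------------------------------
# hotspots and diversity-gold correlation
# ---------------------------------------------------------------------------

def classify_hotspots(
    site_meta: pd.DataFrame, area: str = "anomaly"
) -> tuple[pd.Series, float]:
    """Hotspot labels for anomaly sites: au >= 1.5 x median(anomaly au).

    Returns ``(labels, threshold)`` where labels is a boolean Series over
    the anomaly sites.  The comparison is inclusive (>=).
    """
    sub = site_meta[site_meta["area"] == area]
    if sub.empty:
        raise EcologyError(f"no sites in area {area!r}")
    au = sub["au"]
    if au.isna().any():
        raise EcologyError("missing gold concentrations for hotspot rule")
    threshold = HOTSPOT_FACTOR * float(au.median())
    return au >= threshold, threshold


def pearson_with_p(x, y, tails: int = 2) -> tuple[float, float]:
    """Pearson r and its exact t-transform p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise EcologyError("need >= 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise EcologyError("zero variance")
    r, p_two = stats.pearsonr(x, y)
    if tails == 1:
        return float(r), float(p_two / 2)
    return float(r), float(p_two)


def diversity_gold_correlation(
    table: OtuTable,
    grouping: str = "area",
    tails: int = 2,
    index: str = "inverse_simpson",
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Per-group Pearson correlation between alpha diversity and gold.

    ``grouping`` may be ``"area"`` (anomaly vs reference) or ``"hotspot"``
    (anomaly hotspots only, plus the reference area).  Returns a frame with
    columns r, p, n and ``significant`` at ``alpha`` (default 0.1).
    """
    div = diversity_table(table)
    groups: dict[str, pd.DataFrame] = {}
    if grouping == "area":
        for area in div["area"].unique():
            groups[area] = div[div["area"] == area]
    elif grouping == "hotspot":
        hot, _ = classify_hotspots(table.site_meta)
        groups["hotspot"] = div.loc[hot.index[hot]]
        groups["reference"] = div[div["area"] == "reference"]
    else:
        raise EcologyError(f"unknown grouping {grouping!r}")
    rows = []
    for name, sub in groups.items():
        r, p = pearson_with_p(sub[index], sub["au"], tails=tails)
        rows.append((name, r, p, len(sub), p < alpha))
    return pd.DataFrame(
        rows, columns=["group", "r", "p", "n", "significant"]
    ).set_index("group")


# ---------------------------------------------------------------------------
# co-occurrence networks
# ---------------------------------------------------------------------------

def build_network(
    table: OtuTable,
    sites: list[str] | None = None,
    min_prevalence: int = 7,
    threshold: float = 0.8,
    method: str = "pearson",
    level: str | None = "order",
) -> CooccurrenceNetwork:
    """Correlation-threshold network over (optionally order-aggregated) taxa.

    Taxa must appear in at least ``min_prevalence`` of the selected sites;
    relative abundances are correlated pairwise (Pearson by default,
    Spearman via ``method="spearman"``) and an edge is kept iff
    ``|r| >= threshold``, with its sign recorded.  Constant taxa are
    excluded and listed in ``excluded``.
    """
    counts = table.aggregate(level) if level else table.counts
    if sites is not None:
        counts = counts.loc[sites]
    if len(counts) < 4:
        raise EcologyError("need >= 4 sites to correlate abundances")
    prevalence = (counts > 0).sum(axis=0)
    keep = prevalence[prevalence >= min_prevalence].index
    if len(keep) < 2:
        raise EcologyError("prevalence filter leaves fewer than 2 taxa")
    rel = counts[keep].div(counts.sum(axis=1), axis=0)
    constant = [c for c in rel.columns if np.ptp(rel[c].to_numpy()) == 0]
    rel = rel.drop(columns=constant)
    corr = rel.corr(method=method)
    g = nx.Graph()
    g.add_nodes_from(rel.columns)
    for i, j in itertools.combinations(rel.columns, 2):
        r = float(corr.loc[i, j])
        if abs(r) >= threshold:
            g.add_edge(i, j, correlation=r, sign=1 if r >= 0 else -1)
    return CooccurrenceNetwork(g, threshold, method, excluded=constant)


def greedy_modules(network: CooccurrenceNetwork) -> tuple[dict[str, int], float]:
    """Greedy (agglomerative) modularity maximisation on the unsigned graph.

    Merges the community pair with the largest modularity gain until no
    merge improves Q (Clauset-Newman-Moore).  Returns the node -> module id
    partition and its modularity; both are also stored on the network.
    """
    g = network.graph
    if g.number_of_edges() == 0:
        raise EcologyError("network has no edges; nothing to cluster")
    comms = nx.community.greedy_modularity_communities(g)
    modules = {node: i for i, com in enumerate(comms) for node in com}
    q = nx.community.modularity(g, comms)
    network.modules = modules
    network.modularity = q
    return modules, q


def stress_centrality(network: CooccurrenceNetwork | nx.Graph, node=None):
    """Stress centrality: number of shortest paths passing through a node.

    Counts, over all unordered pairs (s, t) with s != x != t, every
    unweighted shortest path between s and t that contains x as an interior
    node.  Returns an int for one ``node`` or a dict for all nodes.
    """
    g = network.graph if isinstance(network, CooccurrenceNetwork) else network
    if node is not None and node not in g:
        raise EcologyError(f"unknown node {node!r}")
    counts = dict.fromkeys(g.nodes, 0)
    for s, t in itertools.combinations(g.nodes, 2):
        try:
            for path in nx.all_shortest_paths(g, s, t):
                for interior in path[1:-1]:
                    counts[interior] += 1
        except nx.NetworkXNoPath:
            continue
    if node is not None:
        return counts[node]
    return counts


def export_network(
    network: CooccurrenceNetwork, prefix: str | Path
) -> list[Path]:
    """Write edge list (TSV), GraphML, and module/centrality table (TSV)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    files = []
    edge_path = prefix.with_name(prefix.name + "_edges.tsv")
    network.edge_table().to_csv(edge_path, sep="\t", index=False)
    files.append(edge_path)
    gml_path = prefix.with_name(prefix.name + ".graphml")
    nx.write_graphml(network.graph, gml_path)
    files.append(gml_path)
    cent = stress_centrality(network)
    modules = network.modules or {}
    node_path = prefix.with_name(prefix.name + "_nodes.tsv")
    pd.DataFrame(
        {
            "node": list(network.graph.nodes),
            "module": [modules.get(n, -1) for n in network.graph.nodes],
            "stress_centrality": [cent[n] for n in network.graph.nodes],
            "degree": [network.graph.degree(n) for n in network.graph.nodes],
        }
    ).to_csv(node_path, sep="\t", index=False)
    files.append(node_path)
    return files
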