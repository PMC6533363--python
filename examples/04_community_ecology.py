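"""Diversity, hotspot, correlation and network statistics of a simulated
two-area soil survey (gold anomaly vs reference)."""

from aurox import (
    CommunityScenario,
    build_network,
    classify_hotspots,
    diversity_gold_correlation,
    diversity_table,
    gen_otu_table,
    greedy_modules,
    stress_centrality,
)

result = gen_otu_table(CommunityScenario(seed=0))
table = result.table

div = diversity_table(table)
print("per-site alpha diversity (head):")
print(div.head(5).round(3).to_string())

hot, thr = classify_hotspots(table.site_meta)
print(f"\nhotspot rule: au >= 1.5 x median = {thr:.2f} ng/g "
      f"-> {int(hot.sum())} hotspot site(s)")

corr = diversity_gold_correlation(table)
print("\ninverse Simpson vs gold, per area (alpha = 0.1):")
print(corr.round(4).to_string())

net = build_network(table, sites=table.area_sites("anomaly"),
                    min_prevalence=7, threshold=0.8, level="order")
modules, q = greedy_modules(net)
cent = stress_centrality(net)
top = max(cent, key=cent.get)
print(f"\nanomaly co-occurrence network: {net.graph.number_of_nodes()} orders,"
      f" {net.graph.number_of_edges()} edges,"
      f" {len(set(modules.values()))} modules (Q = {q:.3f});"
      f" most stressed node: {top} (c_S = {cent[top]})")

print(
    "\nReading: diversity rises with gold inside the anomaly but not in the"
    "\nreference area, hotspots concentrate the signal, and the network's"
    "\nstress centrality identifies the hub order of the anomaly community."
)
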