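"""How well does dangling centrality agree with the classical metrics?

Computes all six metrics on the 5-node graph and correlates dangling
centrality against each classical metric with Pearson, average-rank
Spearman, and tie-corrected Kendall tau-b.
"""

from danglecent import (
    CentralityVector,
    betweenness_centrality,
    builtin_graph,
    closeness_centrality,
    concordance_report,
    dangling_all,
    degree_centrality,
    eigenvector_centrality,
    katz_centrality,
    rank_nodes,
)

g = builtin_graph("five_node")
phi = CentralityVector("dangling", dangling_all(g).values())
vectors = {
    "dangling": phi,
    "dc": degree_centrality(g),
    "bc": betweenness_centrality(g),
    "cc": closeness_centrality(g),
    "evc": eigenvector_centrality(g)[0],
    "katz": katz_centrality(g, alpha=0.2),
}

report = concordance_report(vectors, reference="dangling")
print(f"{'method':>9} {'metric':>6} {'coefficient':>12}")
for e in report.entries:
    print(f"{e.method:>9} {e.metric_b:>6} {e.coefficient:>12.7f}")

table = rank_nodes(phi)
print(f"\nmost influential node by dangling centrality: {table.top()}")
print(
    "\nAll coefficients are strongly positive: link-removal impact ranks"
    "\nnodes much like the classical metrics do. Spearman/Kendall = 1 for"
    "\ncloseness means the two metrics order the nodes identically here."
)
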