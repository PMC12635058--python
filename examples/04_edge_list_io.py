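"""Reading a raw edge list: comments, self-loops, duplicates, extra columns.

Writes a small messy file in the style of public network datasets (comment
header, a reciprocal directed pair, a self-loop, a rating column), sanitizes
it into a simple undirected graph, and scores it.
"""

import tempfile
from pathlib import Path

from danglecent import dangling_all, read_edge_list

raw = """# toy trust network
# src,dst,rating,timestamp
1,2,4,1289241911.7
2,1,3,1289241912.0
2,2,1,1289241913.0
2,3,5,1289241914.0
3,1,2,1289241915.0
"""

with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "trust.csv"
    path.write_text(raw)
    graph, log = read_edge_list(path)

print(f"graph: {graph.n_nodes} nodes, {graph.n_edges} edges")
print(f"sanitize log: {log}")

for r in dangling_all(graph).per_node:
    print(f"  node {r.label}: dangling = {r.dangling:.5f}")

print(
    "\nThe reciprocal pair 1->2 / 2->1 collapsed to one undirected edge, the"
    "\nself-loop 2-2 was dropped, and the rating/timestamp columns were"
    "\nignored — the counts above record each of those decisions."
)
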