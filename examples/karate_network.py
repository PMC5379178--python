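"""Community detection on the classic 34-node karate-club network.

The network records friendships in a university club that later split into
two factions, making it a standard small test case. The detector returns a
finer division than the two factions (communities are denser sub-groups),
so the NMI against the factions is well below 1 even for a good partition.
"""

import networkx as nx

import ssclpa

graph = ssclpa.from_networkx(nx.karate_club_graph())
report = ssclpa.detect(graph)

print(f"graph: {graph.n} nodes, {graph.m} edges")
print(f"communities found: {report.community_count}")
print(f"Q    = {report.Q:.3f}")
print(f"Q_ds = {report.Q_ds:.3f}")

factions = ssclpa.Partition(
    labels={str(v): d["club"] for v, d in nx.karate_club_graph().nodes(data=True)}
)
print(f"NMI vs the two factions = {ssclpa.nmi(report.partition, factions):.3f}")
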