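"""Find bridge edges in the 52-word component via geodesic-proportion
betweenness.

An edge's betweenness is the share of all shortest paths (between all node
pairs of its component) that traverse it.  Edges close to 0.5 are true
bottlenecks: half of all geodesics squeeze through them.
"""

import networkx as nx

import doubletsnet as dn
from doubletsnet import synth

lad = dn.build_ladder_graph(synth.eight_letter_component())
stats = dn.edge_betweenness(lad)

print("top 5 bridge edges (betweenness = share of all geodesics):")
for s in sorted(stats.values(), key=lambda s: -s.betweenness)[:5]:
    u, v = s.edge
    print(f"  {u:>9s} - {v:<9s}  B={s.betweenness:.3f}  "
          f"type {s.node_type}/{s.change_type} at slot {s.changed_position}")

top = max(stats.values(), key=lambda s: s.betweenness)
g = lad.graph.copy()
g.remove_edge(*top.edge)
print(f"\nremoving {top.edge[0]}-{top.edge[1]} leaves "
      f"{nx.number_connected_components(g)} components:")
for comp in sorted(nx.connected_components(g), key=len):
    print(f"  component of {len(comp)} words")
# The highest-betweenness edge is the sole link between two word families;
# cutting it disconnects the network, which is why the distance construction
# must map high betweenness to a large node separation.
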