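"""Motif census of a triangle-enriched graph against the switching null.

Fifty triangles are planted into a sparse random graph; the degree-preserving
null ensemble reveals the triangle (id238) as an over-represented motif.
"""

import networkx as nx
import numpy as np

from crohnet import motif_zscores

rng = np.random.default_rng(0)
net = nx.relabel_nodes(nx.gnm_random_graph(100, 150, seed=0), str)
nodes = sorted(net.nodes())
for _ in range(50):
    a, b, c = (nodes[int(i)] for i in rng.choice(len(nodes), 3, replace=False))
    net.add_edges_from([(a, b), (b, c), (a, c)])

census = motif_zscores(net, k=3, n_random=50, z_threshold=2.0, seed=1)
print("id\treal\tnull_mean\tnull_sd\tz\tcall")
for cid in sorted(census.classes):
    s = census.classes[cid]
    print(f"{cid}\t{s.real_count}\t{s.null_mean:.1f}\t{s.null_sd:.1f}\t{s.z_score:+.2f}\t{s.call}")
# id78 is the 3-path, id238 the triangle; a positive triangle z-score means
# the graph closes more triangles than its degree sequence alone explains.
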