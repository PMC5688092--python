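"""Construct the heterogeneous network from a synthetic bundle.

Shows the three edge sources: seed-anchored correlation edges per layer,
the noisy-OR fusion with PPIs on the expression layer, and the regulatory
edges from the per-gene expression regression.
"""

from collections import Counter

from ihnet import SimConfig, build_network, generate_bundle, prepare_matrices

bundle = generate_bundle(SimConfig(rng_seed=42))
matrices = prepare_matrices(bundle.matrices)  # align samples + z-score rows
net = build_network(matrices, bundle.seeds, bundle.ppi, bundle.targets,
                    p_threshold=0.05)

print(f"|V| = {net.n_nodes} nodes, |E| = {net.n_edges} undirected edges")
print(f"resistance defaults: eps = |V|/|E|^2 = {net.eps_resistance:.3g}, "
      f"beta = 1/|E| = {net.beta_resistance:.3g}")
kinds = Counter(net.edge_kinds.values())
for kind, count in sorted(kinds.items()):
    print(f"  {kind:<10s} {count}")
# 'fused' edges live on the expression layer (correlation OR PPI evidence),
# 'pcc' on the other layers, 'reg_*' connect a gene's nodes across layers
# with |beta| weights from the regression fit
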