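"""Score and rank genes by propagating seed information with resistance.

Priors come from seed status and seed-neighbor fractions; scores diffuse
over the normalized transition matrix with a small resistance toll that
damps hub-driven leakage. The final gene score is the max over the gene's
expression/CNV/methylation nodes.
"""

from ihnet import (
    PropagationConfig,
    SimConfig,
    aggregate_gene_scores,
    build_network,
    compute_prior_scores,
    generate_bundle,
    prepare_matrices,
    propagate,
)

bundle = generate_bundle(SimConfig(rng_seed=42))
matrices = prepare_matrices(bundle.matrices)
net = build_network(matrices, bundle.seeds, bundle.ppi, bundle.targets)

priors = compute_prior_scores(net, bundle.seeds, alpha=50)
result = propagate(net, priors, PropagationConfig(lambda_mix=0.2))
print(f"converged in {result.iterations_used} iterations "
      f"(final MSE {result.final_mse:.2e})")

scores = aggregate_gene_scores(result, net)
seed_genes = bundle.seeds.gene_ids()
ranked = sorted(scores.items(), key=lambda kv: -kv[1])
print("top 10 genes (seeds propagate their own prior, so they rank first;")
print("high-ranked non-seeds are the candidate predictions):")
for rank, (gene, score) in enumerate(ranked[:10], start=1):
    tag = "seed" if gene in seed_genes else "candidate"
    print(f"  {rank:>2d}. {gene}  {score:.3f}  ({tag})")

in_module = {g for mod in bundle.truth["modules"]["expression"] for g in mod["members"]}
top_candidates = [g for g, _ in ranked[:60] if g not in seed_genes]
hits = sum(g in in_module for g in top_candidates)
print(f"{hits}/{len(top_candidates)} top-ranked candidates lie in planted "
      f"expression modules")
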