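# ihnet

Disease-gene prioritization on a heterogeneous multi-omics network.

`ihnet` is for computational biologists who have, for one disease: per-omics
feature matrices (gene expression, copy-number, DNA methylation, miRNA
expression over a shared patient cohort), a curated list of genes/miRNAs
already known to be disease-associated ("seeds"), protein–protein
interactions and miRNA→target pairs — and who want to rank every other gene
by how strongly the molecular evidence ties it to the disease.

## The model

Every (entity, omics) pair is a network node: a gene contributes up to three
nodes (expression, CNV, methylation), a miRNA one node. Edges encode three
kinds of evidence:

1. **Correlational edges (per layer).** For each seed *s* of a layer and
   every other entity *g*, the absolute Pearson correlation |PCC(s, g)|
   across samples is kept as an edge iff the two-sided correlation t-test
   has p below a cutoff (default 0.05). Each layer's matrix *M* is then
   normalized by its row sums *E(i,i)*:

   M̄(i,j) = M(i,j) / √(E(i,i) · E(j,j))

2. **PPI fusion (expression layer).** STRING-style combined scores are
   rescaled to (0,1], normalized the same way, and merged with the
   correlational edges by a noisy-OR:

   w(i,j) = 1 − (1 − m^pcc(i,j)) (1 − m^ppi(i,j))

3. **Regulatory edges (between layers).** Per gene *i*, ordinary least
   squares of expression on its own CNV and methylation profiles and the
   expression of its miRNA regulators:

   Y_i = β_i^cnv X_i^cnv + β_i^methy X_i^methy + Σ_j β_ij^mir X_ij^mir + ε

   |β| weights the edges between the gene's expression node and its CNV /
   methylation / regulator-miRNA nodes.

The assembled block matrix is symmetrically normalized once more into the
transition matrix W̄ (spectral radius ≤ 1). Each node gets a prior score
D_v — 1 for seeds; for non-seeds the seed fraction among its N_v neighbors,
damped by e^(N_v − α) when N_v < α (default α = 50) — and scores propagate
with a damping mix λ = 0.2:

S^t = λ · f(S^{t−1}) + (1 − λ) · D,  S^1 = D

where f subtracts a small resistance є = |V|/|E|² from every transition and
cuts flow entirely into targets that score below θ = 0.005 and receive no
flow above β = 1/|E| — damping leakage through hub nodes. Iteration stops
when the mean squared change drops to 1e−5. A gene's final score is the max
over its three layer nodes; candidates are ranked by it.

Evaluation is leave-one-out cross-validation in which the held-out seed is
honestly demoted (its seed-anchored edges and prior are recomputed as a
non-seed), reported as ROC/AUC, sensitivity at fixed specificity, top-k%
recovery fractions with hypergeometric p-values, fold enrichment and
precision–recall.

## Worked example

The package ships a synthetic-data generator whose defaults emulate a
desk-scale cohort (500 genes × 300 samples, 60 miRNAs, 30 seed genes in
correlated disease modules, expression generated from the regulatory model
above). `examples/04_loocv_evaluation.py`:

```python
from ihnet import SimConfig, evaluate, generate_bundle, prepare_matrices, run_loocv

bundle = generate_bundle(SimConfig(rng_seed=42))
matrices = prepare_matrices(bundle.matrices)
folds = run_loocv(matrices, bundle.seeds, bundle.ppi, bundle.targets)
report = evaluate(folds)
```

prints

```
30 folds over 500 genes (470 candidates)
AUC = 95.9%
Sn at Sp >= 99%: 40.0%
Sn at Sp >= 95%: 66.7%
Sn at Sp >= 90%: 86.7%
top    5% (25 genes): fraction 0.00, hypergeometric p = 1.0e+00
top   10% (50 genes): fraction 0.67, hypergeometric p = 2.9e-15
top   15% (75 genes): fraction 0.87, hypergeometric p = 9.5e-20
top   20% (100 genes): fraction 0.93, hypergeometric p = 2.8e-19
mean fold enrichment = 82 (1.0 would be the mid-rank expectation)
```

An AUC of 95.9% means a held-out seed outranks a random candidate gene
~96% of the time; 93% of held-out seeds land in the top 20% of the ranking.
The empty top-5% slice is a small-cohort artifact: 5% of 500 genes is 25
ranks, and the 29 training seeds legitimately occupy them (see
`docs/methods.md`). The other examples walk through simulation
(`01_simulate_bundle.py`), network construction (`02_build_network.py`) and
single-run gene ranking (`03_propagate_scores.py`).

The same pipeline is scriptable from the shell:

```bash
ihnet simulate --out data/ --seed 42
ihnet build --data data/ --out net/
ihnet propagate --data data/ --out scores/
ihnet loocv --data data/ --out eval/ --plots
ihnet report --eval-json eval/eval_report.json
```

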