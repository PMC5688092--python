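"""Leave-one-out cross-validation and ranking metrics.

Each LOOCV fold demotes one seed gene to candidate status: its seed-anchored
correlation edges are dropped unless the other endpoint is still a seed, its
prior score is recomputed as a non-seed, and the resistance parameters are
re-derived from the fold's network. The regulatory (regression) edges do not
depend on seed status and are kept. The held-out gene is then ranked among
the candidate genes by its propagated score (ties broken pessimistically:
tied candidates count as ranked better).

Metrics follow the rank-sweep confusion-matrix convention: seed genes are
the gold-standard positives, candidate genes the negatives, and the top-k
predictions define TP/FP/TN/FN, from which Sp = TN/(TN+FP), Sn = TP/(TP+FN),
precision = TP/(TP+FP) and recall = TP/(TP+FN) are computed. The ROC sweeps
the rank threshold and its trapezoid area equals the Mann-Whitney pairwise
count. Rank-cutoff fractions (share of held-out seeds recovered in the top
k% of genes) come with upper-tail hypergeometric p-values, and fold
enrichment is (candidates / 2) / rank, averaged over folds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .io_formats import GENE_LAYERS, InteractionSet, OmicsMatrix, SeedSet, ValidationError
from .network import (
    CorrelationMatrix,
    NormalizedMatrix,
    assemble_heterogeneous_network,
    build_layers,
    compute_seed_correlations,
    fit_regulatory_regression,
    layers_from_correlations,
    mask_held_out_seed,
    prepare_matrices,
)
from .propagation import (
    PropagationConfig,
    aggregate_gene_scores,
    compute_prior_scores,
    propagate,
)

__all__ = [
    "FoldRecord",
    "EvalReport",
    "run_loocv",
    "roc_points",
    "roc_auc",
    "sn_at_sp",
    "rank_cutoff_fractions",
    "fold_enrichment",
    "precision_recall",
    "evaluate",
]

logger = logging.getLogger(__name__)


@dataclass
class FoldRecord:
    """One LOOCV fold: the held-out seed gene, its score and ranks."""

    seed_id: str
    seed_omics: str
    score: float
    rank: int          # among {held-out seed} | candidate genes (1 = best)
    n_candidates: int
    rank_all: int      # among all genes in the network (incl. training seeds)
    n_genes: int
    converged: bool = True
    gene_scores: dict[str, float] | None = None


# ---------------------------------------------------------------------------
# LOOCV
# ---------------------------------------------------------------------------


def _rank_worst_case(score: float, others: np.ndarray) -> int:
    """1-based rank with pessimistic ties: equal scores count as better."""
    return int(np.sum(others >= score)) + 1


def run_loocv(
    matrices: dict[str, OmicsMatrix],
    seeds: SeedSet,
    ppi: InteractionSet,
    targets: InteractionSet,
    p_threshold: float = 0.05,
    alpha: int = 50,
    config: PropagationConfig | None = None,
    cached: bool = True,
    record_scores: bool = False,
) -> list[FoldRecord]:
    """Leave-one-out cross-validation over the seed genes.

    ``cached=True`` computes all seed-anchored correlations once and masks
    the held-out seed's edges per fold; ``cached=False`` recomputes every
    layer from the reduced seed set in each fold. The two modes are
    bit-identical because per-pair correlations do not depend on the seed
    set (enforced by a test).
    """
    if not all(m.normalized for m in matrices.values()):
        matrices = prepare_matrices(matrices)
    config = config or PropagationConfig()

    gene_folds = [
        (i, o) for i, o in seeds.gene_entries()
        if o in matrices and i in set(matrices[o].entity_ids)
    ]
    if len(gene_folds) < 2:
        raise ValidationError("LOOCV needs at least two mapped seed genes")
    seed_gene_ids = seeds.gene_ids()

    coeffs = fit_regulatory_regression(
        matrices["expression"], matrices["cnv"], matrices["methylation"],
        matrices["mirna"], targets,
    )
    if cached:
        corrs_full, ppi_bar = build_layers(matrices, seeds, ppi, p_threshold)
    else:
        expr_ids = matrices["expression"].entity_ids
        from .network import ppi_matrix, symmetric_normalize
        ppi_bar = symmetric_normalize(
            ppi_matrix(ppi, expr_ids), name="ppi", entity_ids=expr_ids
        )

    records: list[FoldRecord] = []
    for held_id, held_omics in gene_folds:
        fold_seeds = seeds.without((held_id, held_omics))
        if cached:
            remaining = set(fold_seeds.ids_for(held_omics))
            corrs = dict(corrs_full)
            corrs[held_omics] = mask_held_out_seed(
                corrs_full[held_omics], held_id, remaining
            )
        else:
            corrs = {
                name: compute_seed_correlations(m, fold_seeds, p_threshold)
                for name, m in matrices.items()
            }
        layers = layers_from_correlations(corrs, ppi_bar)
        net = assemble_heterogeneous_network(layers, coeffs)
        D = compute_prior_scores(net, fold_seeds, alpha=alpha)
        result = propagate(net, D, config)
        gene_scores = aggregate_gene_scores(result, net)

        held_score = gene_scores[held_id]
        candidates = np.array(
            [s for g, s in gene_scores.items() if g not in seed_gene_ids]
        )
        all_others = np.array(
            [s for g, s in gene_scores.items() if g != held_id]
        )
        held_nodes = net.gene_nodes.get(held_id, [])
        if held_nodes and net.degrees()[np.asarray(held_nodes)].max() == 0:
            logger.warning("held-out seed %r isolated in its fold", held_id)
        records.append(
            FoldRecord(
                seed_id=held_id,
                seed_omics=held_omics,
                score=held_score,
                rank=_rank_worst_case(held_score, candidates),
                n_candidates=len(candidates),
                rank_all=_rank_worst_case(held_score, all_others),
                n_genes=len(gene_scores),
                converged=result.converged,
                gene_scores=dict(gene_scores) if record_scores else None,
            )
        )
    return records


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def roc_points(folds: list[FoldRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Pooled ROC from per-fold ranks.

    Sweeps the rank threshold (as a fraction of each fold's ranking-list
    size, so unequal folds pool consistently); at each threshold TP counts
    held-out seeds recovered and FP the candidate genes dragged in. Returns
    (x, y) = (1 - Sp, Sn) point arrays starting at (0, 0).
    """
    if not folds:
        raise ValidationError("need at least one fold")
    ranks = np.array([f.rank for f in folds])
    sizes = np.array([f.n_candidates for f in folds])  # candidates per fold
    lists = sizes + 1
    ts = np.unique(np.concatenate([np.arange(L + 1) / L for L in np.unique(lists)]))
    xs, ys = [], []
    n = len(folds)
    total_neg = sizes.sum()
    for t in ts:
        k = np.floor(t * lists + 1e-9).astype(int)
        tp = (ranks <= k).astype(int)
        fp = np.minimum(k - tp, sizes)
        xs.append(fp.sum() / total_neg)
        ys.append(tp.sum() / n)
    return np.array(xs), np.array(ys)


def roc_auc(folds: list[FoldRecord]) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points plus trapezoid AUC."""
    x, y = roc_points(folds)
    return x, y, float(np.trapezoid(y, x))


def sn_at_sp(
    folds: list[FoldRecord], levels: tuple[float, ...] = (0.99, 0.95, 0.90)
) -> dict[float, float]:
    """Highest sensitivity attainable at each specificity floor."""
    x, y = roc_points(folds)
    sp = 1.0 - x
    out = {}
    for level in levels:
        ok = sp >= level - 1e-12
        out[level] = float(y[ok].max()) if ok.any() else 0.0
    return out


def rank_cutoff_fractions(
    folds: list[FoldRecord], thresholds: tuple[float, ...] = (5, 10, 15, 20)
) -> dict[float, dict[str, float]]:
    """Fraction of held-out seeds recovered in the top k% of genes.

    The denominator is the number of genes in the network (seeds and
    candidates); the p-value is the upper tail of the hypergeometric
    distribution of seeing at least that many of the network's seed genes in
    a random top-k% slice.
    """
    out: dict[float, dict[str, float]] = {}
    n = len(folds)
    for k in thresholds:
        if not (0 < k <= 100):
            raise ValidationError("thresholds must lie in (0, 100]")
        hits = 0
        for f in folds:
            top = int(np.floor(k * f.n_genes / 100.0 + 1e-9))
            hits += int(f.rank_all <= top)
        G = folds[0].n_genes
        K = int(np.floor(k * G / 100.0 + 1e-9))
        # population G genes, n seed genes, K drawn: P(X >= hits)
        p = float(stats.hypergeom.sf(hits - 1, G, n, K))
        out[k] = {"fraction": hits / n, "p_value": p, "n_top": K}
    return out


def fold_enrichment(folds: list[FoldRecord]) -> tuple[list[float], float]:
    """Per-fold (candidates / 2) / rank, and the mean over folds."""
    values = [(f.n_candidates / 2.0) / f.rank for f in folds]
    return values, float(np.mean(values))


def precision_recall(
    folds: list[FoldRecord], thresholds=range(100, 2001, 100)
) -> list[dict[str, float]]:
    """Precision and recall of the top-k prediction sets, pooled over folds.

    At rank threshold k each fold contributes TP = [rank <= k] and
    FP = k - TP (capped at the candidate count). k = 0 yields an empty
    prediction set; precision is reported as 0 by convention.
    """
    ranks = np.array([f.rank for f in folds])
    sizes = np.array([f.n_candidates for f in folds])
    n = len(folds)
    out = []
    for k in thresholds:
        if k < 0:
            raise ValidationError("rank thresholds must be >= 0")
        if k == 0:
            logger.info("precision undefined at k=0 (empty prediction set); reported as 0")
            out.append({"k": 0, "precision": 0.0, "recall": 0.0})
            continue
        kk = np.minimum(k, sizes + 1)
        tp = (ranks <= kk).astype(int)
        fp = np.minimum(kk - tp, sizes)
        TP, FP = int(tp.sum()), int(fp.sum())
        out.append(
            {
                "k": int(k),
                "precision": TP / (TP + FP) if TP + FP else 0.0,
                "recall": TP / n,
            }
        )
    return out


@dataclass
class EvalReport:
    """All LOOCV ranking metrics in one serializable bundle."""

    n_folds: int
    n_genes: int
    n_candidates: int
    auc: float
    roc_x: list[float]
    roc_y: list[float]
    sn_at_sp: dict[float, float]
    rank_cutoffs: dict[float, dict[str, float]]
    fold_enrichment_values: list[float]
    mean_fold_enrichment: float
    precision_recall: list[dict[str, float]]
    folds: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sn_at_sp"] = {str(k): v for k, v in d["sn_at_sp"].items()}
        d["rank_cutoffs"] = {str(k): v for k, v in d["rank_cutoffs"].items()}
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def evaluate(
    folds: list[FoldRecord],
    sp_levels: tuple[float, ...] = (0.99, 0.95, 0.90),
    cutoffs: tuple[float, ...] = (5, 10, 15, 20),
    pr_thresholds=None,
) -> EvalReport:
    """Compute the full metric suite from LOOCV fold records."""
    x, y, auc = roc_auc(folds)
    fe_values, fe_mean = fold_enrichment(folds)
    if pr_thresholds is None:
        top = max(f.n_candidates for f in folds) + 1
        pr_thresholds = [k for k in range(100, 2001, 100) if k <= top] or [top]
    return EvalReport(
        n_folds=len(folds),
        n_genes=folds[0].n_genes,
        n_candidates=folds[0].n_candidates,
        auc=auc,
        roc_x=[float(v) for v in x],
        roc_y=[float(v) for v in y],
        sn_at_sp=sn_at_sp(folds, sp_levels),
        rank_cutoffs=rank_cutoff_fractions(folds, cutoffs),
        fold_enrichment_values=fe_values,
        mean_fold_enrichment=fe_mean,
        precision_recall=precision_recall(folds, pr_thresholds),
        folds=[
            {
                "seed_id": f.seed_id,
                "seed_omics": f.seed_omics,
                "score": f.score,
                "rank": f.rank,
                "rank_all": f.rank_all,
                "n_candidates": f.n_candidates,
                "converged": f.converged,
            }
            for f in folds
        ],
    )
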