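"""Heterogeneous multi-omics network construction.

The network has one node per (entity, omics) pair: a gene contributes up to
three nodes (expression, CNV, methylation) and a miRNA one node. Edges come
from three sources:

* intra-layer correlational edges -- for each seed of a layer, the absolute
  Pearson correlation between the seed and every other entity of that layer,
  kept when the two-sided correlation t-test passes a p-value cutoff;
* the PPI network on the expression layer, fused with the correlational
  edges by a noisy-OR rule ``w = 1 - (1 - m_pcc)(1 - m_ppi)``;
* inter-layer regulatory edges -- per gene, an ordinary least-squares fit of
  its expression on its CNV, methylation and miRNA-regulator profiles; the
  absolute coefficients weight the edges between the gene's expression node
  and its CNV / methylation / regulator-miRNA nodes.

Every weighted matrix is symmetrically normalized by the square roots of its
row sums, ``M̄(i,j) = M(i,j) / sqrt(rowsum_i * rowsum_j)``, both per layer
and once more on the assembled block matrix to obtain the global transition
matrix W̄ (spectral radius <= 1, so damped propagation converges).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .io_formats import (
    GENE_LAYERS,
    OMICS_LAYERS,
    InteractionSet,
    OmicsMatrix,
    SeedSet,
    ValidationError,
    align_samples,
    normalize_features,
)

__all__ = [
    "CorrelationMatrix",
    "NormalizedMatrix",
    "GeneRegression",
    "RegulatoryCoefficients",
    "HeterogeneousNetwork",
    "compute_seed_correlations",
    "symmetric_normalize",
    "ppi_matrix",
    "fuse_expression_edges",
    "fit_regulatory_regression",
    "assemble_heterogeneous_network",
    "prepare_matrices",
    "build_network",
    "write_network",
]

logger = logging.getLogger(__name__)

EDGE_KINDS = ("pcc", "ppi", "fused", "reg_cnv", "reg_methy", "reg_mir")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class CorrelationMatrix:
    """Seed-anchored absolute-PCC matrix of one omics layer.

    ``matrix`` is symmetric CSR over ``entity_ids`` with entries only on
    pairs where at least one endpoint is a seed of this layer and the
    correlation t-test passed the p-value filter. ``n_tested`` / ``n_kept``
    count distinct entity pairs, for calibration checks.
    """

    omics_name: str
    entity_ids: list[str]
    matrix: sparse.csr_matrix
    p_threshold: float
    n_tested: int = 0
    n_kept: int = 0


@dataclass
class NormalizedMatrix:
    """A symmetric nonnegative matrix after sqrt-row-sum normalization."""

    name: str
    entity_ids: list[str]
    matrix: sparse.csr_matrix


@dataclass
class GeneRegression:
    """Per-gene regulatory fit of expression on CNV, methylation and miRNAs."""

    gene_id: str
    beta_cnv: float = np.nan
    beta_methy: float = np.nan
    mir_betas: dict[str, float] = field(default_factory=dict)
    intercept: float = np.nan
    residual_sd: float = np.nan
    unfit_reason: str | None = None

    @property
    def fitted(self) -> bool:
        return self.unfit_reason is None


@dataclass
class RegulatoryCoefficients:
    """Collection of per-gene regulatory fits."""

    fits: dict[str, GeneRegression]

    def fitted_genes(self) -> list[str]:
        return [g for g, f in self.fits.items() if f.fitted]

    def __getitem__(self, gene_id: str) -> GeneRegression:
        return self.fits[gene_id]

    def __len__(self) -> int:
        return len(self.fits)


@dataclass
class HeterogeneousNetwork:
    """The assembled multi-layer network.

    ``nodes`` lists (entity_id, omics) pairs; ``adjacency`` is the raw
    symmetric nonnegative block matrix and ``wbar`` its symmetric-normalized
    counterpart used by the propagation. ``edge_kinds`` maps each stored
    (upper-triangle) edge to its provenance for export.
    """

    nodes: list[tuple[str, str]]
    adjacency: sparse.csr_matrix
    wbar: sparse.csr_matrix
    edge_kinds: dict[tuple[int, int], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.node_index: dict[tuple[str, str], int] = {
            node: i for i, node in enumerate(self.nodes)
        }
        gene_nodes: dict[str, list[int]] = {}
        for i, (ident, omics) in enumerate(self.nodes):
            if omics in GENE_LAYERS:
                gene_nodes.setdefault(ident, []).append(i)
        self.gene_nodes = gene_nodes

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        """Undirected edge count (each pair counted once)."""
        return self.adjacency.nnz // 2

    @property
    def eps_resistance(self) -> float:
        """Default per-transition resistance subtraction, |V| / |E|^2."""
        e = self.n_edges
        return self.n_nodes / e**2 if e else 0.0

    @property
    def beta_resistance(self) -> float:
        """Default incoming-flow floor for the resistance zero branch, 1 / |E|."""
        e = self.n_edges
        return 1.0 / e if e else np.inf

    def gene_ids(self) -> list[str]:
        """Genes with at least one node in the three gene layers."""
        return list(self.gene_nodes)

    def degrees(self) -> np.ndarray:
        """Binary degree of every node on the raw edge structure."""
        a = self.adjacency
        return np.diff(a.indptr).astype(int)


# ---------------------------------------------------------------------------
# correlational edges
# ---------------------------------------------------------------------------


def _pcc_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-value of the correlation t-test, t = r sqrt((n-2)/(1-r^2))."""
    df = n - 2
    r = np.clip(r, -1.0, 1.0)
    denom = 1.0 - r * r
    p = np.empty_like(r)
    perfect = denom <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(r) * np.sqrt(df / np.where(perfect, 1.0, denom))
    p[~perfect] = 2.0 * stats.t.sf(t[~perfect], df)
    p[perfect] = 0.0
    return p


def compute_seed_correlations(
    m: OmicsMatrix, seeds: SeedSet, p_threshold: float = 0.05
) -> CorrelationMatrix:
    """Seed-anchored absolute-PCC edges of one layer.

    For every seed of ``m``'s omics and every other entity, the Pearson
    correlation over samples is computed; the absolute value is kept as a
    symmetric edge iff the two-sided t-test p-value is below ``p_threshold``.
    Pairs where neither endpoint is a seed are never present. Seeds absent
    from the matrix are skipped with a warning.

    Correlations are evaluated one seed at a time against the full z-scored
    matrix, so the result for a pair does not depend on which other seeds are
    in the set -- leave-one-out re-wiring can drop edges of a demoted seed
    without recomputing anything.
    """
    if not m.normalized:
        raise ValidationError("compute_seed_correlations requires a normalized matrix")
    n = len(m.sample_ids)
    if n < 3:
        raise ValidationError("need >= 3 samples for the correlation t-test")
    ids = m.entity_ids
    index = {e: i for i, e in enumerate(ids)}
    seed_ids = []
    for s in seeds.ids_for(m.omics_name):
        if s in index:
            seed_ids.append(s)
        else:
            logger.warning("seed %r absent from %s matrix; skipped", s, m.omics_name)

    Z = m.values
    N = len(ids)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    for s in seed_ids:
        si = index[s]
        # PCC of z-scored rows is the dot product / n (population convention)
        r = Z @ Z[si] / n
        p = _pcc_pvalues(r, n)
        keep = (p < p_threshold) & (np.arange(N) != si)
        j = np.nonzero(keep)[0]
        rows.append(np.full(j.shape, si))
        cols.append(j)
        vals.append(np.abs(np.clip(r[j], -1.0, 1.0)))

    if rows:
        a = np.concatenate(rows)
        b = np.concatenate(cols)
        v = np.concatenate(vals)
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        # seed-seed pairs are produced from both anchors with identical values;
        # keep the first occurrence of each unordered pair
        lin = lo.astype(np.int64) * N + hi
        _, first = np.unique(lin, return_index=True)
        lo, hi, v = lo[first], hi[first], v[first]
        mat = sparse.coo_matrix(
            (np.concatenate([v, v]), (np.concatenate([lo, hi]), np.concatenate([hi, lo]))),
            shape=(N, N),
        ).tocsr()
        n_kept = len(v)
    else:
        mat = sparse.csr_matrix((N, N))
        n_kept = 0

    s_count = len(seed_ids)
    n_tested = s_count * (N - s_count) + s_count * (s_count - 1) // 2
    return CorrelationMatrix(
        omics_name=m.omics_name,
        entity_ids=ids,
        matrix=mat,
        p_threshold=p_threshold,
        n_tested=n_tested,
        n_kept=n_kept,
    )


def mask_held_out_seed(
    cm: CorrelationMatrix, held_out_id: str, remaining_seed_ids: set[str]
) -> CorrelationMatrix:
    """Demote one seed: drop its anchored edges unless the other endpoint is
    still a seed.

    This reproduces exactly what recomputing the layer with the reduced seed
    set yields, because per-pair correlations do not depend on the seed set.
    """
    ids = cm.entity_ids
    index = {e: i for i, e in enumerate(ids)}
    if held_out_id not in index:
        return cm
    h = index[held_out_id]
    keep_anchor = np.zeros(len(ids), dtype=bool)
    for s in remaining_seed_ids:
        if s in index:
            keep_anchor[index[s]] = True
    coo = cm.matrix.tocoo()
    touches = (coo.row == h) | (coo.col == h)
    other = np.where(coo.row == h, coo.col, coo.row)
    drop = touches & ~keep_anchor[other]
    keep = ~drop
    mat = sparse.coo_matrix(
        (coo.data[keep], (coo.row[keep], coo.col[keep])), shape=cm.matrix.shape
    ).tocsr()
    return CorrelationMatrix(
        omics_name=cm.omics_name,
        entity_ids=ids,
        matrix=mat,
        p_threshold=cm.p_threshold,
        n_tested=cm.n_tested,
        n_kept=mat.nnz // 2,
    )


# ---------------------------------------------------------------------------
# normalization and fusion
# ---------------------------------------------------------------------------


def symmetric_normalize(
    matrix: sparse.spmatrix | np.ndarray,
    name: str = "",
    entity_ids: list[str] | None = None,
) -> NormalizedMatrix:
    """Normalize a symmetric nonnegative matrix by sqrt row sums.

    ``M̄(i,j) = M(i,j) / sqrt(E(i,i) * E(j,j))`` with ``E(i,i)`` the sum of
    row i. Rows with zero sum map to all-zero rows. Raises on asymmetric or
    negative input.
    """
    M = sparse.csr_matrix(matrix, dtype=float)
    if M.shape[0] != M.shape[1]:
        raise ValidationError("matrix must be square")
    if (abs(M - M.T) > 1e-12).nnz:
        raise ValidationError("matrix must be symmetric")
    if M.nnz and M.data.min() < 0:
        raise ValidationError("matrix entries must be nonnegative")
    rowsum = np.asarray(M.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(rowsum > 0, 1.0 / np.sqrt(rowsum), 0.0)
    D = sparse.diags(inv_sqrt)
    out = (D @ M @ D).tocsr()
    if entity_ids is None:
        entity_ids = [str(i) for i in range(M.shape[0])]
    return NormalizedMatrix(name=name, entity_ids=entity_ids, matrix=out)


def ppi_matrix(ppi: InteractionSet, entity_ids: list[str]) -> sparse.csr_matrix:
    """Raw symmetric PPI weight matrix over the expression-layer entities."""
    if ppi.kind != "ppi":
        raise ValidationError("ppi_matrix needs a 'ppi' InteractionSet")
    index = {e: i for i, e in enumerate(entity_ids)}
    rows, cols, vals = [], [], []
    dropped = 0
    for a, b, w in ppi.edges:
        ia, ib = index.get(a), index.get(b)
        if ia is None or ib is None:
            dropped += 1
            continue
        rows += [ia, ib]
        cols += [ib, ia]
        vals += [w, w]
    if dropped:
        logger.info("ppi_matrix: dropped %d edge(s) outside the expression layer", dropped)
    n = len(entity_ids)
    return sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def fuse_expression_edges(
    pcc_bar: NormalizedMatrix, ppi_bar: NormalizedMatrix
) -> NormalizedMatrix:
    """Noisy-OR fusion of correlational and PPI evidence on the expression layer.

    ``w_ij = 1 - (1 - m_pcc)(1 - m_ppi) = m_pcc + m_ppi - m_pcc * m_ppi``,
    elementwise over the union of entity ids (missing entries are 0). The
    result is symmetric with entries in [0, 1] and is never below either
    input.
    """
    if pcc_bar.entity_ids == ppi_bar.entity_ids:
        ids = list(pcc_bar.entity_ids)
        A, B = pcc_bar.matrix, ppi_bar.matrix
    else:
        ids = sorted(set(pcc_bar.entity_ids) | set(ppi_bar.entity_ids))
        A = _reindex(pcc_bar, ids)
        B = _reindex(ppi_bar, ids)
    fused = (A + B - A.multiply(B)).tocsr()
    return NormalizedMatrix(name="expression", entity_ids=ids, matrix=fused)


def _reindex(nm: NormalizedMatrix, ids: list[str]) -> sparse.csr_matrix:
    index = {e: i for i, e in enumerate(ids)}
    perm = np.array([index[e] for e in nm.entity_ids])
    coo = nm.matrix.tocoo()
    return sparse.coo_matrix(
        (coo.data, (perm[coo.row], perm[coo.col])), shape=(len(ids), len(ids))
    ).tocsr()


# ---------------------------------------------------------------------------
# inter-layer regression
# ---------------------------------------------------------------------------


def fit_regulatory_regression(
    expr: OmicsMatrix,
    cnv: OmicsMatrix,
    methy: OmicsMatrix,
    mirna: OmicsMatrix,
    targets: InteractionSet,
) -> RegulatoryCoefficients:
    """Per-gene OLS of expression on CNV, methylation and miRNA regulators.

    For gene i with regulators j = 1..m (from the miRNA-target pairs)::

        Y_i = b_cnv X_i_cnv + b_methy X_i_methy + sum_j b_ij X_j_mir + c + eps

    Matrices must be sample-aligned. An intercept c is included (it is ~0 on
    z-scored inputs and reported but not used as an edge weight). Rank
    deficiency (e.g. collinear regulators) is handled by the minimum-norm
    least-squares solution. Genes missing from the CNV or methylation layer,
    or with fewer samples than parameters, are marked unfit with a reason.
    """
    mats = {"expression": expr, "cnv": cnv, "methylation": methy, "mirna": mirna}
    sample_sets = {name: tuple(m.sample_ids) for name, m in mats.items()}
    if len(set(sample_sets.values())) != 1:
        raise ValidationError("matrices are not sample-aligned; run align_samples first")

    regulators = targets.targets_of_gene() if len(targets) else {}
    mir_index = {e: i for i, e in enumerate(mirna.entity_ids)}
    cnv_index = {e: i for i, e in enumerate(cnv.entity_ids)}
    methy_index = {e: i for i, e in enumerate(methy.entity_ids)}
    Xc, Xm, Xr = cnv.values, methy.values, mirna.values
    n = len(expr.sample_ids)

    fits: dict[str, GeneRegression] = {}
    for gi, gene in enumerate(expr.entity_ids):
        if gene not in cnv_index:
            fits[gene] = GeneRegression(gene, unfit_reason="missing_cnv")
            continue
        if gene not in methy_index:
            fits[gene] = GeneRegression(gene, unfit_reason="missing_methylation")
            continue
        mirs = [m for m in regulators.get(gene, []) if m in mir_index]
        cols = [Xc[cnv_index[gene]], Xm[methy_index[gene]]]
        cols += [Xr[mir_index[m]] for m in mirs]
        cols.append(np.ones(n))
        X = np.column_stack(cols)
        if n < X.shape[1]:
            fits[gene] = GeneRegression(gene, unfit_reason="insufficient_samples")
            continue
        y = expr.values[gi]
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = max(n - X.shape[1], 1)
        fits[gene] = GeneRegression(
            gene_id=gene,
            beta_cnv=float(beta[0]),
            beta_methy=float(beta[1]),
            mir_betas={m: float(b) for m, b in zip(mirs, beta[2:-1])},
            intercept=float(beta[-1]),
            residual_sd=float(np.sqrt(resid @ resid / dof)),
        )
    return RegulatoryCoefficients(fits)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def assemble_heterogeneous_network(
    layers: dict[str, NormalizedMatrix],
    coeffs: RegulatoryCoefficients | None = None,
) -> HeterogeneousNetwork:
    """Assemble the global network and its normalized transition matrix.

    ``layers`` maps each omics name to its intra-layer matrix (the fused
    matrix for the expression layer, normalized correlation matrices for the
    others). Inter-layer edges connect, for each fitted gene, its expression
    node to its CNV node (weight ``|beta_cnv|``), to its methylation node
    (``|beta_methy|``) and to each regulator miRNA node (``|beta_mir|``);
    zero coefficients and unfit genes contribute no edge. The global W̄ is
    the sqrt-row-sum symmetric normalization of the full block matrix.
    """
    for name in layers:
        if name not in OMICS_LAYERS:
            raise ValidationError(f"unknown layer {name!r}")
    nodes: list[tuple[str, str]] = []
    offsets: dict[str, int] = {}
    for name in OMICS_LAYERS:
        if name not in layers:
            continue
        offsets[name] = len(nodes)
        nodes.extend((e, name) for e in layers[name].entity_ids)
    n = len(nodes)

    rows, cols, vals = [], [], []
    edge_kinds: dict[tuple[int, int], str] = {}
    for name, nm in layers.items():
        off = offsets[name]
        coo = nm.matrix.tocoo()
        rows.append(coo.row + off)
        cols.append(coo.col + off)
        vals.append(coo.data)
        kind = "fused" if name == "expression" else "pcc"
        up = coo.row < coo.col
        for i, j in zip(coo.row[up] + off, coo.col[up] + off):
            edge_kinds[(int(i), int(j))] = kind

    if coeffs is not None and "expression" in layers:
        expr_index = {e: i for i, e in enumerate(layers["expression"].entity_ids)}
        layer_index = {
            name: {e: i for i, e in enumerate(layers[name].entity_ids)}
            for name in layers
            if name != "expression"
        }
        ir, ic, iv = [], [], []
        for gene, fit in coeffs.fits.items():
            if not fit.fitted or gene not in expr_index:
                continue
            gi = expr_index[gene] + offsets["expression"]
            pairs = []
            if "cnv" in layer_index and gene in layer_index["cnv"]:
                pairs.append((layer_index["cnv"][gene] + offsets["cnv"],
                              abs(fit.beta_cnv), "reg_cnv"))
            if "methylation" in layer_index and gene in layer_index["methylation"]:
                pairs.append((layer_index["methylation"][gene] + offsets["methylation"],
                              abs(fit.beta_methy), "reg_methy"))
            if "mirna" in layer_index:
                for mir, b in fit.mir_betas.items():
                    if mir in layer_index["mirna"]:
                        pairs.append((layer_index["mirna"][mir] + offsets["mirna"],
                                      abs(b), "reg_mir"))
            for j, w, kind in pairs:
                if w <= 0:
                    continue
                ir += [gi, j]
                ic += [j, gi]
                iv += [w, w]
                edge_kinds[(min(gi, j), max(gi, j))] = kind
        if ir:
            rows.append(np.asarray(ir))
            cols.append(np.asarray(ic))
            vals.append(np.asarray(iv, dtype=float))

    if rows:
        adjacency = sparse.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        ).tocsr()
        adjacency.eliminate_zeros()
    else:
        adjacency = sparse.csr_matrix((n, n))
    wbar = symmetric_normalize(adjacency).matrix
    return HeterogeneousNetwork(
        nodes=nodes, adjacency=adjacency, wbar=wbar, edge_kinds=edge_kinds
    )


# ---------------------------------------------------------------------------
# pipeline helpers
# ---------------------------------------------------------------------------


def prepare_matrices(matrices: dict[str, OmicsMatrix]) -> dict[str, OmicsMatrix]:
    """Sample-align all layers and z-score each entity row."""
    names = [n for n in OMICS_LAYERS if n in matrices]
    aligned = align_samples([matrices[n] for n in names])
    out = {}
    for name, m in zip(names, aligned):
        out[name] = m if m.normalized else normalize_features(m)
    return out


def build_layers(
    matrices: dict[str, OmicsMatrix],
    seeds: SeedSet,
    ppi: InteractionSet,
    p_threshold: float = 0.05,
) -> tuple[dict[str, CorrelationMatrix], NormalizedMatrix]:
    """Seed-anchored correlation matrices per layer plus the normalized PPI."""
    corrs = {
        name: compute_seed_correlations(m, seeds, p_threshold)
        for name, m in matrices.items()
    }
    expr_ids = matrices["expression"].entity_ids
    ppi_raw = ppi_matrix(ppi, expr_ids)
    ppi_bar = symmetric_normalize(ppi_raw, name="ppi", entity_ids=expr_ids)
    return corrs, ppi_bar


def layers_from_correlations(
    corrs: dict[str, CorrelationMatrix], ppi_bar: NormalizedMatrix
) -> dict[str, NormalizedMatrix]:
    """Normalize each layer and fuse the expression layer with the PPIs."""
    layers: dict[str, NormalizedMatrix] = {}
    for name, cm in corrs.items():
        bar = symmetric_normalize(cm.matrix, name=name, entity_ids=cm.entity_ids)
        if name == "expression":
            bar = fuse_expression_edges(bar, ppi_bar)
        layers[name] = bar
    return layers


def build_network(
    matrices: dict[str, OmicsMatrix],
    seeds: SeedSet,
    ppi: InteractionSet,
    targets: InteractionSet,
    p_threshold: float = 0.05,
) -> HeterogeneousNetwork:
    """End-to-end network construction from prepared (or raw) matrices."""
    if not all(m.normalized for m in matrices.values()):
        matrices = prepare_matrices(matrices)
    corrs, ppi_bar = build_layers(matrices, seeds, ppi, p_threshold)
    layers = layers_from_correlations(corrs, ppi_bar)
    coeffs = fit_regulatory_regression(
        matrices["expression"], matrices["cnv"], matrices["methylation"],
        matrices["mirna"], targets,
    )
    return assemble_heterogeneous_network(layers, coeffs)


def write_network(net: HeterogeneousNetwork, path) -> None:
    """Export the raw weighted edge list as TSV.

    Columns: id_a, omics_a, id_b, omics_b, weight, edge_kind.
    """
    coo = net.adjacency.tocoo()
    up = coo.row < coo.col
    with open(path, "w") as fh:
        fh.write("id_a\tomics_a\tid_b\tomics_b\tweight\tedge_kind\n")
        for i, j, w in zip(coo.row[up], coo.col[up], coo.data[up]):
            a, oa = net.nodes[i]
            b, ob = net.nodes[j]
            kind = net.edge_kinds.get((int(i), int(j)), "pcc")
            fh.write(f"{a}\t{oa}\t{b}\t{ob}\t{float(w)!r}\t{kind}\n")
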