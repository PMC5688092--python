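"""Prior scores and resistance-modified label propagation.

Each node v starts from a prior information score D_v: 1 for seeds, and for
non-seeds the fraction of its direct neighbors that are seeds, damped
exponentially when the node has fewer than ``alpha`` neighbors::

    D_v = n_v / N_v                      non-seed, N_v >= alpha
    D_v = e^(N_v - alpha) * n_v / N_v    non-seed, 0 < N_v < alpha
    D_v = 1                              seed
    D_v = 0                              isolated non-seed

Scores then diffuse over the normalized transition matrix W̄::

    S^t = lambda * f(S^{t-1}) + (1 - lambda) * D,    S^1 = D

where without resistance f(S)_v = sum_u S_u W̄_uv, and with resistance each
transition pays a small toll eps and flow into low-scoring, weakly reached
targets is cut entirely::

    SR_uv = 0                              if S_v < theta and max_t(S_t W̄_tv) < beta
    SR_uv = max(S_u W̄_uv - eps, 0)        otherwise

with eps = |V|/|E|^2 and beta = 1/|E| by default. The branch test uses the
previous iterate, so each update is a function of S^{t-1} only. Iteration
stops when the mean squared difference between consecutive iterates drops to
``tol`` (or at ``max_iter``, flagged as not converged). Resistance can only
lower scores, and every score keeps the lower bound (1 - lambda) * D_v.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse

from .io_formats import GENE_LAYERS, SeedSet, ValidationError
from .network import HeterogeneousNetwork

__all__ = [
    "PriorScores",
    "PropagationConfig",
    "ScoreVector",
    "compute_prior_scores",
    "resistance_transition",
    "propagate",
    "aggregate_gene_scores",
]

logger = logging.getLogger(__name__)


@dataclass
class PriorScores:
    """Per-node prior vector D with the neighbor-count threshold used."""

    values: np.ndarray
    alpha: int
    seed_nodes: np.ndarray  # indices of seed nodes


@dataclass
class PropagationConfig:
    """Tunable parameters of the propagation.

    lambda_mix is the propagation/prior mix (default 0.2); theta the
    score threshold of the resistance zero branch (default 0.005); eps_r and
    beta_r default to |V|/|E|^2 and 1/|E| of the network at hand when left
    as None; tol is the MSE stopping threshold (default 1e-5).
    """

    lambda_mix: float = 0.2
    theta: float = 0.005
    eps_r: float | None = None
    beta_r: float | None = None
    tol: float = 1e-5
    max_iter: int = 1000
    resistance_enabled: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.lambda_mix < 1.0):
            raise ValidationError("lambda_mix must lie in (0, 1)")
        if self.tol <= 0:
            raise ValidationError("tol must be positive")
        for name in ("eps_r", "beta_r"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be >= 0")

    def resolve(self, net: HeterogeneousNetwork) -> "PropagationConfig":
        """Fill network-derived defaults for eps_r and beta_r."""
        return replace(
            self,
            eps_r=self.eps_r if self.eps_r is not None else net.eps_resistance,
            beta_r=self.beta_r if self.beta_r is not None else net.beta_resistance,
        )


@dataclass
class ScoreVector:
    """Converged propagation scores with iteration diagnostics."""

    values: np.ndarray
    iterations_used: int
    final_mse: float
    converged: bool
    mse_history: list[float] = field(default_factory=list)


def compute_prior_scores(
    net: HeterogeneousNetwork, seeds: SeedSet, alpha: int = 50
) -> PriorScores:
    """Prior information score of every node.

    Neighbors are counted on the binary adjacency of the raw weighted
    network (any nonzero edge). Seeds absent from the network are skipped
    with a warning; isolated non-seeds get D = 0.
    """
    if alpha <= 0:
        raise ValidationError("alpha must be a positive neighbor-count threshold")
    seed_nodes = []
    for entry in seeds.entries:
        idx = net.node_index.get(tuple(entry))
        if idx is None:
            logger.warning("seed node %r not in network; skipped", entry)
        else:
            seed_nodes.append(idx)
    seed_nodes = np.asarray(sorted(seed_nodes), dtype=int)

    deg = net.degrees().astype(float)
    is_seed = np.zeros(net.n_nodes, dtype=bool)
    is_seed[seed_nodes] = True
    adj_bool = net.adjacency.copy()
    adj_bool.data = np.ones_like(adj_bool.data)
    n_seed_neighbors = adj_bool @ is_seed.astype(float)

    with np.errstate(divide="ignore", invalid="ignore", under="ignore"):
        frac = np.where(deg > 0, n_seed_neighbors / np.where(deg > 0, deg, 1.0), 0.0)
        damp = np.where(deg >= alpha, 1.0, np.exp(deg - alpha))
    D = frac * damp
    D[is_seed] = 1.0
    return PriorScores(values=D, alpha=alpha, seed_nodes=seed_nodes)


def _resistance_parts(
    S: np.ndarray, wbar: sparse.csr_matrix, theta: float, eps_r: float, beta_r: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Rows, cols and values of the nonzero SR entries (plus dimension)."""
    coo = wbar.tocoo()
    flow = S[coo.row] * coo.data  # S_u * W̄_uv per stored edge
    n = wbar.shape[0]
    col_max = np.zeros(n)
    np.maximum.at(col_max, coo.col, flow)
    zero_col = (S < theta) & (col_max < beta_r)
    sr = np.maximum(flow - eps_r, 0.0)
    sr[zero_col[coo.col]] = 0.0
    return coo.row, coo.col, sr, n


def resistance_transition(
    S: np.ndarray, wbar: sparse.spmatrix, cfg: PropagationConfig
) -> sparse.csr_matrix:
    """The resistance-modified transition matrix SR for a given score vector.

    SR_uv is zero when the target's score is below theta and no incoming
    flow reaches beta_r; otherwise the flow S_u W̄_uv minus the resistance
    eps_r, clamped at zero. Entries off the sparsity pattern of W̄ are zero
    under both branches, so the sparse result matches the dense definition.
    """
    if cfg.eps_r is None or cfg.beta_r is None:
        raise ValidationError("resolve eps_r/beta_r before building SR")
    wbar = sparse.csr_matrix(wbar, dtype=float)
    rows, cols, sr, n = _resistance_parts(
        np.asarray(S, dtype=float), wbar, cfg.theta, cfg.eps_r, cfg.beta_r
    )
    out = sparse.coo_matrix((sr, (rows, cols)), shape=(n, n)).tocsr()
    out.eliminate_zeros()
    return out


def propagate(
    net: HeterogeneousNetwork, D: PriorScores, cfg: PropagationConfig | None = None
) -> ScoreVector:
    """Iterate S^t = lambda * f(S^{t-1}) + (1 - lambda) * D to convergence.

    With resistance disabled f(S) = S W̄ exactly (the damped linear system
    whose fixed point is (1 - lambda)(I - lambda W̄)^-1 D). Non-convergence
    at max_iter returns a flagged result with a warning, not an exception.
    """
    cfg = (cfg or PropagationConfig()).resolve(net)
    lam = cfg.lambda_mix
    W = net.wbar
    prior = np.asarray(D.values, dtype=float)
    if not np.all(np.isfinite(prior)):
        raise ValidationError("prior scores must be finite")
    S = prior.copy()  # S^1 := D
    mse = np.inf
    it = 0
    history: list[float] = []
    for it in range(1, cfg.max_iter + 1):
        if cfg.resistance_enabled:
            _, cols, sr, n = _resistance_parts(S, W, cfg.theta, cfg.eps_r, cfg.beta_r)
            f = np.bincount(cols, weights=sr, minlength=n)
        else:
            f = W.T @ S  # sum_u S_u W̄_uv
        S_new = lam * f + (1.0 - lam) * prior
        diff = S_new - S
        mse = float(diff @ diff) / len(S)
        history.append(mse)
        S = S_new
        if mse <= cfg.tol:
            return ScoreVector(values=S, iterations_used=it, final_mse=mse,
                               converged=True, mse_history=history)
    logger.warning("propagation did not converge in %d iterations (MSE %.3g)", it, mse)
    return ScoreVector(values=S, iterations_used=it, final_mse=mse,
                       converged=False, mse_history=history)


def aggregate_gene_scores(
    S: ScoreVector | np.ndarray, net: HeterogeneousNetwork
) -> dict[str, float]:
    """Final per-gene score: max over the gene's expression/CNV/methylation
    nodes. miRNA nodes are excluded (only genes are ranked)."""
    values = S.values if isinstance(S, ScoreVector) else np.asarray(S, dtype=float)
    return {
        gene: float(values[idx].max())
        for gene, idx in ((g, np.asarray(ix)) for g, ix in net.gene_nodes.items())
    }
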