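"""Synthetic multi-omics bundles with planted disease-module structure.

The generator emulates the data model the pipeline expects: four
sample-aligned feature matrices (gene expression, CNV, methylation, miRNA
expression), a seed list, a STRING-like PPI edge list and a miRTarBase-like
miRNA->gene target list -- with known ground truth, so every stage of the
pipeline can be tested without external downloads.

Planted structure:

* disease modules -- the seeds of each omics are grouped a few per module;
  each module recruits additional non-seed entities up to ``module_size``
  and all members share one latent factor, ``x = sqrt(rho) f + sqrt(1-rho)
  noise``, giving pairwise Pearson correlation ~= rho within the module;
* expression is generated by the linear regulatory model the pipeline fits:
  ``Y = b_cnv X_cnv + b_methy X_methy + sum_j b_mir X_mir_j + eps``. Genes
  in CNV (methylation) modules get a nonzero planted coefficient for their
  layer, so the module signal reaches the expression layer; a dedicated set
  of regulated genes gets all three coefficient types for regression
  recovery; expression-seed modules plant their factor in the noise term
  (all coefficients zero), which keeps the model exact and yields
  within-module expression correlation ~= rho;
* the PPI graph is Erdos-Renyi at ``ppi_density``, with seed-seed and
  seed-to-own-module pair probabilities multiplied by
  ``seed_ppi_enrichment`` (disease genes cluster in interaction networks).

Everything is drawn from one ``numpy.random.default_rng(rng_seed)`` stream,
so a bundle is bit-reproducible from its configuration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    InteractionSet,
    OmicsMatrix,
    SeedSet,
    ValidationError,
    write_interactions,
    write_omics_matrix,
    write_seed_list,
)

__all__ = ["SimConfig", "SimBundle", "generate_bundle", "generate_null_bundle",
           "null_config", "write_bundle", "read_bundle"]


@dataclass
class SimConfig:
    """Study conditions of a synthetic bundle.

    Defaults are a desk-scale mirror of a tumor multi-omics cohort: 500
    genes x 300 samples, 60 miRNAs, 30 seed genes split 20/4/6 across the
    expression/CNV/methylation layers and 5 seed miRNAs (preserving the
    relative layer proportions of curated disease-gene lists), modules of 10
    entities at within-module correlation 0.8.
    """

    n_genes: int = 500
    n_mirnas: int = 60
    n_samples: int = 300
    n_seed_expression: int = 20
    n_seed_cnv: int = 4
    n_seed_methylation: int = 6
    n_seed_mirnas: int = 5
    module_size: int = 10
    seeds_per_module: int = 4
    rho: float = 0.8
    beta_cnv_range: tuple[float, float] = (0.8, 1.5)
    beta_methy_range: tuple[float, float] = (-1.2, -0.4)
    beta_mir_range: tuple[float, float] = (-0.8, -0.3)
    n_regulated_genes: int = 60
    regulators_per_gene: tuple[int, int] = (1, 3)
    noise_sd: float = 0.5
    ppi_density: float = 0.01
    seed_ppi_enrichment: float = 25.0
    ppi_weight_range: tuple[float, float] = (0.4, 0.99)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_genes, self.n_mirnas, self.n_samples, self.n_seed_expression,
            self.n_seed_cnv, self.n_seed_methylation, self.n_seed_mirnas,
            self.module_size, self.seeds_per_module,
        )
        if any(c <= 0 for c in counts):
            raise ValidationError("all counts must be positive")
        if not (0.0 <= self.rho < 1.0):
            raise ValidationError("rho must lie in [0, 1)")
        if self.n_samples < 10:
            raise ValidationError("need at least 10 samples")
        n_gene_modules = sum(
            -(-n // self.seeds_per_module)
            for n in (self.n_seed_expression, self.n_seed_cnv, self.n_seed_methylation)
        )
        if n_gene_modules * self.module_size + self.n_regulated_genes > self.n_genes:
            raise ValidationError(
                "module membership plus regulated genes exceed n_genes; "
                "reduce module_size or seed counts"
            )

    @property
    def n_seed_genes(self) -> int:
        return self.n_seed_expression + self.n_seed_cnv + self.n_seed_methylation


@dataclass
class SimBundle:
    """A generated dataset plus its ground truth."""

    config: SimConfig
    matrices: dict[str, OmicsMatrix]
    seeds: SeedSet
    ppi: InteractionSet
    targets: InteractionSet
    truth: dict


def _chunk(items: list, size: int) -> list[list]:
    return [items[i:i + size] for i in range(0, len(items), size)]


def _factor_rows(rng: np.random.Generator, k: int, n: int, rho: float) -> np.ndarray:
    f = rng.standard_normal(n)
    noise = rng.standard_normal((k, n))
    return np.sqrt(rho) * f + np.sqrt(1.0 - rho) * noise


def generate_bundle(cfg: SimConfig) -> SimBundle:
    """Generate a complete, sample-aligned multi-omics bundle."""
    rng = np.random.default_rng(cfg.rng_seed)
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    mirnas = [f"MIR{i:03d}" for i in range(cfg.n_mirnas)]
    samples = [f"S{i:03d}" for i in range(cfg.n_samples)]
    n = cfg.n_samples

    # --- seed assignment (disjoint across omics) and module recruitment ----
    perm = list(rng.permutation(cfg.n_genes))
    take = lambda k: [genes[perm.pop()] for _ in range(k)]
    seed_expr = take(cfg.n_seed_expression)
    seed_cnv = take(cfg.n_seed_cnv)
    seed_methy = take(cfg.n_seed_methylation)

    modules: dict[str, list[dict]] = {}
    for omics, seed_list in (
        ("expression", seed_expr), ("cnv", seed_cnv), ("methylation", seed_methy)
    ):
        modules[omics] = []
        for chunk in _chunk(seed_list, cfg.seeds_per_module):
            recruits = take(cfg.module_size - len(chunk))
            modules[omics].append({"seeds": chunk, "members": chunk + recruits})
    regulated = take(cfg.n_regulated_genes)

    mperm = list(rng.permutation(cfg.n_mirnas))
    mtake = lambda k: [mirnas[mperm.pop()] for _ in range(k)]
    seed_mir = mtake(cfg.n_seed_mirnas)
    modules["mirna"] = []
    for chunk in _chunk(seed_mir, cfg.seeds_per_module):
        recruits = mtake(min(cfg.module_size - len(chunk), len(mperm)))
        modules["mirna"].append({"seeds": chunk, "members": chunk + recruits})

    gidx = {g: i for i, g in enumerate(genes)}
    midx = {m: i for i, m in enumerate(mirnas)}

    # --- base matrices with planted module factors -------------------------
    X_cnv = rng.standard_normal((cfg.n_genes, n))
    X_methy = rng.standard_normal((cfg.n_genes, n))
    X_mir = rng.standard_normal((cfg.n_mirnas, n))
    for omics, X, idx in (
        ("cnv", X_cnv, gidx), ("methylation", X_methy, gidx), ("mirna", X_mir, midx)
    ):
        for mod in modules[omics]:
            rows = [idx[e] for e in mod["members"]]
            X[rows] = _factor_rows(rng, len(rows), n, cfg.rho)

    # --- miRNA regulator assignment ----------------------------------------
    lo_reg, hi_reg = cfg.regulators_per_gene
    regulator_map: dict[str, list[str]] = {}
    planted_mir: dict[str, dict[str, float]] = {}
    regulated_set = set(regulated)
    for g in genes:
        if g in regulated_set:
            k = int(rng.integers(lo_reg, hi_reg + 1))
        else:
            k = int(rng.integers(0, 3))  # background target-list entries
        if k:
            regs = [mirnas[i] for i in rng.choice(cfg.n_mirnas, size=k, replace=False)]
            regulator_map[g] = regs

    # --- planted regulatory coefficients ------------------------------------
    def draw(rng_, rangepair):
        lo, hi = rangepair
        return float(rng_.uniform(lo, hi))

    beta_cnv = np.zeros(cfg.n_genes)
    beta_methy = np.zeros(cfg.n_genes)
    for mod in modules["cnv"]:
        for g in mod["members"]:
            beta_cnv[gidx[g]] = draw(rng, cfg.beta_cnv_range)
    for mod in modules["methylation"]:
        for g in mod["members"]:
            beta_methy[gidx[g]] = draw(rng, cfg.beta_methy_range)
    for g in regulated:
        beta_cnv[gidx[g]] = draw(rng, cfg.beta_cnv_range)
        beta_methy[gidx[g]] = draw(rng, cfg.beta_methy_range)
        planted_mir[g] = {m: draw(rng, cfg.beta_mir_range) for m in regulator_map.get(g, [])}

    # --- expression via the linear regulatory model -------------------------
    expr_module_member: dict[str, int] = {}
    for mi, mod in enumerate(modules["expression"]):
        for g in mod["members"]:
            expr_module_member[g] = mi
    expr_factors = [rng.standard_normal(n) for _ in modules["expression"]]

    Y = np.zeros((cfg.n_genes, n))
    for g in genes:
        i = gidx[g]
        y = beta_cnv[i] * X_cnv[i] + beta_methy[i] * X_methy[i]
        for m, b in planted_mir.get(g, {}).items():
            y = y + b * X_mir[midx[m]]
        if g in expr_module_member:
            f = expr_factors[expr_module_member[g]]
            eps = np.sqrt(cfg.rho) * f + np.sqrt(1.0 - cfg.rho) * rng.standard_normal(n)
        else:
            eps = rng.standard_normal(n)
        Y[i] = y + cfg.noise_sd * eps

    # --- PPI graph with seed enrichment -------------------------------------
    seed_gene_set = set(seed_expr) | set(seed_cnv) | set(seed_methy)
    module_of_seed: dict[str, set[str]] = {}
    for omics in ("expression", "cnv", "methylation"):
        for mod in modules[omics]:
            for s in mod["seeds"]:
                module_of_seed[s] = set(mod["members"])
    iu, ju = np.triu_indices(cfg.n_genes, k=1)
    p = np.full(iu.shape, cfg.ppi_density)
    seed_idx = np.zeros(cfg.n_genes, dtype=bool)
    seed_idx[[gidx[g] for g in seed_gene_set]] = True
    enriched = seed_idx[iu] & seed_idx[ju]
    for s, members in module_of_seed.items():
        si = gidx[s]
        mrows = np.zeros(cfg.n_genes, dtype=bool)
        mrows[[gidx[g] for g in members if g != s]] = True
        enriched |= ((iu == si) & mrows[ju]) | ((ju == si) & mrows[iu])
    p[enriched] = np.minimum(cfg.ppi_density * cfg.seed_ppi_enrichment, 0.95)
    drawn = rng.random(iu.shape) < p
    wlo, whi = cfg.ppi_weight_range
    weights = rng.uniform(wlo, whi, size=int(drawn.sum()))
    ppi_edges = [
        (genes[a], genes[b], float(w))
        for a, b, w in zip(iu[drawn], ju[drawn], weights)
    ]

    # --- containers ----------------------------------------------------------
    def mat(name, X, ids):
        df = pd.DataFrame(X, index=pd.Index(ids, name="id"), columns=samples)
        return OmicsMatrix(name, df, normalized=False)

    matrices = {
        "expression": mat("expression", Y, genes),
        "cnv": mat("cnv", X_cnv, genes),
        "methylation": mat("methylation", X_methy, genes),
        "mirna": mat("mirna", X_mir, mirnas),
    }
    seeds = SeedSet(
        [(g, "expression") for g in seed_expr]
        + [(g, "cnv") for g in seed_cnv]
        + [(g, "methylation") for g in seed_methy]
        + [(m, "mirna") for m in seed_mir]
    )
    targets = InteractionSet(
        "mirna_target",
        [(m, g, 1.0) for g, regs in sorted(regulator_map.items()) for m in regs],
    )
    truth = {
        "config": dataclasses.asdict(cfg),
        "modules": {
            omics: [{"seeds": m["seeds"], "members": m["members"]} for m in mods]
            for omics, mods in modules.items()
        },
        "regulated_genes": regulated,
        "beta_cnv": {g: beta_cnv[gidx[g]] for g in genes if beta_cnv[gidx[g]] != 0},
        "beta_methy": {g: beta_methy[gidx[g]] for g in genes if beta_methy[gidx[g]] != 0},
        "beta_mir": planted_mir,
        "regulator_map": regulator_map,
        "null": cfg.rho == 0.0,
    }
    return SimBundle(
        config=cfg,
        matrices=matrices,
        seeds=seeds,
        ppi=InteractionSet("ppi", ppi_edges),
        targets=targets,
        truth=truth,
    )


def null_config(cfg: SimConfig | None = None, **overrides) -> SimConfig:
    """A configuration with all planted signal removed.

    rho = 0, every coefficient range collapsed to 0 and no PPI enrichment:
    seeds carry no information beyond their label.
    """
    base = cfg or SimConfig()
    fields = dataclasses.asdict(base)
    fields.update(
        rho=0.0,
        beta_cnv_range=(0.0, 0.0),
        beta_methy_range=(0.0, 0.0),
        beta_mir_range=(0.0, 0.0),
        seed_ppi_enrichment=1.0,
    )
    fields.update(overrides)
    return SimConfig(**fields)


def generate_null_bundle(cfg: SimConfig | None = None, **overrides) -> SimBundle:
    """Generate a bundle whose seeds carry no planted signal."""
    return generate_bundle(null_config(cfg, **overrides))


# ---------------------------------------------------------------------------
# disk round trip (the exact formats io_formats reads)
# ---------------------------------------------------------------------------


def write_bundle(bundle: SimBundle, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, m in bundle.matrices.items():
        write_omics_matrix(m, out / f"{name}.tsv")
    write_seed_list(bundle.seeds, out / "seeds.tsv")
    write_interactions(bundle.ppi, out / "ppi.tsv")
    with open(out / "targets.tsv", "w") as fh:
        for mir, gene, _ in bundle.targets.edges:
            fh.write(f"{mir}\t{gene}\n")
    with open(out / "truth.json", "w") as fh:
        json.dump(bundle.truth, fh, indent=2)


def read_bundle(indir: str | Path) -> dict:
    """Read a materialized bundle directory back into pipeline inputs."""
    from .io_formats import (
        read_mirna_targets, read_omics_matrix, read_ppi_edges, read_seed_list,
    )

    indir = Path(indir)
    matrices = {
        name: read_omics_matrix(indir / f"{name}.tsv", name)
        for name in ("expression", "cnv", "methylation", "mirna")
    }
    return {
        "matrices": matrices,
        "seeds": read_seed_list(indir / "seeds.tsv"),
        "ppi": read_ppi_edges(indir / "ppi.tsv", matrices["expression"].entity_ids),
        "targets": read_mirna_targets(indir / "targets.tsv"),
    }
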