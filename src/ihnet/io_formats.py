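"""Readers, writers and preprocessing for multi-omics inputs.

This module owns the plain-text interchange formats of the package and the
preprocessing that turns raw per-omics feature tables into sample-aligned,
per-entity z-scored matrices:

* omics feature matrices -- TSV, header row of sample ids, first column the
  gene/miRNA identifier (rows = entities, columns = patient samples);
* seed lists -- two-column TSV ``(identifier, omics)`` of entities already
  known to be disease-associated;
* protein-protein interactions -- three-column TSV ``(protein_a, protein_b,
  combined_score)`` on a STRING-like 0-1000 score scale;
* miRNA->target-gene pairs -- two-column TSV (miRTarBase-like);
* copy-number segment tables and refGene-style gene location tables, used to
  collapse segment-level CNV calls to per-gene values.

Coordinates are treated as 0-based half-open throughout; strand is ignored
for overlap computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OMICS_LAYERS",
    "GENE_LAYERS",
    "FormatError",
    "ValidationError",
    "OmicsMatrix",
    "SeedSet",
    "InteractionSet",
    "SegmentTable",
    "GeneLocationTable",
    "read_omics_matrix",
    "write_omics_matrix",
    "align_samples",
    "normalize_features",
    "map_cnv_segments_to_genes",
    "read_seed_list",
    "write_seed_list",
    "read_ppi_edges",
    "write_interactions",
    "read_mirna_targets",
    "read_segments",
    "read_gene_locations",
]

logger = logging.getLogger(__name__)

#: The four omics layers of the heterogeneous network.
OMICS_LAYERS = ("expression", "cnv", "methylation", "mirna")
#: The three layers whose entities are genes (miRNAs form the fourth layer).
GENE_LAYERS = ("expression", "cnv", "methylation")


class FormatError(ValueError):
    """Raised when an input file cannot be parsed as its declared format."""


class ValidationError(ValueError):
    """Raised when parsed input violates a container invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class OmicsMatrix:
    """One omics layer's feature matrix (entities x samples).

    Parameters
    ----------
    omics_name
        One of :data:`OMICS_LAYERS`.
    data
        DataFrame with entity identifiers as index and sample identifiers as
        columns. Missing measurements are NaN.
    normalized
        True once each row has been z-scored across samples.
    """

    omics_name: str
    data: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.omics_name not in OMICS_LAYERS:
            raise ValidationError(
                f"unknown omics layer {self.omics_name!r}; expected one of {OMICS_LAYERS}"
            )
        dup = self.data.index[self.data.index.duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate entity id(s): {sorted(set(dup))}")
        dup = self.data.columns[self.data.columns.duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate sample id(s): {sorted(set(dup))}")

    @property
    def entity_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def row(self, entity_id: str) -> np.ndarray:
        return self.data.loc[entity_id].to_numpy(dtype=float)


@dataclass
class SeedSet:
    """Known disease-associated entities, each tagged with its omics layer."""

    entries: list[tuple[str, str]]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for ident, omics in self.entries:
            if omics not in OMICS_LAYERS:
                raise ValidationError(
                    f"seed {ident!r} has unknown omics label {omics!r}"
                )
            if (ident, omics) in seen:
                raise ValidationError(f"duplicate seed entry ({ident!r}, {omics!r})")
            seen.add((ident, omics))

    def ids_for(self, omics_name: str) -> list[str]:
        """Seed identifiers of one layer, in entry order."""
        return [i for i, o in self.entries if o == omics_name]

    def gene_entries(self) -> list[tuple[str, str]]:
        """Seed entries in the gene layers (expression/cnv/methylation)."""
        return [(i, o) for i, o in self.entries if o in GENE_LAYERS]

    def gene_ids(self) -> set[str]:
        return {i for i, o in self.entries if o in GENE_LAYERS}

    def without(self, entry: tuple[str, str]) -> "SeedSet":
        """A copy with one (id, omics) entry removed."""
        return SeedSet([e for e in self.entries if e != tuple(entry)])

    def unmapped(self, matrices: dict[str, OmicsMatrix]) -> list[tuple[str, str]]:
        """Seed entries absent from the corresponding feature matrix."""
        out = []
        for ident, omics in self.entries:
            m = matrices.get(omics)
            if m is None or ident not in m.data.index:
                out.append((ident, omics))
        return out

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class InteractionSet:
    """Weighted pairwise interactions: PPIs or miRNA->target-gene pairs.

    For ``kind == "mirna_target"`` the first id is the miRNA and the second
    the target gene. Duplicate pairs are collapsed to the maximum weight and
    PPI self-edges are dropped at construction.
    """

    kind: str
    edges: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        if self.kind not in ("ppi", "mirna_target"):
            raise ValidationError(f"unknown interaction kind {self.kind!r}")
        collapsed: dict[tuple[str, str], float] = {}
        n_self = 0
        for a, b, w in self.edges:
            if not (0.0 < w <= 1.0):
                raise ValidationError(
                    f"edge ({a!r}, {b!r}) weight {w} outside (0, 1]"
                )
            if self.kind == "ppi":
                if a == b:
                    n_self += 1
                    continue
                key = (a, b) if a <= b else (b, a)
            else:
                key = (a, b)
            if key not in collapsed or w > collapsed[key]:
                collapsed[key] = w
        if n_self:
            logger.warning("dropped %d PPI self-edge(s)", n_self)
        self.edges = [(a, b, w) for (a, b), w in collapsed.items()]

    def targets_of_gene(self) -> dict[str, list[str]]:
        """For miRNA targets: map gene -> sorted list of its miRNA regulators."""
        if self.kind != "mirna_target":
            raise ValidationError("targets_of_gene only defined for mirna_target sets")
        out: dict[str, list[str]] = {}
        for mir, gene, _ in self.edges:
            out.setdefault(gene, []).append(mir)
        return {g: sorted(set(ms)) for g, ms in out.items()}

    def restrict_to(self, ids_a: set[str] | None, ids_b: set[str] | None) -> "InteractionSet":
        """Keep edges whose endpoints lie in the given id universes."""
        kept = [
            (a, b, w)
            for a, b, w in self.edges
            if (ids_a is None or a in ids_a) and (ids_b is None or b in ids_b)
        ]
        dropped = len(self.edges) - len(kept)
        if dropped:
            logger.info("dropped %d %s edge(s) with unmapped endpoints", dropped, self.kind)
        return InteractionSet(self.kind, kept)

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class SegmentTable:
    """Copy-number segments: rows of (sample, chromosome, start, end, value)."""

    data: pd.DataFrame  # columns: sample_id, chromosome, start, end, value

    REQUIRED = ("sample_id", "chromosome", "start", "end", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise FormatError(f"segment table missing column(s) {missing}")
        if (self.data["start"] < 0).any():
            raise ValidationError("segment start < 0")
        if (self.data["start"] >= self.data["end"]).any():
            raise ValidationError("segment with start >= end")


@dataclass
class GeneLocationTable:
    """Gene transcript spans; one row per gene (longest transcript kept)."""

    data: pd.DataFrame  # columns: gene_id, chromosome, tx_start, tx_end, strand

    REQUIRED = ("gene_id", "chromosome", "tx_start", "tx_end", "strand")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise FormatError(f"gene location table missing column(s) {missing}")
        if (self.data["tx_start"] >= self.data["tx_end"]).any():
            raise ValidationError("gene with tx_start >= tx_end")
        # keep the longest span per gene
        d = self.data.assign(_span=self.data["tx_end"] - self.data["tx_start"])
        d = d.sort_values(["gene_id", "_span"], ascending=[True, False])
        d = d.drop_duplicates("gene_id", keep="first").drop(columns="_span")
        self.data = d.reset_index(drop=True)


# ---------------------------------------------------------------------------
# omics matrix I/O and preprocessing
# ---------------------------------------------------------------------------


def read_omics_matrix(path: str | Path, omics_name: str) -> OmicsMatrix:
    """Read a TSV feature matrix (header = sample ids, column 1 = entity id).

    Non-numeric cells are parsed as missing (NaN). Duplicate entity or sample
    identifiers raise :class:`ValidationError` naming the duplicates.
    """
    try:
        # round_trip parsing keeps written float64 values bit-identical
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path} as a TSV matrix: {exc}") from exc
    if df.index.name is None or df.shape[1] == 0:
        raise FormatError(f"{path}: malformed header (need entity column + >=1 sample)")
    df = df.apply(lambda c: pd.to_numeric(c, errors="coerce"))
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return OmicsMatrix(omics_name=omics_name, data=df, normalized=False)


def write_omics_matrix(m: OmicsMatrix, path: str | Path) -> None:
    """Write a feature matrix in the TSV layout :func:`read_omics_matrix` reads."""
    m.data.to_csv(path, sep="\t", index_label="id")


def align_samples(matrices: Sequence[OmicsMatrix]) -> list[OmicsMatrix]:
    """Restrict every matrix to the common samples, in sorted order.

    Emulates extracting the patient samples shared by all omics before any
    cross-omics computation. Idempotent; raises on an empty intersection.
    """
    if len(matrices) < 2:
        raise ValidationError("align_samples needs at least two matrices")
    common: set[str] = set(matrices[0].sample_ids)
    for m in matrices[1:]:
        common &= set(m.sample_ids)
    if not common:
        raise ValidationError("no samples shared by all matrices")
    order = sorted(common)
    return [replace(m, data=m.data.loc[:, order]) for m in matrices]


def normalize_features(m: OmicsMatrix, max_missing_fraction: float = 0.2) -> OmicsMatrix:
    """Per-entity z-scoring across samples.

    Entities missing in more than ``max_missing_fraction`` of samples are
    dropped; remaining missing values are imputed to the entity's mean before
    scaling (which places them exactly at 0 after centering). Zero-variance
    rows map to all-zero rows. Standard deviation uses the population
    convention (``ddof=0``), so a non-constant row has mean 0 and sd 1.
    """
    if m.normalized:
        raise ValidationError("matrix is already normalized")
    X = m.values
    frac_missing = np.isnan(X).mean(axis=1)
    keep = frac_missing <= max_missing_fraction
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning(
            "%s: dropping %d entit(ies) missing in > %.0f%% of samples",
            m.omics_name, n_drop, 100 * max_missing_fraction,
        )
    X = X[keep]
    ids = [e for e, k in zip(m.entity_ids, keep) if k]
    with np.errstate(invalid="ignore"):
        row_mean = np.nanmean(X, axis=1, keepdims=True)
    row_mean = np.nan_to_num(row_mean)  # all-NaN rows -> 0
    X = np.where(np.isnan(X), row_mean, X)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    Z = np.divide(X - mu, sd, out=np.zeros_like(X), where=sd > 0)
    df = pd.DataFrame(Z, index=pd.Index(ids, name=m.data.index.name), columns=m.sample_ids)
    return OmicsMatrix(m.omics_name, df, normalized=True)


def map_cnv_segments_to_genes(
    segments: SegmentTable,
    locations: GeneLocationTable,
    samples: Sequence[str],
) -> OmicsMatrix:
    """Collapse segment-level CNV calls to per-gene values.

    For each gene and sample, the value is the overlap-length-weighted mean of
    all segment values intersecting the gene's transcript span [tx_start,
    tx_end). Genes with no overlapping segment in a sample get 0 (logged);
    genes on chromosomes absent from the segment table are skipped with a
    warning.
    """
    seg = segments.data
    known_chroms = set(seg["chromosome"].unique())
    loc = locations.data
    skip = ~loc["chromosome"].isin(known_chroms)
    if skip.any():
        logger.warning(
            "skipping %d gene(s) on chromosome(s) absent from the segment table: %s",
            int(skip.sum()), sorted(loc.loc[skip, "chromosome"].unique()),
        )
    loc = loc.loc[~skip]

    samples = list(samples)
    out = np.zeros((len(loc), len(samples)))
    n_uncovered = 0
    by_chrom_sample = {
        key: grp for key, grp in seg.groupby(["chromosome", "sample_id"], sort=False)
    }
    for gi, row in enumerate(loc.itertuples(index=False)):
        for si, sample in enumerate(samples):
            grp = by_chrom_sample.get((row.chromosome, sample))
            if grp is None:
                n_uncovered += 1
                continue
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            ov = np.minimum(ends, row.tx_end) - np.maximum(starts, row.tx_start)
            mask = ov > 0
            if not mask.any():
                n_uncovered += 1
                continue
            w = ov[mask].astype(float)
            out[gi, si] = float(np.average(grp["value"].to_numpy()[mask], weights=w))
    if n_uncovered:
        logger.info("%d gene/sample pair(s) without segment coverage set to 0", n_uncovered)
    df = pd.DataFrame(out, index=pd.Index(loc["gene_id"].tolist(), name="id"), columns=samples)
    return OmicsMatrix("cnv", df, normalized=False)


# ---------------------------------------------------------------------------
# seed / interaction / annotation I/O
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, n_cols: int, names: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < n_cols:
        raise FormatError(f"{path}: expected >= {n_cols} tab-separated columns")
    df = df.iloc[:, :n_cols]
    df.columns = list(names)
    return df


def read_seed_list(path: str | Path) -> SeedSet:
    """Read a two-column TSV of (identifier, omics) seed entries."""
    df = _read_tsv(path, 2, ["id", "omics"])
    return SeedSet([(r.id, r.omics) for r in df.itertuples(index=False)])


def write_seed_list(seeds: SeedSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for ident, omics in seeds.entries:
            fh.write(f"{ident}\t{omics}\n")


def read_ppi_edges(
    path: str | Path, expression_ids: Iterable[str] | None = None
) -> InteractionSet:
    """Read a three-column PPI TSV (protein_a, protein_b, combined_score).

    Scores on a STRING-like 0-1000 scale (any score > 1) are divided by 1000;
    scores already in (0, 1] are taken as-is. Edges with an endpoint absent
    from the expression matrix are dropped (the PPI network lives on the
    expression layer), with the dropped count logged.
    """
    df = _read_tsv(path, 3, ["a", "b", "score"])
    scores = df["score"].map(float)  # Python float() parsing round-trips exactly
    if (scores <= 0).any():
        raise ValidationError("PPI scores must be positive")
    if (scores > 1).any():
        scores = scores / 1000.0
    if (scores > 1).any():
        raise ValidationError("PPI scores exceed 1 even after /1000 rescale")
    edges = list(zip(df["a"], df["b"], scores))
    iset = InteractionSet("ppi", edges)
    if expression_ids is not None:
        ids = set(expression_ids)
        iset = iset.restrict_to(ids, ids)
    return iset


def read_mirna_targets(path: str | Path) -> InteractionSet:
    """Read a two-column (miRNA, target gene) TSV; weight defaults to 1."""
    df = _read_tsv(path, 2, ["mirna", "gene"])
    return InteractionSet(
        "mirna_target", [(r.mirna, r.gene, 1.0) for r in df.itertuples(index=False)]
    )


def write_interactions(iset: InteractionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b, w in iset.edges:
            fh.write(f"{a}\t{b}\t{float(w)!r}\n")


def read_segments(path: str | Path) -> SegmentTable:
    """Read a five-column (sample, chromosome, start, end, value) segment TSV."""
    df = _read_tsv(path, 5, SegmentTable.REQUIRED)
    df["start"] = pd.to_numeric(df["start"]).astype(int)
    df["end"] = pd.to_numeric(df["end"]).astype(int)
    df["value"] = pd.to_numeric(df["value"]).astype(float)
    return SegmentTable(df)


def read_gene_locations(path: str | Path) -> GeneLocationTable:
    """Read a refGene-style column subset (gene, chrom, txStart, txEnd, strand)."""
    df = _read_tsv(path, 5, GeneLocationTable.REQUIRED)
    df["tx_start"] = pd.to_numeric(df["tx_start"]).astype(int)
    df["tx_end"] = pd.to_numeric(df["tx_end"]).astype(int)
    return GeneLocationTable(df)
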