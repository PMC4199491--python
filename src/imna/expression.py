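"""Probe-level expression matrices: loading, filtering, normalization, clustering.

The substrate of the whole pipeline is a probe x array intensity table from a
sorted-cell microarray atlas (several cell populations, each profiled in
replicate).  This module implements the preprocessing chain applied before any
network learning: removal of never-expressed probes, log2 transformation with
per-probe mean-centering across all conditions, pairwise Pearson correlation of
arrays with hierarchical clustering, and replicate collapsing to one column per
population.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

RAW_INTENSITY = "raw_intensity"
LOG2_CENTERED = "log2_centered"

#: Probes whose raw intensity never reaches this value are treated as unexpressed.
DEFAULT_EXPRESSION_THRESHOLD = 100.0

_ARRAY_ID_RE = re.compile(r"^(?P<population>.+)__rep(?P<replicate>\d+)$")


class ScaleError(ValueError):
    """Operation applied to a matrix on the wrong scale."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but degenerate for the requested operation."""


@dataclass(frozen=True)
class ArrayInfo:
    """Metadata for one array: which cell population, which replicate."""

    array_id: str
    population: str
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate}")


def parse_array_id(array_id: str) -> ArrayInfo:
    """Parse ``<population>__rep<k>`` into :class:`ArrayInfo`.

    Ids without the suffix are treated as single-replicate populations.
    """
    m = _ARRAY_ID_RE.match(array_id)
    if m:
        return ArrayInfo(array_id, m.group("population"), int(m.group("replicate")))
    return ArrayInfo(array_id, array_id, 1)


@dataclass
class ExpressionMatrix:
    """A probe x array value table with array metadata.

    ``values`` is indexed by probe id with one column per array id;
    ``gene_symbols`` maps probe id -> gene symbol (possibly many-to-one);
    ``scale`` is either ``raw_intensity`` or ``log2_centered``.
    """

    values: pd.DataFrame
    gene_symbols: pd.Series
    arrays: list[ArrayInfo]
    scale: str = RAW_INTENSITY

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.scale not in (RAW_INTENSITY, LOG2_CENTERED):
            raise ValueError(f"unknown scale {self.scale!r}")
        if list(self.values.columns) != [a.array_id for a in self.arrays]:
            raise ValueError("values columns do not match array metadata order")
        if not self.values.index.is_unique:
            raise ValueError("probe ids must be unique")
        keys = [(a.population, a.replicate) for a in self.arrays]
        if len(set(keys)) != len(keys):
            raise ValueError("(population, replicate) pairs must be unique")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        missing = self.values.index.difference(self.gene_symbols.index)
        if len(missing):
            raise ValueError(f"{len(missing)} probes lack a gene symbol mapping")
        if self.scale == RAW_INTENSITY and (self.values.to_numpy() <= 0).any():
            raise ValueError("raw intensities must be strictly positive")

    # -- convenience -------------------------------------------------------

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def array_ids(self) -> list[str]:
        return [a.array_id for a in self.arrays]

    @property
    def populations(self) -> list[str]:
        """Populations in first-appearance order."""
        seen: dict[str, None] = {}
        for a in self.arrays:
            seen.setdefault(a.population, None)
        return list(seen)

    def arrays_of(self, population: str) -> list[str]:
        ids = [a.array_id for a in self.arrays if a.population == population]
        if not ids:
            raise KeyError(f"unknown population {population!r}")
        return ids

    def subset_probes(self, probe_ids) -> "ExpressionMatrix":
        probe_ids = list(probe_ids)
        return ExpressionMatrix(
            values=self.values.loc[probe_ids],
            gene_symbols=self.gene_symbols.loc[probe_ids],
            arrays=list(self.arrays),
            scale=self.scale,
        )

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "gene_symbol", self.gene_symbols.loc[out.index])
        out.index.name = "probe_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, scale: str = RAW_INTENSITY) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="probe_id")
        if "gene_symbol" not in df.columns:
            raise ValueError(f"{path}: missing gene_symbol column")
        symbols = df["gene_symbol"].astype(str)
        values = df.drop(columns="gene_symbol").astype(float)
        arrays = [parse_array_id(c) for c in values.columns]
        return cls(values=values, gene_symbols=symbols, arrays=arrays, scale=scale)


@dataclass
class CorrelationMatrix:
    """Symmetric array x array Pearson correlation with unit diagonal."""

    labels: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.r.shape != (n, n):
            raise ValueError("correlation matrix shape mismatch")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-12):
            raise ValueError("correlation diagonal must be 1")
        if np.any(np.abs(self.r) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.r, index=self.labels, columns=self.labels).to_csv(path, sep="\t")


@dataclass
class Dendrogram:
    """Agglomerative merge tree over arrays (scipy linkage encoding)."""

    labels: list[str]
    linkage: np.ndarray
    method: str = "average"
    metric: str = "one_minus_pearson"

    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, n_clusters: int) -> dict[str, int]:
        """Flat clustering into ``n_clusters`` groups, label -> cluster id."""
        flat = hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in flat)))

    def to_newick(self) -> str:
        """Newick string; branch lengths are merge-height deltas."""
        root = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height):
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(root, root.dist) + ";"


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def filter_expressed_probes(
    matrix: ExpressionMatrix, threshold: float = DEFAULT_EXPRESSION_THRESHOLD
) -> ExpressionMatrix:
    """Drop probes whose raw intensity is below ``threshold`` in every array.

    A probe is kept iff its value reaches ``threshold`` (inclusive) in at least
    one array; probes that never do are considered unexpressed.  Probe order is
    preserved and the array set is unchanged.
    """
    if matrix.scale != RAW_INTENSITY:
        raise ScaleError("filter_expressed_probes requires a raw-intensity matrix")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    keep = (matrix.values.to_numpy() >= threshold).any(axis=1)
    if not keep.any():
        raise DegenerateInputError("no expressed probes at this threshold")
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_expressed_probes: removed %d of %d probes", n_removed, len(keep))
    return matrix.subset_probes(matrix.values.index[keep])


def normalize_log2_center(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2-transform and mean-center each probe across all arrays."""
    if matrix.scale != RAW_INTENSITY:
        raise ScaleError("normalize_log2_center requires a raw-intensity matrix")
    vals = matrix.values.to_numpy()
    if (vals <= 0).any():
        i, j = np.argwhere(vals <= 0)[0]
        raise ValueError(
            f"non-positive value at probe {matrix.values.index[i]!r}, "
            f"array {matrix.values.columns[j]!r}"
        )
    log2 = np.log2(vals)
    centered = log2 - log2.mean(axis=1, keepdims=True)
    return ExpressionMatrix(
        values=pd.DataFrame(centered, index=matrix.values.index, columns=matrix.values.columns),
        gene_symbols=matrix.gene_symbols,
        arrays=list(matrix.arrays),
        scale=LOG2_CENTERED,
    )


def center_rows(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Re-center a log2 matrix row-wise (idempotent on centered input)."""
    vals = matrix.values.to_numpy()
    centered = vals - vals.mean(axis=1, keepdims=True)
    return replace(
        matrix,
        values=pd.DataFrame(centered, index=matrix.values.index, columns=matrix.values.columns),
        scale=LOG2_CENTERED,
    )


def correlate_and_cluster(
    matrix: ExpressionMatrix, linkage: str = "average"
) -> tuple[CorrelationMatrix, Dendrogram]:
    """Pairwise Pearson correlation of arrays and agglomerative clustering.

    Distance is ``1 - r``; zero-variance probe rows are dropped from the
    correlation (only), with the count logged.
    """
    if matrix.scale != LOG2_CENTERED:
        raise ScaleError("correlate_and_cluster expects a log2-centered matrix")
    if len(matrix.arrays) < 2:
        raise ValueError("need at least 2 arrays to correlate")
    vals = matrix.values.to_numpy()
    var = vals.var(axis=1)
    keep = var > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("correlate_and_cluster: dropped %d zero-variance probe rows", n_dropped)
    if keep.sum() < 2:
        raise DegenerateInputError(
            "fewer than 2 probe rows with variance; correlation undefined")
    r = np.corrcoef(vals[keep].T)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    corr = CorrelationMatrix(labels=matrix.array_ids, r=r)
    dist = squareform(np.maximum(1.0 - r, 0.0), checks=False)
    Z = hierarchy.linkage(dist, method=linkage)
    dend = Dendrogram(labels=matrix.array_ids, linkage=Z, method=linkage)
    return corr, dend


def collapse_replicates(matrix: ExpressionMatrix, how: str = "mean") -> ExpressionMatrix:
    """Average replicate arrays, producing one column per population."""
    if how != "mean":
        raise ValueError(f"unsupported collapse method {how!r}")
    pops = matrix.populations
    cols = {p: matrix.values[matrix.arrays_of(p)].mean(axis=1) for p in pops}
    values = pd.DataFrame(cols, index=matrix.values.index)
    arrays = [ArrayInfo(array_id=p, population=p, replicate=1) for p in pops]
    return ExpressionMatrix(
        values=values,
        gene_symbols=matrix.gene_symbols,
        arrays=arrays,
        scale=matrix.scale,
    )


def collapse_to_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Probe -> gene collapse keeping, per gene, the probe with highest mean value.

    Deterministic: ties broken by probe input order.  Intended for gene-level
    analyses; the pipeline otherwise works at probe level.
    """
    means = matrix.values.mean(axis=1)
    best: dict[str, str] = {}
    for probe in matrix.values.index:
        gene = matrix.gene_symbols.loc[probe]
        if gene not in best or means[probe] > means[best[gene]]:
            best[gene] = probe
    keep = [p for p in matrix.values.index if best[matrix.gene_symbols.loc[p]] == p]
    return matrix.subset_probes(keep)
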