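"""GMT gene sets, per-population module mapping, and overrepresentation tests.

The module map asks, for each cell population and each gene set, whether the
set is statistically over-represented among the genes that are up (log2 value
>= +1) or down (<= -1) in that population, on the replicate-collapsed matrix
(one column per population).  Significant cells are reported with the mean
expression of the hit genes, the statistic displayed in module-map heat maps.
Overrepresentation of a query gene list against a GMT collection (the
functional-annotation step) reuses the same one-sided hypergeometric kernel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexp import benjamini_hochberg, overlap_fisher_counts
from .expression import ExpressionMatrix, LOG2_CENTERED, ScaleError

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets: name -> (description, member set)."""

    sets: dict[str, tuple[str, set[str]]]

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def members(self, name: str) -> set[str]:
        return self.sets[name][1]

    def names(self) -> list[str]:
        return list(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>member...`` per line.

    Duplicate members within a set are deduplicated with a logged warning;
    lines with fewer than three fields are a parse error.
    """
    sets: dict[str, tuple[str, set[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has <3 fields")
            name, desc, members = fields[0], fields[1], fields[2:]
            members = [m for m in members if m]
            unique = set(members)
            if len(unique) < len(members):
                logger.warning("%s:%d: set %r has duplicate members", path, lineno, name)
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = (desc, unique)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


@dataclass
class ModuleMapResult:
    """Per (population, set, direction) enrichment calls.

    ``table`` columns: population, gene_set, direction, hits, set_size,
    threshold_size, universe_size, p_value, q_value, state, display_value.
    ``state`` is 'enriched' (direction up), 'depleted' (direction down) or
    'none'; display_value is the mean log2 value of the hit genes and is NaN
    when there are no hits.
    """

    table: pd.DataFrame
    up_cut: float
    down_cut: float

    def display_matrix(self, direction: str = "up") -> pd.DataFrame:
        """Set x population matrix of display values (0 where state is none)."""
        sub = self.table[self.table["direction"] == direction]
        mat = sub.pivot(index="gene_set", columns="population", values="display_value")
        state = sub.pivot(index="gene_set", columns="population", values="state")
        return mat.where(state != "none", 0.0).fillna(0.0)

    def significant(self, direction: str | None = None) -> pd.DataFrame:
        sub = self.table[self.table["state"] != "none"]
        if direction is not None:
            sub = sub[sub["direction"] == direction]
        return sub

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def module_map(
    matrix: ExpressionMatrix,
    sets: GeneSetCollection,
    up_cut: float = 1.0,
    down_cut: float = -1.0,
    alpha: float = 0.05,
    fdr: float = 0.05,
) -> ModuleMapResult:
    """Gene-set enrichment/depletion per population at fixed log2 cutoffs.

    For each population, U_up = genes with value >= ``up_cut`` and U_down =
    genes with value <= ``down_cut``; each set is tested for overrepresentation
    among U_up (enriched) and U_down (depleted) by a one-sided hypergeometric
    test over the matrix's gene universe.  BH runs across all
    (population, set, direction) tests of one call.
    """
    if matrix.scale != LOG2_CENTERED:
        raise ScaleError("module_map expects a log2-centered matrix")
    universe = set(matrix.values.index)
    n_universe = len(universe)
    if all(not (sets.members(s) & universe) for s in sets):
        raise ValueError("gene-set collection is disjoint from the matrix universe")

    rows = []
    for pop in matrix.populations:
        col = matrix.values[matrix.arrays_of(pop)].mean(axis=1)
        for direction, thr_ids in (
            ("up", set(col.index[col >= up_cut])),
            ("down", set(col.index[col <= down_cut])),
        ):
            for name in sets:
                members = sets.members(name) & universe
                hits = members & thr_ids
                res = overlap_fisher_counts(
                    a=len(hits),
                    b=len(thr_ids) - len(hits),
                    c=len(members) - len(hits),
                    d=n_universe - len(thr_ids) - len(members) + len(hits),
                )
                rows.append({
                    "population": pop,
                    "gene_set": name,
                    "direction": direction,
                    "hits": len(hits),
                    "set_size": len(members),
                    "threshold_size": len(thr_ids),
                    "universe_size": n_universe,
                    "p_value": res.p_one_sided,
                    "display_value": float(col.loc[sorted(hits)].mean()) if hits else np.nan,
                })
    table = pd.DataFrame(rows)
    table["q_value"] = benjamini_hochberg(table["p_value"].to_numpy())
    sig = (table["p_value"] < alpha) & (table["q_value"] < fdr)
    table["state"] = np.where(
        ~sig, "none", np.where(table["direction"] == "up", "enriched", "depleted")
    )
    order = ["population", "gene_set", "direction", "hits", "set_size",
             "threshold_size", "universe_size", "p_value", "q_value", "state",
             "display_value"]
    return ModuleMapResult(table=table[order], up_cut=up_cut, down_cut=down_cut)


def overrepresentation(
    query,
    sets: GeneSetCollection,
    universe,
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric overrepresentation of ``query`` per gene set.

    Returns rows (gene_set, overlap, set_size, query_size, p_value, q_value)
    sorted by p and filtered at q < ``fdr_cut``; BH runs across all sets.
    """
    query, universe = set(query), set(universe)
    if not query <= universe:
        raise ValueError("query must be contained in the universe")
    rows = []
    for name in sets:
        members = sets.members(name) & universe
        if not members:
            continue
        res = overlap_fisher_counts(
            a=len(query & members),
            b=len(query) - len(query & members),
            c=len(members) - len(query & members),
            d=len(universe) - len(query | members),
        )
        rows.append({
            "gene_set": name,
            "overlap": res.a,
            "set_size": len(members),
            "query_size": len(query),
            "p_value": res.p_one_sided,
            "log10_p": res.log10_p,
        })
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no gene set intersects the universe")
    table["q_value"] = benjamini_hochberg(table["p_value"].to_numpy())
    table = table.sort_values(["p_value", "gene_set"], kind="stable")
    return table[table["q_value"] < fdr_cut].reset_index(drop=True)
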