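"""Iterative module network analysis: seeded multi-run regulator ranking.

A single module-network run is unstable: which regulators end up in the
regulation programs depends on the random initialization.  The iterative
procedure therefore runs the learner many times with different seeds, counts
for each candidate regulator the fraction of runs in which it appears in at
least one regulation program ("frequency"), and ranks regulators by that
frequency.  The module count and run count are chosen by sweeping a grid and
scoring each cell by the recovery of a known-regulator training list; the
ranking itself is validated by a GSEA enrichment score of the known list.
Finally, each regulator's predicted activated/repressed targets are extracted
from the archived models and validated against an independent
knockout-vs-control differential-expression contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexp import DEResult, OverlapResult, overlap_fisher
from .expression import ExpressionMatrix, collapse_replicates
from .genesets import GeneSetCollection, overrepresentation
from .modnet import ModuleNetworkModel, ScoreHyperparameters, learn_model, model_regulators

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Run archive and frequency ranking
# ---------------------------------------------------------------------------


@dataclass
class RunRecord:
    seed: int
    model: ModuleNetworkModel
    regulators: set[tuple[str, int, int]]  # (regulator, module, sign)

    def regulator_ids(self) -> set[str]:
        return {r for r, _, _ in self.regulators}


@dataclass
class RunArchive:
    """Every model from one multi-run campaign, in run order."""

    runs: list[RunRecord]
    regulator_ids: list[str]
    M: int

    def __len__(self) -> int:
        return len(self.runs)

    def union_regulators(self, first_k: int | None = None) -> set[str]:
        k = len(self.runs) if first_k is None else first_k
        out: set[str] = set()
        for rec in self.runs[:k]:
            out |= rec.regulator_ids()
        return out

    def best_run(self) -> RunRecord:
        return max(self.runs, key=lambda rec: rec.model.total_score)

    def to_dir(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for i, rec in enumerate(self.runs):
            rec.model.to_json(outdir / f"model_run{i:03d}_seed{rec.seed}.json")


@dataclass
class FrequencyTable:
    """Regulator -> fraction of runs appearing in any program, with ranks.

    A frequency of 1.0 means the regulator appeared in every run.  Ranks are
    1 = highest frequency; ties broken by lexicographic regulator id.
    """

    table: pd.DataFrame  # index: regulator; columns: frequency, rank
    n_runs: int

    def frequency(self, regulator: str) -> float:
        return float(self.table.loc[regulator, "frequency"])

    def ranked_ids(self) -> list[str]:
        return list(self.table.sort_values("rank").index)

    def to_tsv(self, path) -> None:
        self.table.sort_values("rank").rename_axis("regulator").to_csv(path, sep="\t")


def frequency_table(archive: RunArchive) -> FrequencyTable:
    counts = {r: 0 for r in archive.regulator_ids}
    for rec in archive.runs:
        for r in rec.regulator_ids():
            counts[r] += 1
    n = len(archive.runs)
    df = pd.DataFrame({"frequency": {r: c / n for r, c in counts.items()}})
    order = sorted(df.index, key=lambda r: (-df.loc[r, "frequency"], r))
    df["rank"] = pd.Series({r: i + 1 for i, r in enumerate(order)})
    return FrequencyTable(table=df, n_runs=n)


def run_imna(
    matrix: ExpressionMatrix,
    regulator_ids,
    M: int,
    n_runs: int,
    base_seed: int = 0,
    max_depth: int = 5,
    max_sweeps: int = 20,
    h: ScoreHyperparameters = ScoreHyperparameters(),
    max_regulators: int | None = None,
) -> tuple[FrequencyTable, RunArchive]:
    """Run the learner ``n_runs`` times (run r uses seed ``base_seed + r``)
    and rank regulators by appearance frequency across runs."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    regulator_ids = list(regulator_ids)
    runs: list[RunRecord] = []
    for r in range(n_runs):
        seed = base_seed + r
        try:
            kwargs = {} if max_regulators is None else \
                {"max_regulators": max_regulators}
            model = learn_model(matrix, regulator_ids, M=M, seed=seed,
                                max_depth=max_depth, max_sweeps=max_sweeps, h=h,
                                **kwargs)
        except Exception as exc:  # annotate with the failing run index
            raise RuntimeError(f"learner failed in run {r} (seed {seed}): {exc}") from exc
        regs = model_regulators(model, matrix)
        runs.append(RunRecord(seed=seed, model=model, regulators=regs))
        logger.info("run %d/%d: score %.2f, %d regulators",
                    r + 1, n_runs, model.total_score, len({x for x, _, _ in regs}))
    archive = RunArchive(runs=runs, regulator_ids=regulator_ids, M=M)
    return frequency_table(archive), archive


# ---------------------------------------------------------------------------
# Parameter sweep scored by known-regulator recovery
# ---------------------------------------------------------------------------


def recovery_percent(archive: RunArchive, known, first_k: int | None = None) -> float:
    """Percent of the known list found in the regulator union of the first k runs."""
    known = set(known)
    if not known:
        raise ValueError("known set must be non-empty")
    found = archive.union_regulators(first_k) & known
    return 100.0 * len(found) / len(known)


@dataclass
class SweepResult:
    """Known-regulator recovery over a (module count x run count) grid."""

    grid: pd.DataFrame  # index: module count, columns: run count, values: percent
    best: tuple[int, int]  # (m, k) argmax, ties to smaller m then smaller k

    def to_csv(self, path) -> None:
        self.grid.rename_axis("modules").to_csv(path)


def parameter_sweep(
    matrix: ExpressionMatrix,
    regulator_ids,
    module_grid,
    iteration_grid,
    known,
    base_seed: int = 0,
    **learner_kwargs,
) -> tuple[SweepResult, dict[int, RunArchive]]:
    """Fill the recovery grid, reusing one archive of max(iteration_grid) runs
    per module count.  Recovery is cumulative over the first k runs, hence
    non-decreasing in k for fixed m."""
    module_grid = sorted(set(int(m) for m in module_grid))
    iteration_grid = sorted(set(int(k) for k in iteration_grid))
    if not module_grid or not iteration_grid:
        raise ValueError("grids must be non-empty")
    archives: dict[int, RunArchive] = {}
    rows = {}
    for m in module_grid:
        _, archive = run_imna(matrix, regulator_ids, M=m,
                              n_runs=max(iteration_grid), base_seed=base_seed,
                              **learner_kwargs)
        archives[m] = archive
        rows[m] = {k: recovery_percent(archive, known, first_k=k)
                   for k in iteration_grid}
    grid = pd.DataFrame(rows).T.loc[module_grid, iteration_grid]
    flat_best, best_cell = -1.0, (module_grid[0], iteration_grid[0])
    for m in module_grid:
        for k in iteration_grid:
            if grid.loc[m, k] > flat_best:
                flat_best, best_cell = grid.loc[m, k], (m, k)
    return SweepResult(grid=grid, best=best_cell), archives


# ---------------------------------------------------------------------------
# GSEA enrichment score of a gene/regulator set on a ranking
# ---------------------------------------------------------------------------


@dataclass
class GseaResult:
    es: float
    running_sum: np.ndarray = field(repr=False)
    p_value: float | None
    p_w: int
    n_perm: int


def _running_es(is_hit: np.ndarray, weights: np.ndarray) -> tuple[float, np.ndarray]:
    hit_w = np.where(is_hit, weights, 0.0)
    total_hit = hit_w.sum()
    if total_hit == 0:
        hit_w = is_hit.astype(float)  # all-zero weights: fall back to unweighted hits
        total_hit = hit_w.sum()
    n_miss = int((~is_hit).sum())
    steps = np.where(is_hit, hit_w / total_hit, -1.0 / n_miss)
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), running


def gsea_es(
    ranking: FrequencyTable | list[str],
    gene_set,
    p_w: int = 1,
    n_perm: int = 1000,
    seed: int = 0,
    weights: np.ndarray | None = None,
) -> GseaResult:
    """Enrichment score of ``gene_set`` on a ranked list (classic GSEA walk).

    Walking the ranking from rank 1, a hit increments the running sum by
    w_i / sum(set weights) with w_i = frequency_i ** p_w (p_w = 0 gives the
    classic unweighted statistic), a miss decrements it by 1/(n - |set|); the
    ES is the signed extremum.  The permutation p-value is one-sided, matching
    the observed ES sign, over seeded permutations of the hit labels.
    """
    if p_w not in (0, 1):
        raise ValueError("p_w must be 0 or 1")
    if isinstance(ranking, FrequencyTable):
        ids = ranking.ranked_ids()
        w = np.asarray([ranking.frequency(r) for r in ids]) if p_w == 1 else \
            np.ones(len(ids))
    else:
        ids = list(ranking)
        if weights is None:
            w = np.ones(len(ids))
        else:
            w = np.asarray(weights, dtype=float)
        if p_w == 0:
            w = np.ones(len(ids))
    gene_set = set(gene_set)
    n = len(ids)
    if not gene_set or not gene_set <= set(ids):
        raise ValueError("gene_set must be a non-empty subset of the ranked ids")
    if len(gene_set) >= n:
        raise ValueError("gene_set must be a proper subset of the ranked ids")
    is_hit = np.asarray([i in gene_set for i in ids])
    es, running = _running_es(is_hit, w)

    p_value = None
    if n_perm and n_perm > 0:
        rng = np.random.default_rng(seed)
        k = len(gene_set)
        more_extreme = 0
        for _ in range(n_perm):
            perm_hit = np.zeros(n, dtype=bool)
            perm_hit[rng.choice(n, size=k, replace=False)] = True
            es_p, _ = _running_es(perm_hit, w)
            if (es >= 0 and es_p >= es) or (es < 0 and es_p <= es):
                more_extreme += 1
        p_value = (1 + more_extreme) / (1 + n_perm)
    return GseaResult(es=es, running_sum=running, p_value=p_value, p_w=p_w,
                      n_perm=n_perm or 0)


# ---------------------------------------------------------------------------
# Regulator target extraction and validation
# ---------------------------------------------------------------------------


@dataclass
class TargetPrediction:
    """Predicted activated or repressed targets of one regulator."""

    regulator: str
    direction: str  # 'activated' | 'repressed'
    module_ids: list[int]
    targets: set[str]
    filter_cut: float
    context_populations: list[str]

    @property
    def module_count(self) -> int:
        return len(self.module_ids)

    def to_dict(self) -> dict:
        return {
            "regulator": self.regulator,
            "direction": self.direction,
            "module_ids": self.module_ids,
            "module_count": self.module_count,
            "targets": sorted(self.targets),
            "filter_cut": self.filter_cut,
            "context_populations": self.context_populations,
        }


def extract_targets(
    source: RunArchive | RunRecord,
    matrix: ExpressionMatrix,
    regulator: str,
    direction: str = "activated",
    filter_cut: float = 1.0,
    context_populations: list[str] | None = None,
    mode: str = "best",
) -> TargetPrediction:
    """Union the member genes of the modules a regulator is predicted to drive
    (sign +1 for activated, -1 for repressed), then keep only genes whose
    replicate-collapsed log2 value clears ``filter_cut`` (>= +cut for
    activated, <= -cut for repressed) in at least one context population.

    Default context: the population where the regulator's own collapsed
    expression is maximal.  ``mode`` 'best' uses the best-scoring archived run;
    'union' pools modules across every archived run.
    """
    if direction not in ("activated", "repressed"):
        raise ValueError("direction must be 'activated' or 'repressed'")
    want_sign = +1 if direction == "activated" else -1
    if isinstance(source, RunArchive):
        records = [source.best_run()] if mode == "best" else source.runs
    else:
        records = [source]

    collapsed = collapse_replicates(matrix)
    if context_populations is None:
        reg_profile = collapsed.values.loc[regulator]
        context_populations = [str(reg_profile.idxmax())]
    for p in context_populations:
        if p not in collapsed.populations:
            raise ValueError(f"unknown context population {p!r}")

    module_ids: list[int] = []
    genes: set[str] = set()
    for rec in records:
        for r, m, s in rec.regulators:
            if r == regulator and s == want_sign:
                module_ids.append(m)
                genes |= rec.model.module_members(m)
    if not module_ids:
        logger.warning("regulator %s has no %s modules in the archive",
                       regulator, direction)
        return TargetPrediction(regulator=regulator, direction=direction,
                                module_ids=[], targets=set(),
                                filter_cut=filter_cut,
                                context_populations=context_populations)
    ctx = collapsed.values.loc[sorted(genes), context_populations]
    if direction == "activated":
        keep = ctx.index[(ctx >= filter_cut).any(axis=1)]
    else:
        keep = ctx.index[(ctx <= -filter_cut).any(axis=1)]
    return TargetPrediction(
        regulator=regulator,
        direction=direction,
        module_ids=sorted(set(module_ids)),
        targets=set(keep),
        filter_cut=filter_cut,
        context_populations=list(context_populations),
    )


def validate_targets(
    prediction: TargetPrediction,
    mutant_vs_control: DEResult,
    universe,
    sets: GeneSetCollection | None = None,
    fdr_cut: float = 0.05,
) -> tuple[OverlapResult, pd.DataFrame | None]:
    """Overlap the predicted targets with the concordant side of a
    knockout-vs-control DE contrast (activated targets should be downregulated
    in the mutant; repressed targets upregulated), plus optional functional
    overrepresentation of the predicted set against a GMT collection.

    ``mutant_vs_control`` must be oriented mutant minus control, so loss of an
    activator shows its targets with negative fold change.
    """
    universe = set(universe)
    if not prediction.targets <= universe:
        raise ValueError("prediction targets must be contained in the universe")
    de_direction = "down" if prediction.direction == "activated" else "up"
    reference = mutant_vs_control.passing(de_direction) & universe
    overlap = overlap_fisher(prediction.targets, reference, universe)
    table = None
    if sets is not None:
        table = overrepresentation(prediction.targets, sets, universe,
                                   fdr_cut=fdr_cut)
    return overlap, table
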