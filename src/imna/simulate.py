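"""Synthetic expression-atlas generator with planted regulatory structure.

Emulates a sorted-cell microarray atlas: ~12 cell populations profiled in
replicate, log-normal raw intensities with a sub-threshold probe fraction,
co-expression modules driven by a small set of planted regulator profiles
through signed weighted programs, a designated "known regulator" subset
(emulating a curated training list), and a regulator-knockout condition with
known activated/repressed targets.  Everything downstream is validated against
the ground truth recorded here.

Module means are linear in their regulators' population profiles:
``mean(module, pop) = sum_j sign_j * w_j * profile(reg_j, pop)``.  Linear
programs are recoverable by depth-1 regression-tree splits, which keeps sign
conventions unambiguous in recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .expression import (
    ArrayInfo,
    DEFAULT_EXPRESSION_THRESHOLD,
    ExpressionMatrix,
    RAW_INTENSITY,
)

#: Fixed order of per-component RNG streams spawned from the master seed.
#: One stream per logical component so that e.g. changing n_replicates does
#: not perturb the regulator profiles.
_STREAMS = (
    "profiles",
    "programs",
    "assignment",
    "offsets",
    "baselines",
    "noise",
    "low",
    "decoys",
    "mutant",
)


@dataclass(frozen=True)
class AtlasConfig:
    """Study design of the synthetic atlas.

    Defaults mirror the profiled-atlas design the pipeline targets: 12 cell
    populations in triplicate, ~1,200 probes of which a known fraction never
    rises above the expression threshold, 20 planted modules driven by 15 of
    60 candidate regulators, 12 of which are on the "known" training list.
    """

    n_populations: int = 12
    n_replicates: int = 3
    n_genes: int = 1200
    n_modules: int = 20
    n_regulators: int = 60
    n_planted_regulators: int = 15
    n_known_listed: int = 12
    n_low_probes: int = 100
    noise_sd: float = 0.3
    gene_offset_sd: float = 0.2
    weight_range: tuple[float, float] = (0.5, 1.5)
    baseline_log2_range: tuple[float, float] = (6.0, 10.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_planted_regulators > self.n_regulators:
            raise ValueError("n_planted_regulators must be <= n_regulators")
        if self.n_known_listed > self.n_planted_regulators:
            raise ValueError("n_known_listed must be <= n_planted_regulators")
        if self.n_modules > self.n_genes / 10:
            raise ValueError("n_modules must be <= n_genes / 10")
        if self.n_planted_regulators > 2 * self.n_modules:
            raise ValueError("cannot cover >2 planted regulators per module")
        if self.n_module_genes < self.n_modules:
            raise ValueError("fewer module genes than modules")
        for name in ("n_populations", "n_replicates", "n_genes", "n_modules",
                     "n_regulators", "n_planted_regulators"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_module_genes(self) -> int:
        return self.n_genes - self.n_regulators - self.n_low_probes

    @property
    def populations(self) -> list[str]:
        return [f"P{i + 1:02d}" for i in range(self.n_populations)]

    def streams(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


@dataclass
class SyntheticTruth:
    """Planted ground truth of one atlas draw."""

    module_of: dict[str, int]
    program_of: dict[int, list[tuple[str, int, float]]]
    regulator_profiles: pd.DataFrame
    planted_regulators: set[str]
    known_list: set[str]
    low_probes: set[str]
    gene_offsets: dict[str, float] = field(default_factory=dict, repr=False)
    baselines: dict[str, float] = field(default_factory=dict, repr=False)

    def module_members(self, module: int) -> set[str]:
        return {g for g, m in self.module_of.items() if m == module}

    def module_means(self) -> pd.DataFrame:
        """Noiseless module mean per population (modules x populations)."""
        rows = {}
        for module, program in self.program_of.items():
            mean = np.zeros(self.regulator_profiles.shape[1])
            for reg, sign, w in program:
                mean = mean + sign * w * self.regulator_profiles.loc[reg].to_numpy()
            rows[module] = mean
        return pd.DataFrame(rows, index=self.regulator_profiles.columns).T.sort_index()

    def expected_centered_log2(self) -> pd.DataFrame:
        """Expected row-centered log2 value per (module gene or regulator) x population."""
        means = self.module_means()
        rows, index = [], []
        for g, m in self.module_of.items():
            rows.append(means.loc[m].to_numpy())
            index.append(g)
        for r in self.regulator_profiles.index:
            rows.append(self.regulator_profiles.loc[r].to_numpy())
            index.append(r)
        arr = np.asarray(rows)
        arr = arr - arr.mean(axis=1, keepdims=True)
        return pd.DataFrame(arr, index=index, columns=self.regulator_profiles.columns)

    def modules_of_regulator(self, regulator: str, sign: int) -> list[int]:
        return sorted(
            m for m, prog in self.program_of.items()
            if any(r == regulator and s == sign for r, s, _ in prog)
        )

    def to_json(self, path) -> None:
        payload = {
            "module_of": self.module_of,
            "program_of": {str(m): [[r, s, w] for r, s, w in prog]
                           for m, prog in self.program_of.items()},
            "regulator_profiles": {
                r: list(map(float, self.regulator_profiles.loc[r]))
                for r in self.regulator_profiles.index
            },
            "populations": list(self.regulator_profiles.columns),
            "planted_regulators": sorted(self.planted_regulators),
            "known_list": sorted(self.known_list),
            "low_probes": sorted(self.low_probes),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class MutantTruth:
    """Ground truth of a simulated regulator knockout."""

    master_regulator: str
    population: str
    true_activated_targets: set[str]
    true_repressed_targets: set[str]
    expected_log2_change: dict[str, float]

    def __post_init__(self) -> None:
        if self.true_activated_targets & self.true_repressed_targets:
            raise ValueError("activated and repressed target sets must be disjoint")


def _gene_ids(config: AtlasConfig) -> tuple[list[str], list[str], list[str]]:
    genes = [f"G{i + 1:04d}" for i in range(config.n_module_genes)]
    regs = [f"R{i + 1:02d}" for i in range(config.n_regulators)]
    lows = [f"LOW{i + 1:02d}" for i in range(config.n_low_probes)]
    return genes, regs, lows


def _plant_programs(
    config: AtlasConfig, planted: list[str], rng: np.random.Generator
) -> dict[int, list[tuple[str, int, float]]]:
    """Assign 1-2 planted regulators (signed, weighted) to each module.

    Every planted regulator is guaranteed to lead at least one program, so the
    planted set is fully discoverable in principle.
    """
    lo, hi = config.weight_range
    programs: dict[int, list[tuple[str, int, float]]] = {}
    order = list(rng.permutation(config.n_modules))
    for slot, m in enumerate(order):
        primary = planted[slot % len(planted)] if slot < len(planted) else \
            planted[int(rng.integers(len(planted)))]
        prog = [(primary, int(rng.choice([1, -1])), float(rng.uniform(lo, hi)))]
        if rng.random() < 0.5 and len(planted) > 1:
            second = primary
            while second == primary:
                second = planted[int(rng.integers(len(planted)))]
            prog.append((second, int(rng.choice([1, -1])), float(rng.uniform(lo, hi))))
        programs[int(m)] = prog
    return programs


def generate_atlas(config: AtlasConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw one raw-intensity atlas and its ground truth. Deterministic in seed."""
    config.validate()
    rngs = config.streams()
    pops = config.populations
    genes, regs, lows = _gene_ids(config)

    profiles = pd.DataFrame(
        rngs["profiles"].standard_normal((config.n_regulators, config.n_populations)),
        index=regs, columns=pops,
    )
    planted = list(rngs["programs"].choice(regs, size=config.n_planted_regulators,
                                           replace=False))
    known = set(rngs["programs"].choice(planted, size=config.n_known_listed,
                                        replace=False))
    programs = _plant_programs(config, planted, rngs["programs"])

    perm = rngs["assignment"].permutation(config.n_module_genes)
    module_of = {genes[int(g)]: int(i % config.n_modules) for i, g in enumerate(perm)}

    truth = SyntheticTruth(
        module_of=module_of,
        program_of=programs,
        regulator_profiles=profiles,
        planted_regulators=set(planted),
        known_list=known,
        low_probes=set(lows),
    )

    module_means = truth.module_means()
    n_arr = config.n_populations * config.n_replicates
    array_infos = [
        ArrayInfo(f"{p}__rep{r + 1}", p, r + 1)
        for p in pops for r in range(config.n_replicates)
    ]
    pop_index = np.repeat(np.arange(config.n_populations), config.n_replicates)

    probe_ids = genes + regs + lows
    offsets = rngs["offsets"].normal(0.0, config.gene_offset_sd, size=len(genes))
    base_lo, base_hi = config.baseline_log2_range
    baselines = rngs["baselines"].uniform(base_lo, base_hi, size=len(genes) + len(regs))
    truth.gene_offsets = dict(zip(genes, map(float, offsets)))
    truth.baselines = dict(zip(genes + regs, map(float, baselines)))

    signal = np.empty((len(genes) + len(regs), n_arr))
    for i, g in enumerate(genes):
        signal[i] = module_means.loc[module_of[g]].to_numpy()[pop_index] + offsets[i]
    for j, r in enumerate(regs):
        signal[len(genes) + j] = profiles.loc[r].to_numpy()[pop_index]
    noise = rngs["noise"].normal(0.0, config.noise_sd, size=signal.shape) \
        if config.noise_sd > 0 else 0.0
    log2_raw = baselines[:, None] + signal + noise
    # expressed probes are expressed by design: lift any gene whose realized
    # maximum would fall below the expression threshold (the sub-threshold
    # fraction is exactly the designated low probes); the per-gene constant
    # shift cancels in row-centering
    floor = np.log2(1.2 * DEFAULT_EXPRESSION_THRESHOLD)
    deficit = floor - log2_raw.max(axis=1)
    log2_raw += np.maximum(deficit, 0.0)[:, None]
    raw_expressed = 2.0 ** log2_raw
    raw_low = rngs["low"].uniform(10.0, 90.0, size=(len(lows), n_arr))

    values = pd.DataFrame(
        np.vstack([raw_expressed, raw_low]),
        index=probe_ids,
        columns=[a.array_id for a in array_infos],
    )
    matrix = ExpressionMatrix(
        values=values,
        gene_symbols=pd.Series(probe_ids, index=probe_ids, name="gene_symbol"),
        arrays=array_infos,
        scale=RAW_INTENSITY,
    )
    return matrix, truth


def default_master(truth: SyntheticTruth) -> str:
    """Planted regulator driving the most positively-signed modules.

    Emulates picking a master regulator with a broad activated-target program
    as the knockout subject; ties broken lexicographically.
    """
    counts = {r: len(truth.modules_of_regulator(r, +1))
              for r in truth.planted_regulators}
    return min(counts, key=lambda r: (-counts[r], r))


def generate_mutant_pair(
    truth: SyntheticTruth,
    config: AtlasConfig,
    master: str,
    population: str | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix, MutantTruth]:
    """Simulate a knockout of ``master`` in one population, paired with control.

    The control is a fresh draw of the atlas restricted to the population where
    the master's profile is maximal (configurable).  The mutant shares the
    control's gene offsets and baselines but has the master's profile forced to
    its across-population minimum before propagation through the programs, so
    activated targets drop and repressed targets rise by ``w * delta``.
    """
    config.validate()
    if master not in truth.planted_regulators:
        raise ValueError(f"{master!r} is not a planted regulator")
    profiles = truth.regulator_profiles
    if population is None:
        population = str(profiles.loc[master].idxmax())
    delta = float(profiles.loc[master, population] - profiles.loc[master].min())

    rng = config.streams()["mutant"]
    genes = sorted(truth.module_of)
    regs = list(profiles.index)
    module_means = truth.module_means()

    activated: set[str] = set()
    repressed: set[str] = set()
    change: dict[str, float] = {}
    module_change: dict[int, float] = {}
    for m, prog in truth.program_of.items():
        shift = 0.0
        for reg, sign, w in prog:
            if reg == master:
                shift += -sign * w * delta  # knockout lowers master to its minimum
        module_change[m] = shift
        if shift != 0.0:
            members = truth.module_members(m)
            for r, s, _ in prog:
                if r == master:
                    (activated if s > 0 else repressed).update(members)
    activated -= repressed  # a gene in both an activated and repressed module is ambiguous
    for g in genes:
        change[g] = module_change[truth.module_of[g]]

    offsets = rng.normal(0.0, config.gene_offset_sd, size=len(genes))
    lo, hi = config.baseline_log2_range
    baselines = rng.uniform(lo, hi, size=len(genes) + len(regs))
    R = config.n_replicates

    def build(condition: str, master_value: float) -> ExpressionMatrix:
        rows = np.empty((len(genes) + len(regs), R))
        reg_vals = profiles[population].copy()
        reg_vals.loc[master] = master_value
        mod_mean = {}
        for m, prog in truth.program_of.items():
            mod_mean[m] = sum(s * w * reg_vals.loc[r] for r, s, w in prog)
        for i, g in enumerate(genes):
            rows[i] = mod_mean[truth.module_of[g]] + offsets[i]
        for j, r in enumerate(regs):
            rows[len(genes) + j] = reg_vals.loc[r]
        noise = rng.normal(0.0, config.noise_sd, size=rows.shape) \
            if config.noise_sd > 0 else 0.0
        raw = 2.0 ** (baselines[:, None] + rows + noise)
        ids = genes + regs
        arrays = [ArrayInfo(f"{condition}__rep{k + 1}", condition, k + 1)
                  for k in range(R)]
        return ExpressionMatrix(
            values=pd.DataFrame(raw, index=ids, columns=[a.array_id for a in arrays]),
            gene_symbols=pd.Series(ids, index=ids, name="gene_symbol"),
            arrays=arrays,
            scale=RAW_INTENSITY,
        )

    control = build("control", float(profiles.loc[master, population]))
    mutant = build("mutant", float(profiles.loc[master].min()))
    mtruth = MutantTruth(
        master_regulator=master,
        population=population,
        true_activated_targets=activated,
        true_repressed_targets=repressed,
        expected_log2_change=change,
    )
    return control, mutant, mtruth


def make_decoy_sets(
    truth: SyntheticTruth, config: AtlasConfig
) -> dict[int, set[str]]:
    """Shuffled decoy gene sets, size-matched to the planted modules."""
    rng = config.streams()["decoys"]
    genes = sorted(truth.module_of)
    return {
        m: set(rng.choice(genes, size=len(truth.module_members(m)), replace=False))
        for m in sorted(truth.program_of)
    }


def write_atlas_bundle(outdir, config: AtlasConfig, with_mutant: bool = True) -> dict:
    """Emit the full simulation bundle: expression TSV, truth JSON, regulator
    lists, a GMT of planted modules plus decoys, and (optionally) the mutant
    pair.  Returns the paths written."""
    from pathlib import Path
    from .genesets import GeneSetCollection, write_gmt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, truth = generate_atlas(config)
    paths = {}

    paths["expression"] = outdir / "atlas_raw.tsv"
    matrix.to_tsv(paths["expression"])
    paths["truth"] = outdir / "truth.json"
    truth.to_json(paths["truth"])
    paths["regulators"] = outdir / "regulators.txt"
    paths["regulators"].write_text(
        "".join(f"{r}\n" for r in truth.regulator_profiles.index))
    paths["known"] = outdir / "known_regulators.txt"
    paths["known"].write_text("".join(f"{r}\n" for r in sorted(truth.known_list)))

    sets = {f"MODULE{m:02d}": ("planted module", truth.module_members(m))
            for m in sorted(truth.program_of)}
    for m, members in make_decoy_sets(truth, config).items():
        sets[f"DECOY{m:02d}"] = ("shuffled decoy", members)
    paths["gmt"] = outdir / "modules.gmt"
    write_gmt(GeneSetCollection(sets), paths["gmt"])

    if with_mutant:
        master = default_master(truth)
        control, mutant, mtruth = generate_mutant_pair(truth, config, master)
        paths["control"] = outdir / "mutant_control.tsv"
        control.to_tsv(paths["control"])
        paths["mutant"] = outdir / "mutant_knockout.tsv"
        mutant.to_tsv(paths["mutant"])
        paths["mutant_truth"] = outdir / "mutant_truth.json"
        with open(paths["mutant_truth"], "w") as fh:
            json.dump({
                "master_regulator": mtruth.master_regulator,
                "population": mtruth.population,
                "true_activated_targets": sorted(mtruth.true_activated_targets),
                "true_repressed_targets": sorted(mtruth.true_repressed_targets),
            }, fh, indent=1)
    return paths
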