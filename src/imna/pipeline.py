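"""Configuration and end-to-end orchestration of the analysis pipeline.

Chains simulate -> filter -> normalize -> cluster -> signatures -> module map
-> iterative network analysis -> target extraction -> knockout validation,
writing every stage artifact plus a JSON report of summary metrics and a
manifest of sha256 checksums.  A single master seed fans out deterministically
to per-stage seeds (fixed documented offsets), so the whole run — and any
stage rerun in isolation — is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import diffexp, expression, genesets, iterative, modnet
from . import simulate as sim

logger = logging.getLogger(__name__)

#: Per-stage seed offsets added to the master seed.
STAGE_SEED_OFFSETS = {"atlas": 0, "imna": 1000, "gsea": 2000}


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with the defaults used throughout.

    Thresholds: expression filter 100 (raw intensity), signature quadruple
    p<=0.001 / FDR<=0.05 / |log2FC|>=1 / SD<=0.5, DE q<0.05 at |log2FC|>=1,
    module map p<0.05 / FDR<0.05 at log2 cutoffs +/-1, tree depth 5.
    """

    simulate: bool = True
    output_dir: str = "pipeline_out"
    seed: int = 0

    # input paths (used when simulate is false; the mutant pair is optional)
    expression_path: str | None = None
    regulators_path: str | None = None
    known_path: str | None = None
    gmt_path: str | None = None
    mutant_control_path: str | None = None
    mutant_knockout_path: str | None = None

    atlas: sim.AtlasConfig = field(default_factory=sim.AtlasConfig)
    score: modnet.ScoreHyperparameters = field(
        default_factory=modnet.ScoreHyperparameters)

    filter_threshold: float = 100.0
    signature: diffexp.SignatureParams = field(
        default_factory=diffexp.SignatureParams)
    de_alpha: float = 0.05
    de_fc_cut: float = 1.0
    map_alpha: float = 0.05
    map_fdr: float = 0.05
    map_up_cut: float = 1.0
    map_down_cut: float = -1.0
    modules: int = 20
    n_runs: int = 25
    max_depth: int = 5
    max_sweeps: int = 20
    target_filter_cut: float = 1.0
    gsea_n_perm: int = 200
    linkage: str = "average"

    def validate(self) -> None:
        if self.modules < 2:
            raise ValueError("modules must be >= 2")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.max_depth < 0:
            raise ValueError("max_depth must be >= 0")
        if self.filter_threshold <= 0:
            raise ValueError("filter_threshold must be positive")
        for name in ("de_alpha", "map_alpha", "map_fdr"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        self.atlas.validate()
        if not self.simulate:
            for name in ("expression_path", "regulators_path", "known_path"):
                if getattr(self, name) is None:
                    raise ValueError(f"{name} is required when simulate is false")

    def stage_seed(self, stage: str) -> int:
        return (self.seed + STAGE_SEED_OFFSETS[stage]) % (2**31)


_NESTED = {"atlas": sim.AtlasConfig, "score": modnet.ScoreHyperparameters,
           "signature": diffexp.SignatureParams}


def _build_config(data: dict) -> PipelineConfig:
    known_fields = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known_fields
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key in _NESTED:
            cls = _NESTED[key]
            sub_fields = {f.name for f in dataclasses.fields(cls)}
            bad = set(value) - sub_fields
            if bad:
                raise ValueError(f"unknown key(s) under {key!r}: {sorted(bad)}")
            if key == "atlas" and "weight_range" in value:
                value["weight_range"] = tuple(value["weight_range"])
            if key == "atlas" and "baseline_log2_range" in value:
                value["baseline_log2_range"] = tuple(value["baseline_log2_range"])
            kwargs[key] = cls(**value)
        else:
            kwargs[key] = value
    config = PipelineConfig(**kwargs)
    config.validate()
    return config


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML/JSON pipeline config; defaults fill gaps."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    config = _build_config(data)
    logger.info("resolved config: %s", asdict(config))
    return config


def write_config(config: PipelineConfig, path) -> None:
    d = asdict(config)
    d["atlas"]["weight_range"] = list(d["atlas"]["weight_range"])
    d["atlas"]["baseline_log2_range"] = list(d["atlas"]["baseline_log2_range"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage, returning the summary report (also written as JSON
    together with a checksum manifest of all artifacts)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    # the echoed config is rooted at its own directory so that identical
    # analyses in different locations produce identical manifests
    write_config(dataclasses.replace(config, output_dir="."),
                 out / "config_resolved.yaml")
    report: dict = {"stages": []}
    artifacts: list[Path] = [out / "config_resolved.yaml"]

    def stage(name: str):
        report["stages"].append(name)
        logger.info("stage: %s", name)

    try:
        # ------------------------------------------------------------------
        stage("inputs")
        mutant_pair = None
        truth = None
        if config.simulate:
            atlas_cfg = dataclasses.replace(config.atlas,
                                            seed=config.stage_seed("atlas"))
            raw, truth = sim.generate_atlas(atlas_cfg)
            regulator_ids = list(truth.regulator_profiles.index)
            known = sorted(truth.known_list)
            sets = genesets.GeneSetCollection({
                **{f"MODULE{m:02d}": ("planted module", truth.module_members(m))
                   for m in sorted(truth.program_of)},
                **{f"DECOY{m:02d}": ("shuffled decoy", members)
                   for m, members in sim.make_decoy_sets(truth, atlas_cfg).items()},
            })
            master = sim.default_master(truth)
            mutant_pair = sim.generate_mutant_pair(truth, atlas_cfg, master)
            raw.to_tsv(out / "atlas_raw.tsv")
            truth.to_json(out / "truth.json")
            artifacts += [out / "atlas_raw.tsv", out / "truth.json"]
        else:
            raw = expression.ExpressionMatrix.from_tsv(config.expression_path)
            regulator_ids = [l.strip() for l in
                             open(config.regulators_path) if l.strip()]
            known = [l.strip() for l in open(config.known_path) if l.strip()]
            sets = genesets.read_gmt(config.gmt_path) if config.gmt_path else None
            master = None
            if config.mutant_control_path and config.mutant_knockout_path:
                mutant_pair = (
                    expression.ExpressionMatrix.from_tsv(config.mutant_control_path),
                    expression.ExpressionMatrix.from_tsv(config.mutant_knockout_path),
                    None,
                )

        # ------------------------------------------------------------------
        stage("preprocess")
        filtered = expression.filter_expressed_probes(raw, config.filter_threshold)
        normalized = expression.normalize_log2_center(filtered)
        report["n_probes_raw"] = len(raw.probe_ids)
        report["n_probes_after_filter"] = len(filtered.probe_ids)

        stage("cluster")
        corr, dend = expression.correlate_and_cluster(normalized,
                                                      linkage=config.linkage)
        corr.to_tsv(out / "array_correlation.tsv")
        (out / "array_dendrogram.newick").write_text(dend.to_newick() + "\n")
        collapsed = expression.collapse_replicates(normalized)
        collapsed.to_tsv(out / "atlas_collapsed.tsv")
        artifacts += [out / "array_correlation.tsv",
                      out / "array_dendrogram.newick", out / "atlas_collapsed.tsv"]

        stage("signatures")
        sig_sizes = {}
        for pop in normalized.populations:
            sig = diffexp.cell_signature(normalized, pop, config.signature)
            sig.table.rename_axis("probe_id").to_csv(
                out / f"signature_{pop}.tsv", sep="\t")
            artifacts.append(out / f"signature_{pop}.tsv")
            sig_sizes[pop] = {"positive": len(sig.positive),
                              "negative": len(sig.negative)}
        report["signature_sizes"] = sig_sizes

        if sets is not None:
            stage("module_map")
            mm = genesets.module_map(collapsed, sets, up_cut=config.map_up_cut,
                                     down_cut=config.map_down_cut,
                                     alpha=config.map_alpha, fdr=config.map_fdr)
            mm.to_tsv(out / "module_map.tsv")
            mm.display_matrix("up").to_csv(out / "module_map_display_up.tsv",
                                           sep="\t")
            artifacts += [out / "module_map.tsv",
                          out / "module_map_display_up.tsv"]
            report["module_map_significant"] = int(len(mm.significant()))

        # ------------------------------------------------------------------
        stage("imna")
        freq, archive = iterative.run_imna(
            normalized, regulator_ids, M=config.modules, n_runs=config.n_runs,
            base_seed=config.stage_seed("imna"), max_depth=config.max_depth,
            max_sweeps=config.max_sweeps, h=config.score)
        freq.to_tsv(out / "regulator_frequency.tsv")
        archive.to_dir(out / "models")
        artifacts.append(out / "regulator_frequency.tsv")
        artifacts += sorted((out / "models").glob("*.json"))
        report["recovery_percent_known"] = iterative.recovery_percent(archive, known)

        stage("gsea")
        gsea = iterative.gsea_es(freq, set(known), p_w=1,
                                 n_perm=config.gsea_n_perm,
                                 seed=config.stage_seed("gsea"))
        with open(out / "gsea_known.json", "w") as fh:
            json.dump({"es": gsea.es, "p_value": gsea.p_value,
                       "p_w": gsea.p_w, "n_perm": gsea.n_perm}, fh)
        artifacts.append(out / "gsea_known.json")
        report["gsea_es_known"] = gsea.es
        report["gsea_p_known"] = gsea.p_value

        # ------------------------------------------------------------------
        if mutant_pair is not None:
            stage("knockout_validation")
            control, mutant, mtruth = mutant_pair
            if master is None and truth is None:
                master = regulator_ids[0]
            combined_vals = control.values.join(mutant.values)
            combined = expression.ExpressionMatrix(
                values=combined_vals,
                gene_symbols=control.gene_symbols,
                arrays=list(control.arrays) + list(mutant.arrays),
                scale=expression.RAW_INTENSITY,
            )
            de_input = expression.normalize_log2_center(
                expression.filter_expressed_probes(combined,
                                                   config.filter_threshold))
            de = diffexp.pairwise_de(
                de_input,
                group_a=[a.array_id for a in mutant.arrays],
                group_b=[a.array_id for a in control.arrays],
                fc_cut=config.de_fc_cut, alpha=config.de_alpha)
            de.to_tsv(out / "mutant_de.tsv")
            artifacts.append(out / "mutant_de.tsv")

            universe = set(normalized.values.index) & set(de.table.index)
            validation = {}
            for direction in ("activated", "repressed"):
                pred = iterative.extract_targets(
                    archive, normalized, master, direction=direction,
                    filter_cut=config.target_filter_cut)
                pred = dataclasses.replace(pred, targets=pred.targets & universe)
                overlap, table = iterative.validate_targets(
                    pred, de, universe,
                    sets=sets, fdr_cut=0.05) if pred.targets else (None, None)
                entry = {"prediction": pred.to_dict()}
                if overlap is not None:
                    entry["overlap"] = overlap.to_dict()
                    if table is not None:
                        table.to_csv(out / f"targets_{direction}_functions.tsv",
                                     sep="\t", index=False)
                        artifacts.append(out / f"targets_{direction}_functions.tsv")
                validation[direction] = entry
            with open(out / "target_validation.json", "w") as fh:
                json.dump(validation, fh, indent=1)
            artifacts.append(out / "target_validation.json")
            report["master_regulator"] = master
            for direction in ("activated", "repressed"):
                ov = validation[direction].get("overlap")
                if ov:
                    report[f"{direction}_overlap_fraction"] = ov["overlap_fraction"]
                    report[f"{direction}_log10_p"] = ov["log10_p"]
        else:
            logger.info("no mutant pair configured; skipping knockout validation")

        # ------------------------------------------------------------------
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        artifacts.append(out / "report.json")
        manifest = {str(p.relative_to(out)): _sha256(p) for p in sorted(artifacts)}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    except Exception:
        # partial outputs are left in place, but the manifest is removed so a
        # half-finished run can never masquerade as a complete one
        (out / "manifest.json").unlink(missing_ok=True)
        raise
    return report
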