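# imna — iterative module network analysis

Tools for inferring transcriptional regulators and their target genes from a
cell-type expression atlas (e.g. microarrays of FACS-purified cell
populations profiled in replicate), aimed at systems biologists studying
lineage specification and anyone who needs a tested, reproducible module
network stack with planted-truth benchmarks.

## The method

A **module network** couples a partition of genes into co-expression modules
with one **regulation program** per module: a small regression tree over
candidate regulators' expression values whose leaves model the pooled
expression of the module's genes in the arrays routed to them, routed left
when the regulator's value exceeds the split.  The objective is the Bayesian
score — the log marginal likelihood of the leaf data under a conjugate
Normal-Gamma model:

    log m(y) = lnΓ(αₙ) − lnΓ(α₀) + α₀ ln β₀ − αₙ ln βₙ + ½(ln λ₀ − ln λₙ) − (n/2) ln 2π

with λₙ = λ₀ + n, αₙ = α₀ + n/2, βₙ = β₀ + ½ss + λ₀n(ȳ − μ₀)²/(2λₙ).
Learning alternates greedy tree fitting (depth ≤ 5) with seeded-order gene
reassignment, monotonically increasing the total score.

Because a single run is initialization-dependent, the **iterative** procedure
runs the learner many times with different seeds and ranks each candidate
regulator by the fraction of runs in which it appears in at least one
program (frequency 1.0 = appeared in every run).  Module and run counts are
chosen by a grid sweep scored against a known-regulator training list, the
ranking is validated by a GSEA enrichment score of that list, and each
regulator's predicted activated/repressed targets are checked against an
independent knockout-vs-control differential-expression contrast with a
one-sided Fisher/hypergeometric overlap test.

The package also provides the surrounding expression analytics — expression
filtering (raw ≥ 100 in ≥ 1 array), log2 mean-centering, array correlation
with average-linkage clustering, four-parameter cell-type signatures
(p ≤ 0.001, FDR ≤ 0.05, |log2FC| ≥ 1, within-type SD ≤ 0.5),
Benjamini-Hochberg FDR, per-population gene-set module maps, and a GMT-based
overrepresentation test — plus a synthetic atlas generator that plants
modules, regulator programs, a known-regulator subset and a simulated
knockout, providing exact ground truth for every stage.  See
`docs/methods.md` for the full model description and design rationale.

## Worked example

```python
import imna

# a synthetic atlas: 12 populations x 3 replicates, 1,200 probes,
# 20 planted modules driven by 15 of 60 candidate regulators
cfg = imna.AtlasConfig(seed=1)
matrix, truth = imna.generate_atlas(cfg)

filtered = imna.filter_expressed_probes(matrix)      # drops the 100 low probes
normalized = imna.normalize_log2_center(filtered)
print("expressed probes:", len(filtered.probe_ids))

freq, archive = imna.run_imna(
    normalized, list(truth.regulator_profiles.index),
    M=20, n_runs=25, base_seed=0)
print("known-regulator recovery: %.1f%%"
      % imna.recovery_percent(archive, truth.known_list))

es = imna.gsea_es(freq, truth.known_list, p_w=1, n_perm=200, seed=0)
print("GSEA ES of the known list: %.3f (p = %.4f)" % (es.es, es.p_value))
```

prints

```
expressed probes: 1100
known-regulator recovery: 100.0%
GSEA ES of the known list: 0.591 (p = 0.0547)
```

1,100 of 1,200 probes clear the expression filter (the 100 planted
sub-threshold probes are removed); the union of regulators over 25 runs
recovers the full known-regulator training list; and the known regulators
concentrate near the top of the frequency ranking (enrichment score 0.59
against the 200-permutation null).

The same workflow is available from the shell: `imna simulate`, `imna run`,
`imna sweep`, `imna targets`, `imna demo` and `imna run-all --config
cfg.yaml` (the full pipeline: simulate → preprocess → cluster → signatures →
module map → iterative ranking → GSEA → knockout validation, with a checksum
manifest for byte-reproducibility).

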