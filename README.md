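# rebel

**Regulatory Element Behavior Extraction Learning** — a pipeline for asking
whether the transcription-factor binding-site (TFBS) composition of a
regulatory element predicts its regulatory fate, and which motifs carry the
prediction.

The setting is acute promyelocytic leukemia, where the PML::RARA fusion
transcription factor rewires promoter–enhancer contacts: upon fusion-protein
induction, some long-range interactions are gained and some lost, while the
associated genes go up, down, or stay flat. Crossing the two axes yields six
element categories. `rebel` takes open-chromatin peaks, fusion-protein
binding peaks, a differential-expression table, per-replicate
promoter-capture interaction counts and a PWM library, and:

1. calls **consensus differential interactions** with an exact binomial test
   per replicate pair (expected proportion from the control condition, +0.5
   pseudo-count), distance-stratified Benjamini–Hochberg FDR control, and a
   ≥ 2-same-direction-replicates consensus rule at FDR ≤ 0.01;
2. **categorizes** ATAC peaks on fusion-associated differential fragments
   into the six interaction × expression categories, with a 400-bp window
   centered on each peak summit;
3. scans every window with every PWM (log-odds, both strands, per-motif
   thresholds) into a motifs × elements **count matrix**, viewed through
   `log10(x + 1)`;
4. trains **gradient-boosted tree classifiers** one category against a
   balanced mixture of the rest (fixed subsample 0.8, colsample 0.8,
   eta 0.1, gamma 1; 400-point grid over min_child_weight × max_depth with
   five-fold CV on an 80 % split; then five disjoint held-out subsets
   covering 100 % of each category);
5. computes exact tree-path **Shapley attributions** for correctly predicted
   elements from their held-out model, embeds them with t-SNE, clusters with
   DBSCAN, and ranks each cluster's **driver motifs** with a
   present-predictive / absent-predictive call and a contribution fraction.

A planted-signature synthetic generator emulates every input with known
ground truth, so the whole pipeline is testable offline. It also supports
the supporting statistics: a 4-kb interaction matcher, a Monte-Carlo overlap
test against resampled interaction universes, and a Fisher-exact motif
presence enrichment utility.

## Worked example

Simulate a small bundle with planted signatures and run every stage:

```bash
rebel simulate --seed 5 --out demo --elements-per-category 40 --n-motifs 40
rebel run-all --genome demo/genome.fa --peaks demo/atac_peaks.narrowPeak \
    --fusion-peaks demo/fusion_peaks.narrowPeak --motifs demo/motifs.homer \
    --de demo/expression.tsv --interactions demo/interactions.tsv \
    --seed 5 --grid-size 4 --out demo_run
```

or equivalently from Python:

```python
from rebel import pipeline
from rebel.model import ModelConfig

result = pipeline.recovery_benchmark(
    seed=1,
    model_config=ModelConfig(seed=1, grid=pipeline.BENCHMARK_GRID),
    elements_per_category=60, n_motifs=40,
    perplexity=10, combined_perplexity=30, min_pts=5,
)
print({k: round(v, 3) for k, v in result["auc_per_category"].items()})
print(result["top_driver_union"]["gained_up"])
```

which prints

```
{'gained_down': 0.956, 'gained_no_change': 0.932, 'gained_up': 0.983,
 'lost_down': 0.938, 'lost_no_change': 0.943, 'lost_up': 0.93}
['M0000', 'M0001', 'M0002', 'M0003', 'M0004']
```

— each category's one-vs-all mean held-out AUC, and the union of top-5
driver motifs over the `gained_up` clusters. The generator planted motifs
M0000–M0002 in `gained_up` elements at penetrance 0.6 over a Poisson(0.05)
background, so the drivers recover the planted signature; AUC ≈ 0.95 rather
than 1.0 because each required motif is missing from 40 % of its category's
elements.

Outputs of `run-all` land in the output directory as TSV/JSON:
`differential_interactions.tsv`, `elements.tsv`, `matrix.tsv`,
`predictions.tsv`, `embedding.tsv`, `cluster_drivers.tsv`, and a
`run_manifest.json` recording seeds and per-stage record counts.

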