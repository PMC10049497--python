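# mecp2core

Cross-study consensus differential-expression meta-analysis, modelled on
the MeCP2 (Rett syndrome / MECP2 duplication syndrome) transcriptome
literature: dozens of RNA-seq contrasts that individually disagree, yet
share a reproducible "common core" of dysregulated genes once they are
aggregated with direction harmonization.

The package implements the full statistical pipeline on synthetic data
with known ground truth:

- **Consensus core identification.** Per-contrast log2 fold changes are
  masked at FDR ≤ α (default 0.01), gain-of-function (overexpression)
  contrasts are sign-inverted so directions are comparable to
  loss-of-function models, and genes significant in ≥ k contrasts
  (default k = 4, ~10%) form the core, split into core-up / core-down by
  the mean of their significant fold changes.
- **Biotype and positional characterization.** Eight-category
  composition of gene sets, and a TSS-ordered 6/3/0 encoding
  (core-up / background / core-down) per chromosome segmented by a
  simplified circular binary segmentation (max-t arc search with a
  within-interval permutation p-value).
- **Pre-ranked enrichment.** Genes ranked by −log10(FDR) × log2FC; the
  weighted Kolmogorov–Smirnov running-sum statistic
  (hits add |s|^w / Σ|s|^w, misses subtract 1/(N − n_hits)) with a
  gene-permutation null, sign-stratified NES and GSEA-style FDR; plus
  direction-stratified Fisher / hypergeometric overlap tests.
- **Down-sampling power analysis.** A desk-scale negative binomial Wald
  test (median-of-ratios size factors, moment dispersions shrunk to a
  trend, BH adjustment) applied to repeated balanced subsamples of a
  deep two-group count matrix, recording DEG counts under fold-change
  cutoffs and the Rand index against the full-data calls.
- **Synthetic data generators** for every input, with planted truth:
  multi-contrast tables with a concordant core and inverted contrasts,
  annotations with positional clusters, and NB count matrices in the
  low signal-to-noise regime (most effects below two-fold).

## Worked example

```python
from mecp2core import core, simulate

tables, meta, truth = simulate.generate_multi_contrast(seed=20240901)
cfg = core.ConsensusConfig(alpha=0.01, min_contrasts=4,
                           invert_ids=frozenset(truth.inverted_contrasts))
matrix, result = core.run_core_pipeline(tables, cfg)
print(len(result.core_genes), len(result.core_up), len(result.core_down))
```

prints `270 150 120`: the pipeline recovers exactly the planted 150
upregulated and 120 downregulated core genes from 40 noisy contrasts in
which each core gene is significant in only ~60% of contrasts and two
contrasts have globally inverted signs.

The full analysis narrative lives in `analysis/` and writes its tables
under `results/`:

```
python analysis/01_simulate_inputs.py      # inputs + ground truth
python analysis/02_identify_core.py        # core, threshold grid, sub-cores
python analysis/03_genome_composition.py   # composition + chr8 CBS segments
python analysis/04_enrichment_overlap.py   # pre-ranked enrichment, overlap
python analysis/05_downsampling_power.py   # replicate down-sampling power
```

For example, step 03 reports the planted chr8 cluster as a single
elevated segment (`chr8:798,897-49,207,305`, mean level 5.61 on the
6/3/0 encoding), and step 05 shows mean DEG counts rising from ~82 at
n = 3 to ~132 at n = 10 per group without saturating, with the FC > 20%
cutoff flattening the curve.

A `mecp2core` command-line interface wraps the same functions
(`mecp2core simulate|core|segment|power --help`).

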