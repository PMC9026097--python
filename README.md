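# modscape

Comparative transcriptomics of fumarate compounds in astrocytes, rebuilt as a
tested, reusable Python pipeline. Dimethyl fumarate derivatives — monomethyl
fumarate (MMF), diroximel fumarate (DRF), and isosorbide di-(methyl fumarate)
(IDMF) — are candidate multiple-sclerosis therapies whose transcriptional
effects in astrocytes differ in breadth and direction. `modscape` implements
the full analysis used to contrast such compounds:

- **Differential expression** with empirical-Bayes moderated t-statistics:
  per-gene residual variances s²_g (df *d*) are shrunk toward a scaled
  inverse-χ² prior (d₀, s₀²) estimated by moment matching on log s²_g, giving
  s̃²_g = (d₀s₀² + d·s²_g)/(d₀ + d) and t = Δ/(s̃_g·√(1/n_a + 1/n_b)) with
  d + d₀ degrees of freedom; Benjamini–Hochberg FDR; DEG calling at
  p < 0.05 with FC > 1.25 or FC < 0.80 (stringent: FDR < 0.10).
- **Co-expression modules** discovered on an independent 24-sample reference
  set: average-linkage Euclidean clustering of gene-standardized profiles,
  pruned with a variable-height rule (a module is a maximal subtree whose
  merge height drops ≥ `prune_depth` below its join height), labeled
  `GENE-size`, summarized by medoids, connected where medoid Spearman
  r_s ≥ 0.80, and tested for differential module expression (DEM) by
  Wilcoxon rank-sum of member fold changes vs all other detectable genes.
- **Directional signature statistics**: Fisher's exact test on the up/down
  split of expressed signature members vs background, and a signed
  cumulative-overlap area statistic over the FC-ranked gene list (positive ⇔
  concentration among increased genes) with a rank-sum p.
- **Resampling nulls**: mean |log₂FC| of a disease gene set vs 10,000
  equal-size random draws, and mean nearest-GWAS-locus distance of top DEGs
  vs 1,000 random gene sets, both with add-one empirical p-values.
- **Promoter motif enrichment**: both-strand log-odds PWM scanning of 5 kb
  upstream sequences and a semiparametric logistic model,
  logit P(DEG) = β·motif + s(GC), with an unpenalized B-spline s(·) and a
  likelihood-ratio test for β = 0, applied per PWM with BH adjustment
  (including an IRF-family profile with positional hit histograms).
- **Small-sample validation statistics**: exact Wilcoxon rank-sum by full
  enumeration, 2^(−ΔΔCt) qPCR fold changes, and Fisher's LSD with compact
  letter display.
- **Synthetic data with planted ground truth** for every input the pipeline
  touches, so each stage is validated by parameter recovery.

## Worked example

```python
from modscape.synthio import SimParams, simulate_experiment, simulate_reference
from modscape.diffexpr import fit_moderated_t, call_degs
from modscape.comod import standardize_reference, detect_modules

params = SimParams(n_genes=5000, seed=7)          # 4 groups x 3 replicates
matrix, truth = simulate_experiment(params)        # planted signed log2 effects

de, prior = fit_moderated_t(
    matrix, matrix.samples_in_group("IDMF"), matrix.samples_in_group("CTL")
)
up, down = call_degs(de)
print(f"IDMF vs CTL: {len(up)} up, {len(down)} down "
      f"(prior df = {prior.d0:.1f}, prior variance = {prior.s0_sq:.4f})")

planted = set(truth.planted_deg_sets["IDMF"])
recall = len((set(up) | set(down)) & planted) / len(planted)
print(f"recall of {len(planted)} planted DEGs: {recall:.3f}")

ref, _ = simulate_reference(SimParams(n_genes=1200, n_modules=4,
                                      module_signal=0.6, seed=7))
z, _ = standardize_reference(ref)
modules = detect_modules(z)
print(f"modules detected: {len(modules.module_ids)}, sizes {modules.sizes()}")
```

prints

```
IDMF vs CTL: 344 up, 382 down (prior df = 1000000.0, prior variance = 0.0626)
recall of 500 planted DEGs: 0.996
modules detected: 5, sizes {1: 54, 2: 101, 3: 75, 4: 72, 5: 26}
```

The 726 called DEGs recover 99.6% of the 500 planted effects (the simulated
residual variances are homogeneous, so the prior df estimate hits its cap —
maximal shrinkage, the correct limit here). Four of the five detected modules
are the planted ones, recovered essentially exactly; the extra 26-gene
cluster is a chance aggregation of background genes, the documented
false-positive behaviour of the pruning rule on pure noise (a few percent of
genes at most).

The same analysis runs end to end from the command line:

```bash
modscape run --outdir demo_out --seed 11        # full synthetic demo
modscape diffexpr --matrix X.tsv --groups groups.tsv --contrast IDMF:CTL --out de.tsv
modscape modules detect --ref ref.tsv --min-size 25 --out modules.json
modscape smallstats wilcoxon --a a.txt --b b.txt
```

The demo writes one table per analysis stage (DE tables per contrast, module
assignments, DEM tests, signature statistics, disease-gene nulls, GWAS
proximity, motif enrichment, and a summary table) plus a JSON manifest with
per-stage seeds, timings, and output checksums; identical configs reproduce
identical checksums.

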