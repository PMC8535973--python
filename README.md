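# pyropattern

Expression-pattern discovery and PCA-based prognostic scoring for tumor
cohorts, with the synthetic ground-truth machinery needed to validate
every stage at desk scale.

The pipeline:

1. **data_io** — expression / clinical / gene-set / mutation / CNV
   ingestion, FPKM→TPM conversion, short-follow-up sample filtering,
   cohort merging on shared genes, and a deterministic location–scale
   batch adjustment on log2 expression.
2. **pattern_discovery** — subsampled consensus clustering of samples
   over a curated regulator panel (k-means or average-linkage base
   clusterer), with PAC-based selection of the number of clusters.
3. **signature_scoring** — rank-based single-sample enrichment scores
   (running-sum statistic with weight exponent `alpha`), combined
   immune/stromal scoring with a cosine purity transform, and
   hypergeometric over-representation analysis with BH correction.
4. **differential_expression** — moderated t statistics on log2
   expression (empirical-Bayes variance shrinkage fitted by
   digamma/trigamma moment matching), BH FDR, and the intersection of
   all pairwise cluster contrasts into an overlap signature-gene set.
5. **pyroptosis_score** — univariate Cox screening of the signature
   genes, a centered two-component PCA model, per-sample score
   (PC1 coordinate + PC2 coordinate), explicit protective orientation,
   and a maximally selected log-rank cutpoint with an optional
   permutation p-value.
6. **survival_stats** — Kaplan–Meier, multi-group log-rank, Cox
   proportional hazards (Newton–Raphson on the Breslow partial
   likelihood with step-halving), IPCW time-dependent ROC AUC, rank and
   location tests, and Spearman association with exact small-sample
   inference.
7. **genomic_landscape** — per-gene mutation frequency, Fisher
   co-mutation tests, CNV gain/loss summaries, and per-sample tumor
   mutation burden.
8. **synthetic_data** — a fully seeded generator planting K expression
   patterns, a sample-level latent score driving survival and mutation
   burden, multi-cohort batch effects, and the matching truth object.

## CLI

Every stage is exposed through the `pyropattern` command; prepared data
is a plain directory of TSVs.

```bash
pyropattern simulate --seed 7 --out study/           # synthetic study
pyropattern prepare  --expr e.tsv --clinical c.tsv --cohorts m.tsv --out prep/
pyropattern cluster  --prepared prep/ --panel panel.gmt --kmin 2 --kmax 6 \
                     --reps 1000 --seed 17 --out clusters.tsv
pyropattern score-sets --prepared prep/ --gmt cells.gmt --out ssgsea.tsv
pyropattern estimate --prepared prep/ --stromal s.gmt --immune i.gmt --out est.tsv
pyropattern de       --prepared prep/ --clusters clusters.tsv --fdr 0.01 --out degs.tsv
pyropattern ps       --prepared prep/ --clusters clusters.tsv --out ps.tsv
pyropattern survival --ps ps.tsv --clinical clinical.tsv --out surv.json
pyropattern landscape --maf muts.tsv --cnv cnv.tsv --panel panel.gmt --out land.json
```

`pyropattern simulate` writes a ready-to-use prepared directory plus
mutation/CNV tables, the regulator panel GMT, and the ground truth, so
the whole chain can be exercised end-to-end without external data.
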