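# gosurv

Survival prediction models whose covariates are single genes, GO gene
groups, or **preclustered** GO-group subclusters.

The pipeline:

1. **Preclustering** — within every gene group, genes are partitioned by
   PAM (partitioning around medoids) on the dissimilarity
   `d(i,j) = 1 − Pearson correlation`; the number of clusters K is chosen
   to maximize the mean intra-cluster correlation (ICC) over K = 2..N−1
   (capped by `k_max`).
2. **Covariate construction** — each gene set (gene / group / subcluster)
   is summarized into one per-sample covariate via the first principal
   component of the standardized member genes, sign-oriented toward the
   cluster medoid (or mean profile). All transform constants are learned
   on training samples only and frozen for test-set projection.
3. **Model fitting** — Cox proportional hazards with an L1 (lasso) or L2
   (ridge) penalty on the genomic coefficients; clinical covariates are
   mandatory and unpenalized. The penalty weight λ is tuned by 10-fold
   cross-validated partial likelihood (CVPL). Ties use the Breslow
   convention.
4. **Evaluation** — on held-out test samples: logrank test on median-split
   risk groups, likelihood-ratio test of the prognostic index, and the
   IPCW (integrated) Brier score with t* = 10 years, over repeated random
   2:1 train/test splits (default 100) shared across all method × mode
   combinations.

A synthetic-data module generates expression matrices with block-correlated
subclusters nested in (optionally overlapping) gene groups plus Cox-model
survival times, so the whole pipeline is testable without external data.

## Test

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (PAM vs exhaustive
enumeration, Cox fits vs an independent Newton oracle, closed-form Brier
checks, null-calibration of the p-values, planted-signal recovery, the
anticorrelated motivating phenomenon, and reproducibility/leakage checks).

## CLI

```bash
# write a synthetic benchmark (expression.tsv, clinical.csv, groups.tsv, truth.json)
gosurv simulate --preset clustered_signal --seed 1 --outdir scratch/sim

# precluster every group
gosurv precluster --expression scratch/sim/expression.tsv \
    --clinical scratch/sim/clinical.csv --groups scratch/sim/groups.tsv \
    --covariate-cols z_bin,z_cont --outdir scratch/pre

# tune and fit one model
gosurv fit --expression scratch/sim/expression.tsv \
    --clinical scratch/sim/clinical.csv --groups scratch/sim/groups.tsv \
    --covariate-cols z_bin,z_cont --mode preclustered --method l1 \
    --outdir scratch/fit

# full repeated-split evaluation with tables and plots
gosurv evaluate --expression scratch/sim/expression.tsv \
    --clinical scratch/sim/clinical.csv --groups scratch/sim/groups.tsv \
    --covariate-cols z_bin,z_cont --n-splits 25 --seed 1 --outdir scratch/eval
```

Input formats: expression is a genes × samples TSV (first column gene ids,
header sample ids); the clinical table is a CSV with a positive `time`
column, a 0/1 `event` column, and optional covariate columns (non-numeric
covariates are dummy-encoded with sorted levels, first dropped); the group
map is a headerless two-column TSV `gene_id<TAB>group_id`, many-to-many.

## Library use

```python
import gosurv as gs

ds, truth = gs.make_benchmark_dataset("clustered_signal", seed=1)
pre = gs.precluster_all_groups(ds, k_max=20)
design = gs.build_design(ds, "preclustered", preclustered=pre)
inp = gs.RiskModelInput(design.X, ds.clinical.values, ds.survival)
lam, curve = gs.tune_lambda(inp, "l1", M=10)
fit = gs.fit_penalized_cox(inp, "l1", lam)

summary = gs.run_evaluation(ds, n_splits=25, methods=("l1", "l2"),
                            modes=("preclustered", "clinical_only"))
gs.report(summary, "scratch/report")
```
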