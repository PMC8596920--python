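# celldrop

Dropout-aware cell type identification from single-cell gene and lncRNA
expression profiles.

scRNA-seq matrices are dominated by *dropouts* — exact zeros produced both
by true absence of a transcript and by technical non-detection. Most
pipelines impute or smooth these zeros away. `celldrop` does the opposite:
it treats the dropout pattern itself as the primary signal for grouping
cells, and only afterwards brings expression levels back in to refine the
grouping into cell types and to call candidate markers.

The pipeline, end to end:

1. **QC filters** — drop molecules detected in < 3 cells or with mean
   total-count-normalized expression < 1e-5; drop cells whose detected-
   molecule count is a significant left-tail outlier under a Normal fit
   (BH FDR < 0.05).
2. **Dropout-based feature selection** — the dropout rate of a molecule
   with mean expression S follows the Michaelis–Menten law
   `P = 1 − S/(K + S)`. A global Michaelis constant K is fitted by least
   squares; each molecule gets its own `K_j = P_j·S_j/(1 − P_j)`, and
   molecules with log K_j significantly above log K (one-sided z-test with
   binomial/delta-method standard error, BH FDR < 0.01, genes and lncRNAs
   fitted separately) are selected — these drop out more than their
   expression level explains, the signature of subpopulation-specific
   expression.
3. **Dropout clusters** — binarize the selected features (1 = expressed),
   compute Manhattan distances between cells, z-score them ("dropout
   distance"), and run DBSCAN with both hyperparameters chosen by a
   silhouette-maximizing coordinate ascent over (eps, MinPts).
4. **Differential analysis** — each dropout cluster vs all remaining
   cells: differential-dropout molecules (|Δ dropout rate| > 0.5, strict)
   and differentially expressed molecules (|log2 FC| > 1 and Wilcoxon
   p < 0.05 on log2(x+1) values); the deduplicated union across clusters
   is the differential-molecule set.
5. **Co-expression network** — Spearman correlation between every pair of
   differential molecules; keep edges with |rho| > 0.4 (strict) and
   p < 0.05; edge weight = |rho|.
6. **Differential modules** — Markov clustering (MCL, inflation 2.5) of
   the weighted network.
7. **Cell types** — each module's average log2 expression is a new
   per-cell feature; a second Manhattan/z-score/DBSCAN round on these
   features yields cell types lettered A, B, … by decreasing size, with
   DBSCAN noise collected into pseudo-type "0".
8. **Candidate markers** — per lettered type vs the rest, a two-group
   linear-model t-test with empirical-Bayes variance moderation; markers
   are molecules with |log2 FC| > 2 (strict) and p < 0.05.

A fully seeded synthetic-data generator (`celldrop.simulate`) plants cell
types, Michaelis–Menten dropout, fold-change markers, dropout shifts,
correlated modules and doublet-like outlier cells, with ground-truth
evaluation (ARI, marker precision/recall, module F1), so every stage is
testable without any external download.

## Worked example

```bash
celldrop simulate --outdir sim --seed 1            # 300 cells, 4 planted types
celldrop run-all --input sim/matrix.csv --kinds sim/kinds.tsv \
    --outdir run --seed 1
celldrop evaluate --truth-dir sim --run-dir run --out metrics.json
```

The `run-all` step prints per-stage counts, ending with (seed 1):

```
"cell_types": {
  "n_noise": 133,
  "n_types": 4,
  "sizes": {"0": 133, "A": 46, "B": 44, "C": 39, "D": 38}
},
"markers": {
  "n_markers": 167,
  "per_type": {"A": 43, "B": 42, "C": 41, "D": 41}
}
```

and `evaluate` prints:

```
{"ari": 1.0, "marker_precision": 0.958, "marker_recall": 1.0,
 "n_types_found": 4, "outlier_recall": 1.0, ...}
```

Reading: the second DBSCAN round recovered exactly the 4 planted types
(ARI 1.0 over clustered cells), every planted 16-fold marker was called
(recall 1.0), ~96% of called markers were planted signal, all 6 planted
doublet-like outliers landed in pseudo-type "0", and 133 borderline cells
were left untyped — density clustering with silhouette-tuned parameters
keeps tight cores and is deliberately conservative about fringes.

The same steps are available as a Python API:

```python
from celldrop.simulate import SimulationConfig, simulate, evaluate
from celldrop.pipeline import RunConfig, run_pipeline

m, truth = simulate(SimulationConfig(seed=1, n_outliers=6))
results, manifest = run_pipeline(m, RunConfig(seed=1), outdir="run")
print(evaluate(truth, results["cell_types"], results["markers"], results["modules"]))
```

Real data enter through `celldrop.io.read_expression_matrix` (CSV/TSV in
either orientation, or MatrixMarket with `.rows`/`.cols` sidecar id
files) plus a two-column molecule→kind (gene/lncRNA) annotation.

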