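# Methods

## The dropout model

In a cells × molecules single-cell expression matrix, the fraction of
cells in which a molecule is exactly zero (its dropout rate P) falls with
its mean expression S following a Michaelis–Menten curve,

    P = 1 − S / (K + S),

where K — the Michaelis constant — is the expression level at which half
the cells drop out. The package fits the global K by nonlinear least
squares of P against S over all molecules with S > 0 and P < 1,
parameterized in log K so positivity is automatic; the optimizer starts
at the median of the per-molecule constants and runs to machine tolerance
(noiseless curves are recovered to ~1e-16 relative error, verified in the
test suite for K spanning 0.1–1000).

Feature selection inverts the law per molecule, K_j = P_j·S_j/(1 − P_j),
and asks whether K_j significantly exceeds the global K: a one-sided
z-test on the log scale, with the standard error propagated from the
binomial error of P_j by the delta method,

    se(log K_j) = 1 / sqrt(n · P_j · (1 − P_j)).

This ignores the (smaller) sampling error of S_j; with ~300 cells and
log-normal expression noise of sd 0.5 the neglected term inflates the z
variance by under 10%, which the Benjamini–Hochberg step at FDR 0.01
absorbs — the empirical false-discovery proportion on planted-outlier
simulations is ≤ 0.02. Genes and lncRNAs are fitted and tested in two
independent runs because their mean-expression regimes differ. Molecules
with S = 0, P = 0 or P = 1 carry no usable dropout information; they are
flagged and never selected.

## Density clustering and the hyperparameter search

Cells are compared by Manhattan distance — on binary dropout features it
counts discordant detections, and it does not square away the many exact
zeros — then z-score-normalized using the off-diagonal mean and sample sd
(the "dropout distance"). DBSCAN runs on the precomputed matrix; a point
is core when at least MinPts points (itself included) lie within eps,
clusters are connected components of cores plus reachable border points,
and all tie-breaks are deterministic (border points join the cluster of
their lowest-index core neighbour; clusters are renumbered by decreasing
size).

Both hyperparameters are chosen by coordinate ascent: with MinPts fixed,
eps sweeps (step 0.001 on the z scale) over the range of MinPts-distances
— each cell's distance to its MinPts-th closest point counting itself,
the smallest eps at which that cell becomes core; with eps fixed, MinPts
sweeps 2…⌈0.1 n⌉; the rounds repeat until the pair is stable (≤ 20
rounds), and the best pair seen anywhere is returned. A labelling only
scores when it has ≥ 2 clusters and at least half the points non-noise;
otherwise it scores −1. Two implementation notes:

* **The score is the silhouette on the original metric.** z-scoring is
  monotone affine, so it changes only the eps scale, not any labelling;
  but the silhouette ratio (b − a)/max(a, b) is not shift-invariant and
  leaves [−1, 1] when "distances" are negative. The z-scored matrix
  therefore carries its affine parameters, and the silhouette is
  evaluated on the de-normalized distances. Noise points are excluded
  from the mean; singleton clusters contribute 0 (the Rousseeuw
  convention).
* **The sweep is cached, not subsampled.** Two eps values falling between
  the same adjacent pairwise distances give identical labellings, so
  DBSCAN runs once per distinct neighbourhood structure; the result is
  identical to the literal fixed-step sweep.

Silhouette maximization with noise excluded has a known bias worth
stating plainly: on data with soft (e.g. Gaussian) cluster boundaries it
prefers tight cores and declares fringe points noise, down to the 50%
non-noise floor. This is intrinsic to the method, not an artifact — the
same behaviour appears in the framework's published application, where a
third of cells ended in the unassigned pseudo-type — and it is why the
pseudo-type "0" exists at all. Downstream analyses keep noise cells in
every "remaining cells" comparison group.

## Differential analysis and the network

Per dropout cluster (cluster vs all remaining cells, noise included in
the remainder): a molecule is differential-dropout when the dropout-rate
difference strictly exceeds 0.5, and differentially expressed when
|log2 FC| strictly exceeds 1 with a two-sided p < 0.05. All published
thresholds in this framework are "greater than", and the implementation
keeps every one strict; boundary cases (difference exactly 0.5, |rho|
exactly 0.4, |logFC| exactly 1 or 2) are excluded, with tests pinning
each boundary. The default two-sample test is the Wilcoxon rank-sum —
robust to the zero-inflated, heavy-tailed log2 values — computed by exact
permutation enumeration when the two groups total ≤ 12 cells and by the
normal approximation with tie correction otherwise; Welch's t is a
config option. logFC is the difference of group means of log2(x+1)
values. p-values are used raw, mirroring the stated rule; BH adjustment
is available behind a flag. These tests run over the full filtered
matrix by default (the feature-selected subset feeds only the dropout
clustering); `differential_universe="selected"` restricts them.

The co-expression network tests every unordered pair of differential
molecules: Spearman rho as the Pearson correlation of mid-ranks, p from
the t approximation t = rho·sqrt((n−2)/(1−rho²)). Edges require
|rho| > 0.4 and p < 0.05; the weight is |rho| with the signed rho kept as
an edge attribute; molecules with no surviving edge leave the node set.
Rank correlations within 1e-12 of ±1 are snapped to exactly ±1 (discrete
rank correlations cannot otherwise fall in that interval; this removes
floating-point noise on perfectly monotone pairs).

## Markov clustering

MCL runs on the weighted adjacency with self-loops set to each node's
maximum incident weight (1 for isolated nodes): column-normalize, then
iterate expansion (2nd matrix power), inflation (entrywise power 2.5,
re-normalize) and pruning (entries < 1e-5) until the matrix changes by
< 1e-6, at most 100 iterations (non-convergence returns the current
state with a warning; in practice convergence takes < 40 iterations).
Each node is assigned to the attractor row holding the largest share of
its column mass — attractor rows of one cluster are identical at
convergence, so this is well defined, resolves overlaps deterministically
and makes the modules an exact partition. Disconnected components can
never merge (the iteration preserves block structure), which the tests
exploit as an oracle.

## Cell types and markers

Module features (per cell, the mean log2 expression of each module's
members) feed a second distance/z-score/DBSCAN round. Clusters become
types A, B, … by decreasing size (overflowing to AA, AB, …); noise
becomes pseudo-type "0", which is never tested for markers by default
(testing it is a flag intended as a negative control) but always counts
among the "remaining cells".

The marker test is a two-group linear-model t with empirical-Bayes
variance moderation: per-molecule residual variances s² (df = n − 2) are
shrunk toward a prior s0² with d0 prior degrees of freedom, both
moment-estimated from the distribution of log s² via digamma/trigamma
identities of the scaled-F model (trigamma inverted by Newton); the
moderated statistic uses s̃² = (d0·s0² + df·s²)/(d0 + df) with df + d0
degrees of freedom. With moderation off the p-values equal the pooled-
variance two-sample t exactly, which is the oracle the tests check
against; a second test verifies that moderation tames near-zero-variance
molecules. Markers require |log2 FC| > 2 (strict) and p < 0.05;
direction is the sign of logFC.

## The synthetic-data generator

`simulate()` draws, from one seed: log-normal base means (meanlog 1,
sdlog 1; lncRNA means scaled by 0.5 to mirror their sparser detection),
cell types as multiplicative mean profiles, log-normal mean-one
expression noise (sd 0.5), and independent per-entry dropout with
probability from the Michaelis–Menten law at the molecule's type-specific
mean (global K = 10 by default). Non-zero values are scaled by
1/(1 − p), so the configured mean is the expected *observed* mean and
unperturbed molecules sit exactly on the Michaelis–Menten curve in
observed (S, P) space — the property the feature selection tests, and
what makes the generator's closed-form dropout check exact.

Planted structure, under the standard study conditions (300 cells, 4
balanced types, 1,000 genes + 200 lncRNAs):

* **Markers** — 40 molecules per type at 16-fold elevated mean, planted
  on molecules with at least median base expression: below that, the
  dropout law leaves the molecule near-undetectable everywhere and a
  16-fold change in its configured mean cannot produce |log2 FC| > 2 in
  observed values, so it would encode no recoverable signal.
* **Dropout shifts** — 40 molecules per type whose dropout probability
  moves by a signed delta in that type, default −0.6 ("switched on" in
  its type), planted only where the base rate leaves room for the full
  |delta|. The sign matters: with K = 10 and these base means most
  molecules already drop out in ~80% of cells, so a +0.6 shift clips at
  1 and plants at most a ~0.2 observable difference; a −0.6 shift is
  realizable for the majority of molecules.
* **Modules** — blocks sharing a latent per-cell factor, giving a chosen
  within-block rank correlation. These are planted among otherwise-null
  molecules and test the correlation machinery in isolation; having no
  fold change or shift, they are not differential and do not enter the
  end-to-end network (the acceptance script measures their recovery by a
  direct network + MCL run instead).
* **Outliers** — doublet-like cells, each a ~50/50 mixture of a distinct
  pair of type profiles. Cells with i.i.d.-random profiles would all
  average to the same point in module-feature space and form their own
  spurious cluster; mixtures of distinct pairs sit between the type
  clusters, far from the types and from each other, and are the planted
  DBSCAN noise.
* **K-outliers** — molecules whose dropout obeys an inflated Michaelis
  constant (K × 10 by default), the ground truth for feature-selection
  power.

What the generator does *not* emulate: library-size variation, batch
effects, counts (values are continuous), gene-length effects, or
transcriptional kinetics. Passing tests therefore demonstrate that the
pipeline recovers the structure this data model plants under
Michaelis–Menten zero inflation — not that it is robust to every real
scRNA-seq artifact.

`evaluate()` reports ARI between planted and assigned types over the
cells the pipeline actually typed (noise counted separately, with the
fraction of planted outliers reaching type "0"), marker precision (a
call counts as signal when it is a planted marker *or* a planted
dropout-shift molecule of the mapped type — the shift is genuine
type-specific differential signal the marker rule legitimately finds),
marker recall over planted fold-change markers (union per planted type,
so a split cluster cannot inflate it), and best-match module F1.

## Problem sizes and determinism

The default test and acceptance configurations use 300 cells and 1,200
molecules (smaller for plumbing tests), sizes at which every stage of
the pipeline — including the two full hyperparameter searches — runs in
seconds while leaving all statistical checks well-powered. The pipeline
itself contains no randomness: given a matrix and a config it is fully
deterministic, all tie-breaks are specified, and the only stochastic
component is the generator behind a single integer seed, so repeated
runs produce byte-identical manifests.

## Known limitations

* The silhouette-guided search inherits silhouette's preference for
  convex, comparably dense clusters, and (as discussed) trims soft
  cluster boundaries into the noise type.
* The z-test for elevated K_j treats S_j as fixed; very low-expression
  molecules (few non-zero cells) have anti-conservative tails, mitigated
  but not eliminated by the FDR step.
* The Spearman p-value uses the t approximation, inaccurate below ~10
  cells; an exact permutation option exists for small n.
* With fewer than ~2 molecules selected, no differential molecules, or
  an empty network, the pipeline stops with a "no cluster structure"
  stage failure rather than inventing types — on structureless data this
  is the expected outcome.
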