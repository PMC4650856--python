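# Methods

`grnpath` implements a network-based strategy for finding disease-gene
candidates and differential-diagnosis biomarkers from paired mRNA/miRNA
expression profiles. This note records the models, the numerical choices, and
what the synthetic benchmark does and does not establish.

## Pipeline model

The analysis has three stages.

**1. Tissue-specific gene regulatory network (GRN).** A candidate network of
directed regulations — TF→gene, TF→miRNA and miRNA→gene, from target
prediction and curated-interaction resources — is filtered by co-expression:
each candidate edge receives the Pearson correlation α of its endpoint
expression vectors, and edges with |α| below a cutoff are discarded. The
cutoff is chosen by the scale-free criterion: for a grid of cutoffs, the
degree distribution of each thresholded sub-network (miRNA regulators and TF
regulators separately, in- and out-degree) is fit to a power law

    p(k) = k^(−λ),

by least squares of log₁₀ p(k) on log₁₀ k over the distinct observed degrees
(zero-frequency degrees are excluded since their log is undefined; no binning
or regularization is applied). The fit quality R² rises with the cutoff while
the network shrinks; the chosen default of 0.8 for both regulator classes
balances the two, and results are reportedly robust over 0.6–0.8. The scan
table is advisory; the cutoff used is always an explicit configuration value.
Retained edges carry the path weight **β = 1 − |α|**, so strongly co-expressed
regulations are short.

Correlations are computed over the disease-class samples by default (the GRN
is tissue-specific); an `all`-samples mode exists, and regulator–target pairs
that span the two platforms use the sample intersection of both matrices.
Each expression matrix is quantile-normalized independently; no cross-platform
rescaling is applied (Pearson correlation is scale-invariant, so this affects
nothing downstream of scoring).

**2. Shortest-path candidate discovery.** Known disease genes ("seeds") are
mapped into the GRN and the minimum-total-β path is computed for every seed
pair with Dijkstra's algorithm. By guilt-by-association, the interior nodes of
these paths — the "path genes" — are new candidates. The graph view is
undirected by default: many seeds are non-TF targets with zero out-degree, and
paths between two such seeds exist only through incoming regulations.
Antiparallel duplicate edges merge keeping the smaller β. Seeds absent from
the GRN are skipped with a warning, and unreachable pairs contribute no path;
both situations occur in real data and are counted, never fatal.

**3. Biomarker selection by KNN + jackknife.** Candidate genes are scored as
class discriminators with a Euclidean K-nearest-neighbor classifier using
cumulative ("one-dimensional") voting: class m receives

    Y_m = Σ_{K=1..k_max} (number of class-m samples among the K nearest neighbors),

i.e. the neighbor at rank r contributes k_max − r + 1 votes. This removes the
arbitrary choice of a single K and reduces exactly to 1-NN at k_max = 1. The
printed form of this scoring rule in the source literature is typographically
garbled; the cumulative-vote reading implemented here is the one consistent
with its stated intent, and a plain fixed-K majority vote is provided as an
alternative. Gene sets are evaluated by the jackknife (leave-one-out) test:

    accuracy = 100 · correct predictions / total predictions  [%].

Sets are assembled by greedy forward selection in descending singleton-
accuracy order, adding a gene when it strictly increases the joint jackknife
accuracy and stopping at 100 % or exhaustion. The exact set-assembly rule used
in the original study is unstated, so the strategy is pluggable (a
threshold-on-singleton-accuracy alternative is included) and no claim is made
of reproducing specific published gene lists.

## Statistical components

- **Differential expression:** two-sided equal-variance Student's t-test
  (Welch behind a flag) plus median-ratio fold change, computed on log2 data
  as 2^(median(A) − median(B)). A feature is DE when p < 0.01 (strict) and
  FC ≥ 2 or ≤ 0.5 (inclusive). No multiple-testing correction enters the
  call — the procedure is deliberately a raw-p filter — but a
  Benjamini–Hochberg FDR column is emitted for information.
- **Enrichment:** Fisher's exact test (two-sided by default) of path genes
  against the DE status of their role-class background. Two background
  conventions are reported: disjoint rows (candidates removed from the
  background row; standard practice) and the printed convention (background
  row as typically typeset in overlap tables, including the candidates).
- **Quantile normalization:** per-rank means across samples; tied values
  within a column receive the mean of the reference values at the ranks they
  occupy (average-rank convention). Idempotent on tie-free data.

## Numerical conventions and degenerate inputs

- β = 1 − |α| is computed exactly; ties at the cutoff (|α| = cutoff) are
  retained; |α| = 1 gives zero-weight edges, which paths may traverse freely.
- Dijkstra tie-breaking is fully deterministic: among equal-β paths, fewest
  hops, then lexicographically smallest node sequence (the heap key is the
  tuple (distance, hops, node sequence), which stays monotone because β ≥ 0).
  An `all_optimal` mode enumerates every co-optimal path instead.
- KNN distance ties rank neighbors in training order; callers sort samples by
  id first, so ties resolve by sample id. Tied class scores go to the class
  of the single nearest neighbor, then lexicographically. Expression is used
  on the log2 scale without re-standardization (an optional z-score flag is
  the sensitivity analysis); default k_max = 3, since the smallest class at
  study scale leaves 4–5 same-class neighbors in a leave-one-out fold.
- t-test with zero variance in both groups: p = 1 for equal means, p = 0
  otherwise. Fisher's test with a degenerate margin: p = 1.
- Power-law fits need ≥ 3 distinct degrees; scan rows where the fit is
  undefined are flagged, not dropped. Missing expression values are rejected
  outright rather than imputed.

## Synthetic data: what it emulates

The generator plants every structure the pipeline is supposed to find, with
defaults at the study scale: 14 + 6 + 6 + 5 samples in four classes
(SPN / PanNET / PDAC / normal), 30 TFs, 30 miRNAs, 150 genes.

- **Co-expression** is planted through shared latent signals: a true edge's
  target has latent u_t = ±α·u_reg + √(1−α²)·ε with α = 0.9 by default, so
  the expected edge correlation is exactly ±α (negative for miRNA
  regulators, which repress). Each target has at most one true regulator,
  keeping per-edge correlations analytic; decoy candidate edges (50 % of the
  random candidates by default) carry no signal. Expression is
  base (8.0) + 0.5·latent on the log2 scale.
- **Seed structure:** 26 seeds (4 TFs, 7 miRNAs, 15 genes, the scale of a
  curated disease-gene list). Five designated intermediate TFs each regulate
  one disjoint seed pair, so the shortest path of that pair provably runs
  through the intermediate and nothing can bypass it. Remaining seeds stay
  unconnected, mirroring seeds that fail to map in real networks.
- **DE genes:** ten genes shifted ±2 log2 units in the disease class
  (median-ratio FC 4 / 0.25). **Biomarkers:** five genes per diagnostic
  contrast shifted 3 log2 units between the contrasted classes.

The benchmark experiments use these sizes: 20 replicate simulations for
recovery rates; 10 for the acceptance script (pooled edge counts are then in
the hundreds, which bounds the Monte-Carlo error of the reported rates well
below the margins tested); the scale-free recovery check uses
preferential-attachment graphs of 30 000 nodes (m = 2), the size at which the
unbinned least-squares exponent estimate stabilizes inside the scale-free
range (2, 3) — on smaller graphs this estimator is biased low by the sparse
degree tail, a known property of log-log regression on raw frequencies.

Two deliberate choices in the recovery experiments: **(i)** edge-recovery is
measured at the default cutoff 0.8 on disease-class samples (n = 14), where
the sampling spread of r at ρ = 0.9 makes per-edge retention ≈ 0.9 — the
realistic operating point; **(ii)** path-intermediate recovery, which needs
*every* planted edge of a seed pair simultaneously, is run at cutoff 0.6
(inside the robust 0.6–0.8 range) with correlations over all samples, where
per-edge retention is ≈ 1 and the experiment measures the path machinery
rather than correlation sampling noise. The label-permutation null for the
classifier uses balanced 14 + 14 classes because leave-one-out on small
balanced groups has an intrinsic pessimistic bias of (n−1)/(2n−1) under
random labels (45.5 % at 6 + 6, 48.1 % at 14 + 14); at 14 + 14 the null mean
isolates classifier behavior from that small-sample artifact.

What the synthetic benchmark does **not** show: robustness to probe-level
microarray noise, batch effects, correlated measurement error between
platforms, multi-regulator targets with diluted correlations, or
genome-scale (20 000-gene) networks. Passing tests demonstrate that each
stage recovers the structure it is defined to recover under its own model
assumptions, not that those assumptions hold for any particular real dataset.

## Known limitations

- The power-law fit is the field's conventional log-log least squares on the
  empirical density; it is not a maximum-likelihood (Clauset-style) estimator
  and is biased on heavy-tailed samples — acceptable here because the fit is
  used as a relative fitness score across cutoffs, not as an estimate of λ.
- Greedy forward selection is order-dependent and makes no optimality claim;
  with small sample counts, 100 % jackknife accuracy is a weak guarantee of
  generalization (the original study makes the same caveat).
- The pipeline assumes each feature id appears in exactly one platform matrix
  and performs no probe-to-gene mapping.
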