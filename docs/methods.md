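# Methods

## The model

`biparclust` analyses heterogeneity among spatially resolved transcriptome
profiles of the feto-maternal interface. Each profile (one region of
interest, ROI) comes from one tissue layer — amnion epithelium (AEC), amnion
mesenchyme (AMC), chorion trophoblast (CTC) or maternal decidua (DEC) — of
one patient with one pregnancy phenotype: term not in labor (TNIL, control),
term in labor (TIL), spontaneous preterm birth (PTB) or preterm prelabor
rupture of membranes (PPROM).

The analysis proceeds in five stages.

**1. Feature selection.** For each gene, the coefficient of variation of its
log2 normalized counts across all samples,

    CV = SD[log2 X] / Mean[log2 X],

with the sample (n−1) standard deviation. The top 10% of genes by CV are
retained; the selection count is ⌊fraction × n_genes⌋, which maps 11,921
genes to 1,192 at the default fraction. Counts are floored at 1 before the
log2 so transformed values (and downstream edge weights) are nonnegative;
genes whose mean log2 is zero (entirely at or below the floor) get an
infinite-CV sentinel, sort last and are never selected. The default computes
CV on all samples, controls included; `cv_cases_only` restricts it to cases.

**2. Bipartite network.** Case samples (TIL ∪ PTB ∪ PPROM; TNIL excluded)
and selected genes are the two node classes; every case–gene pair carries an
edge of weight w_ij = log2 max(X_ij, 1). Zero weights are equivalent to
absent edges. Negative weights are forbidden — the modularity below is not
defined for them — which the floor guarantees.

**3. Biclustering by weighted bipartite modularity.** The objective is
Barber's bipartite modularity, weighted:

    Q = (1/m) Σ_ij [ w_ij − s_i t_j / m ] δ(g_i, h_j)

with case strengths s_i (row sums), gene strengths t_j (column sums), total
weight m, and δ coupling only case–gene pairs in the same cluster.
Equivalently Q = Σ_c (W_c/m − S_c T_c/m²) over clusters. The all-in-one
partition scores exactly 0, and k equal disjoint blocks score 1 − 1/k under
the block partition — both used as exact test anchors.

The optimizer alternates one-sided optimal reassignments (each gene to its
best cluster given the case labels, then vice versa — each side's
reassignment decomposes node-by-node, so every sweep is monotone in Q) with
a greedy cluster-merge phase, and restarts from seeded random case
partitions (default 20 restarts; restart 0 starts from all-singleton case
labels). Each one-sided move also offers an "empty cluster" option scoring
exactly 0, without which zero-contribution singletons are unreachable and
small sparse networks get stuck below the optimum. Ties in label moves break
toward the lowest label, making runs bit-reproducible at a fixed seed. The
number of clusters is emergent, never user-set; if the best found Q is
negative the single-cluster baseline (Q = 0) is returned. On every network
small enough to enumerate all joint set partitions (≤ 4 cases × 4 genes) the
search attains the exhaustive optimum; this is asserted in the test suite
over 50 random networks. Clusters containing only cases or only genes are
permitted but flagged (`single_sided`).

**4. Permutation significance.** The null model shuffles, independently for
every gene, its weight vector across cases — preserving the node sets, every
per-gene weight multiset (hence every gene strength) and m exactly, while
destroying case–gene association. Each permuted network is re-maximized
under the same restart/seed protocol, so the null is a distribution of
*maximized* Q; `rescore_fixed_partition` exposes the cheaper alternative of
re-scoring the observed partition. Reported are the null mean (the Q-Random
of a permutation analysis), z = (Q_real − mean)/SD (sample SD), the normal
approximation p = 2(1 − Φ(|z|)), and the add-one two-tailed empirical p
= (#{|q_perm − mean| ≥ |Q_real − mean|} + 1)/(n_perms + 1), whose floor is
1/(n_perms+1). Default n_perms = 1000; the test suite uses 200 with the
resolution caveat that implies. One child seed per permutation index makes
the result independent of evaluation order.

**5. Layer-profile enrichment.** Per cluster, the case ROIs are tallied by
layer (and, descriptively, by phenotype). Every unordered cluster pair is
compared by Pearson chi-square on the 2×L layer table without continuity
correction; layers empty in *both* clusters are dropped first, so df =
(retained layers − 1) varies by pair — this reproduces the heterogeneous
df pattern such tables show. p-values come from the regularized upper
incomplete gamma; the Bonferroni factor is the number of cluster pairs
(6 for 4 clusters), capped at 1. Expected cells below 5 raise a warning but
do not switch to an exact test. Clusters with no cases are excluded and do
not inflate the correction factor.

A control-inclusive companion analysis (`hierclust`) z-scales the log2
expression of the top-CV genes per gene (subset first, then scale) and
clusters samples by average linkage (UPGMA) on Pearson distances d = 1 − r
(not 1 − |r|). UPGMA is computed by scipy's linkage; heights are monotone by
construction of average linkage.

## Visualization

`fruchterman_reingold` is a standard force simulation — attraction w·d²/k
along edges, repulsion k²/d between all pairs, linear cooling — implemented
in-package so the equilibrium spacing is physical (two nodes joined by a
unit edge settle near distance k) rather than rescaled to a bounding box.
`explode_layout` rigidly translates each cluster so centroids sit equally
spaced on a circle of configurable radius, preserving within-cluster
geometry exactly (an isometry per cluster). The rendered SVG marks cases as
phenotype-colored circles, genes as triangles, edge opacity proportional to
weight (only the top weight quantile drawn, default 0.5), and a red arrow
between every cluster pair significant after Bonferroni correction; arrows
carry SVG gids so figures are machine-checkable, and rendering is
byte-stable for identical inputs.

## Synthetic data generator

The generator emulates the target study design: 13 patients (TNIL 4, TIL 3,
PTB 3, PPROM 3) × 4 layers = 52 ROIs, with QC dropout to 44. Four planted
expression programs mirror the reported cluster pattern: DEC genes across
all labor phenotypes; AEC genes in PPROM and PTB; CTC genes across labor
phenotypes; AMC+CTC genes in term labor. Defaults: 1,000 genes (a
`full_shape_config` emits 11,921), 2.5% of genes per program, planted
effect +4 log2 units, negative-binomial noise with size r = 10
(var = μ + μ²/r) around a baseline of 2⁶ counts, and a patient random
intercept of SD 0.3 log2 units mimicking patient-level correlation across
layers. Draws are scaled to a common library size and rounded, standing in
for platform normalization while keeping counts integral. Baseline,
dispersion and intercept SD are chosen as typical of ROI-level profiling
data; no published fold changes exist for the planted programs, so the
effect size is a testability choice, not an estimate.

Uniform random dropout cannot reproduce the published sample bookkeeping, so
`study_shaped()` drops 3 case and 5 control ROIs stratified, yielding
exactly 33 cases + 11 TNIL controls.

Recovery against the planted truth is scored on the gene side only
(adjusted Rand index between recovered gene clusters and program labels,
restricted to planted genes surviving selection): a case ROI can belong to
two programs at once (CTC×TIL sits in both the CTC program and the AMC+CTC
term-labor program), so a case-side truth partition is ill-defined.

What the generator does *not* emulate: probe-level chemistry and
segmentation, gene–gene correlation beyond the planted programs,
heavy-tailed library-size variation, batch effects, or biologically
realistic effect-size spectra. Passing recovery tests therefore demonstrate
correctness of the machinery under a clean planted model, not expected
performance on real tissue data.

## Numerical choices

- Modularity comparisons use absolute tolerance 1e-12; the optimizer treats
  improvements below that as noise.
- The permutation conserves per-gene weight multisets exactly; strengths
  recomputed from a reordered column can differ by float-summation
  associativity (≈1 ulp), so exactness checks canonicalize summation order.
- Sample SD (ddof = 1) is used everywhere a SD appears: CV, z-scaling, the
  permutation z.
- Stage seeds derive from the top-level seed by hashing named streams
  (`maximize`, `significance`, `layout`), and the significance test spawns
  one child per permutation; all derived seeds stay below 2³¹.
- Degenerate inputs fail loudly: single-sample CV, zero-variance vectors in
  Pearson distance, all-zero networks, metadata-less samples and unknown
  layer/phenotype labels are errors, never silent drops.

## Scale of the shipped experiments

The default synthetic size (1,000 genes → 100 selected, 33 cases) runs the
full pipeline in seconds and is the size used by the test suite and the
acceptance script; planted-recovery experiments use 20 seeds, significance
tests 200 permutations, and the null-calibration experiment 50 zero-effect
replicates at 5 optimizer restarts per maximization (the calibration
property requires only that real and permuted networks share a protocol,
not a particular restart count).

## Known limitations

- Modularity maximization is a heuristic; beyond exhaustively checkable
  sizes there is no optimality guarantee, only multi-restart robustness.
- The observed-data headline quantities of the motivating study (its exact
  Q, z, and four-cluster composition) depend on an undeposited expression
  matrix and are not reproducible here; the package's claims are the
  property-based ones above.
- The chi-square enrichment is a large-sample approximation applied to
  small per-cluster counts (warned, as published analyses of this design
  do implicitly); treat borderline corrected p-values as hypothesis-
  generating.
- One published corrected value (the pair printing statistic 7.79 with
  p = 0.02618) is internally inconsistent with the chi-square survival
  function (sf(7.79, 2) ≈ 0.0203, consistent instead with a statistic of
  ≈7.29); it is documented here and excluded from numeric anchoring.
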