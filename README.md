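# biparclust

Bipartite-network biclustering of spatially resolved transcriptome profiles
from the feto-maternal interface.

Spatial ROI profiling of fetal membranes yields one transcriptome per
tissue layer (amnion epithelium AEC, amnion mesenchyme AMC, chorion
trophoblast CTC, decidua DEC) per patient, across pregnancy phenotypes
(TNIL term-not-in-labor controls; TIL, PTB, PPROM cases). The scientific
question is which layers, in which conditions, share transcriptional
programs. `biparclust` answers it by treating case samples and
high-variability genes as the two sides of a weighted bipartite network and
finding joint clusters of both.

## Method

1. **Feature selection** — per gene, CV = SD[log2 X]/Mean[log2 X] across
   samples; keep the top 10% (⌊0.10 · n⌋ genes; 11,921 → 1,192).
2. **Network** — cases × selected genes with edge weights w_ij =
   log2 max(X_ij, 1).
3. **Biclustering** — maximize weighted Barber bipartite modularity
   Q = (1/m) Σ_ij [w_ij − s_i t_j/m] δ(g_i, h_j) by a dual-sided local-move
   + merge heuristic with seeded restarts; the number of biclusters is
   emergent.
4. **Significance** — compare Q with re-maximized Q over networks whose
   per-gene weight vectors are shuffled across cases (preserving each
   gene's weight distribution exactly); report Q-Random (null mean), z and
   two-tailed p (normal and empirical).
5. **Enrichment** — per cluster-pair Pearson chi-square on the case layer
   profiles (all-empty layers dropped, hence per-pair df), Bonferroni-
   corrected by the number of pairs.
6. **Visualization** — Fruchterman–Reingold layout, exploded by cluster,
   with arrows between significantly different cluster pairs; plus a
   control-inclusive UPGMA/Pearson-distance dendrogram of all samples.

A synthetic generator reproduces the study shape (13 patients × 4 layers →
44 post-QC ROIs = 33 cases + 11 controls) with four planted layer×phenotype
programs, so the entire pipeline runs and is tested without any download.

## Worked example

```python
import biparclust as bp

matrix, records, truth = bp.study_shaped(seed=1)        # 1,000 genes, 44 ROIs
selected = bp.select_top_cv(bp.gene_cv(bp.log2_transform(matrix)), 0.10)
cases, controls = bp.split_cases_controls(matrix, records)
network = bp.build_network(cases, selected)
solution = bp.maximize_modularity(network, seed=7, n_restarts=20)
result = bp.modularity_significance(network, n_perms=200, seed=7, solution=solution)
table = bp.pairwise_enrichment(bp.cluster_profiles(solution, records))
print(network, "->", solution.n_clusters, "biclusters, Q=%.4f" % solution.q)
print("Q_random=%.4f z=%.1f p_emp=%.4g"
      % (result.q_random_mean, result.z, result.p_empirical))
print(table[["Cluster_i", "Cluster_j", "Chi_square", "p_Bonferroni"]].head(3))
```

prints

```
BipartiteNetwork(33 cases x 100 genes, m=2.22e+04) -> 4 biclusters, Q=0.0857
Q_random=0.0314 z=78.5 p_emp=0.004975
   Cluster_i  Cluster_j  Chi_square  p_Bonferroni
0          1          2   17.000000      0.001221
1          1          3   10.406250      0.032996
2          1          4    5.833333      0.094352
```

i.e. the optimizer recovers 4 biclusters whose separation (Q = 0.086) is far
above the permutation null (0.031, empirical p at its 200-permutation
floor), and most cluster pairs differ in tissue-layer composition after
Bonferroni correction. On this synthetic dataset the recovered gene clusters match the
planted programs exactly (`bp.recovery_ari(solution, truth, selected)` → 1.0).

The same pipeline runs from the shell:

```sh
biparclust simulate --seed 7 --out-prefix sim/
biparclust run --config pipeline.yaml     # paths + fraction/floor/perms/seed/alpha
```

`run` writes `genes.txt`, `solution.json`, `perm.json`, `table1.csv`,
`profiles.csv`, `dendro.json`/`.nwk`, `fig.svg` and a `manifest.json`
(seed, config hash, versions); re-running a manifest's config reproduces
every output byte-for-byte. Subcommands `validate`, `select`, `cluster`,
`significance`, `enrich`, `hclust`, `plot` expose the stages individually.

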