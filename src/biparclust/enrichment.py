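"""Per-cluster layer/phenotype profiles and pairwise chi-square enrichment.

For every unordered pair of biclusters, the distribution of case tissue
layers is compared with a Pearson chi-square on the 2 x L contingency table
(layers empty in both clusters dropped, hence the heterogeneous df), with
Bonferroni correction by the number of cluster pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaincc

from .bipartite import BiclusterSolution
from .io_metadata import CASE_PHENOTYPES, LAYERS, SampleMetadata

ENRICHMENT_COLUMNS = [
    "Cluster_i",
    "Cluster_j",
    "Chi_square",
    "Degree_of_freedom",
    "p_value",
    "p_Bonferroni",
    "significant",
]


@dataclass
class ClusterProfile:
    """Counts of case samples per tissue layer and per phenotype in one bicluster."""

    cluster: int
    counts_by_layer: dict[str, int] = field(
        default_factory=lambda: {l: 0 for l in LAYERS}
    )
    counts_by_phenotype: dict[str, int] = field(
        default_factory=lambda: {p: 0 for p in CASE_PHENOTYPES}
    )

    @property
    def n_cases(self) -> int:
        return sum(self.counts_by_layer.values())

    def layer_vector(self) -> np.ndarray:
        return np.array([self.counts_by_layer[l] for l in LAYERS], dtype=float)


def cluster_profiles(
    solution: BiclusterSolution, records: Sequence[SampleMetadata]
) -> list[ClusterProfile]:
    """Tally each cluster's cases by layer and phenotype; gene nodes are ignored."""
    by_id = {r.sample_id: r for r in records}
    profiles = {c: ClusterProfile(cluster=c) for c in range(1, solution.n_clusters + 1)}
    for case_id, label in zip(solution.case_ids, solution.case_labels):
        rec = by_id.get(case_id)
        if rec is None:
            raise ValueError(f"case {case_id!r} has no metadata record")
        prof = profiles[int(label)]
        prof.counts_by_layer[rec.layer] += 1
        if rec.phenotype in prof.counts_by_phenotype:
            prof.counts_by_phenotype[rec.phenotype] += 1
    return [profiles[c] for c in sorted(profiles)]


def profiles_frame(profiles: Sequence[ClusterProfile]) -> pd.DataFrame:
    """Long-format table of the per-cluster layer and phenotype counts."""
    rows = []
    for p in profiles:
        for layer, n in p.counts_by_layer.items():
            rows.append((p.cluster, "layer", layer, n))
        for pheno, n in p.counts_by_phenotype.items():
            rows.append((p.cluster, "phenotype", pheno, n))
    return pd.DataFrame(rows, columns=["cluster", "kind", "label", "n_cases"])


def chi_square_statistic(table: np.ndarray) -> tuple[float, int]:
    """Pearson chi-square of a 2 x L count table, no continuity correction.

    Columns that are zero in both rows are dropped before computing, so
    df = (retained columns - 1); this is what yields the heterogeneous df
    across cluster pairs. Expected cells below 5 draw a warning, not a switch
    to an exact test.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError(f"expected a 2 x L table, got shape {table.shape}")
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.shape[1] < 2:
        raise ValueError("profiles identical support: fewer than 2 non-empty columns")
    if np.any(table.sum(axis=1) == 0):
        raise ValueError("a cluster row has zero cases")
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    total = table.sum()
    expected = np.outer(row, col) / total
    if np.any(expected < 5):
        warnings.warn(
            "expected cell count < 5; chi-square approximation may be poor",
            stacklevel=2,
        )
    chi2 = float(((table - expected) ** 2 / expected).sum())
    df = int((table.shape[1] - 1) * (table.shape[0] - 1))
    return chi2, df


def chi_square_sf(x: float, df: int) -> float:
    """Upper-tail chi-square probability via the regularized upper incomplete gamma."""
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    if x < 0:
        raise ValueError(f"statistic must be >= 0, got {x}")
    return float(gammaincc(df / 2.0, x / 2.0))


def pairwise_enrichment(
    profiles: Sequence[ClusterProfile], alpha: float = 0.05
) -> pd.DataFrame:
    """All pairwise layer-profile chi-square tests with Bonferroni correction.

    Returns one row per unordered cluster pair with columns Cluster_i,
    Cluster_j, Chi_square, Degree_of_freedom, p_value, p_Bonferroni and a
    boolean ``significant`` flag at corrected p < alpha. Clusters with zero
    cases are excluded (with a warning) and do not count toward the
    correction factor.
    """
    usable = [p for p in profiles if p.n_cases > 0]
    dropped = [p.cluster for p in profiles if p.n_cases == 0]
    if dropped:
        warnings.warn(f"clusters with zero cases excluded: {dropped}", stacklevel=2)
    if len(usable) < 2:
        raise ValueError("need >= 2 clusters with at least one case each")
    n_comparisons = len(usable) * (len(usable) - 1) // 2
    rows = []
    for a, b in combinations(usable, 2):
        table = np.vstack([a.layer_vector(), b.layer_vector()])
        chi2, df = chi_square_statistic(table)
        p = chi_square_sf(chi2, df)
        p_bonf = min(1.0, p * n_comparisons)
        rows.append((a.cluster, b.cluster, chi2, df, p, p_bonf, p_bonf < alpha))
    return pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS)
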