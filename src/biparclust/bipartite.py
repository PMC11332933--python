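"""Weighted case-gene bipartite network and bicluster detection.

The network has case samples on one side, genes on the other, and an edge of
weight log2(X) for every case-gene pair (X the normalized count, floored at 1
so weights are nonnegative). Biclusters are found by maximizing the weighted
Barber bipartite modularity

    Q = (1/m) sum_ij [ w_ij - s_i t_j / m ] delta(g_i, h_j)

where s_i and t_j are case and gene node strengths, m the total edge weight,
and delta couples only case-gene pairs sharing a cluster. Equivalently, over
clusters c with within-cluster weight W_c and one-sided strengths S_c, T_c:

    Q = sum_c ( W_c / m  -  S_c T_c / m^2 ).

The optimizer is a bipartite dual-sided local-move heuristic (BRIM-style
alternation of one-sided optimal reassignments) interleaved with a greedy
cluster-merge phase, restarted from seeded random initial partitions; the
number of clusters is emergent, never user-set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_metadata import ExpressionMatrix

_MAX_SWEEPS = 200
_Q_TOL = 1e-12


class BipartiteNetwork:
    """Case nodes + gene nodes + a dense nonnegative weight grid.

    Zero weights represent absent edges; they contribute nothing to strengths
    or modularity either way.
    """

    def __init__(
        self,
        case_ids: Sequence[str],
        gene_ids: Sequence[str],
        weights: np.ndarray,
    ) -> None:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (len(case_ids), len(gene_ids)):
            raise ValueError(
                f"weights shape {weights.shape} does not match "
                f"{len(case_ids)} cases x {len(gene_ids)} genes"
            )
        if not np.all(np.isfinite(weights)):
            raise ValueError("non-finite edge weight")
        if np.any(weights < 0):
            raise ValueError("negative edge weight; modularity requires w >= 0")
        overlap = set(case_ids) & set(gene_ids)
        if overlap:
            raise ValueError(f"ids used both as case and gene: {sorted(overlap)[:5]}")
        self.case_ids = [str(c) for c in case_ids]
        self.gene_ids = [str(g) for g in gene_ids]
        self.weights = weights

    @property
    def n_cases(self) -> int:
        return self.weights.shape[0]

    @property
    def n_genes(self) -> int:
        return self.weights.shape[1]

    @property
    def m(self) -> float:
        """Total edge weight."""
        return float(self.weights.sum())

    @property
    def case_strengths(self) -> np.ndarray:
        return self.weights.sum(axis=1)

    @property
    def gene_strengths(self) -> np.ndarray:
        return self.weights.sum(axis=0)

    def __repr__(self) -> str:
        return (
            f"BipartiteNetwork({self.n_cases} cases x {self.n_genes} genes, "
            f"m={self.m:.4g})"
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "case_ids": self.case_ids,
            "gene_ids": self.gene_ids,
            "weights": [[float(w) for w in row] for row in self.weights],
        }
        Path(path).write_text(json.dumps(payload) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "BipartiteNetwork":
        payload = json.loads(Path(path).read_text())
        return cls(
            payload["case_ids"], payload["gene_ids"], np.array(payload["weights"])
        )


def build_network(
    case_matrix: ExpressionMatrix,
    selected_genes: Sequence[str],
    floor: float = 1.0,
) -> BipartiteNetwork:
    """Weight each case-gene edge by log2(max(X, floor)) over the selected genes."""
    if len(selected_genes) == 0:
        raise ValueError("empty selected gene list")
    if floor <= 0:
        raise ValueError(f"floor must be > 0, got {floor}")
    sub = case_matrix.subset_genes(list(selected_genes))
    weights = np.log2(np.maximum(sub.values, floor)).T  # cases x genes
    if weights.sum() <= 0:
        raise ValueError("all-zero network: every weight at or below the floor")
    return BipartiteNetwork(case_matrix.sample_ids, list(selected_genes), weights)


@dataclass
class BiclusterSolution:
    """A joint partition of case and gene nodes with its modularity.

    ``case_labels`` / ``gene_labels`` hold integer cluster labels 1..n_clusters
    aligned to the network's node orderings. ``single_sided`` flags clusters
    containing only cases or only genes.
    """

    case_ids: list[str]
    gene_ids: list[str]
    case_labels: np.ndarray
    gene_labels: np.ndarray
    q: float
    single_sided: list[int] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return int(max(self.case_labels.max(initial=0), self.gene_labels.max(initial=0)))

    @property
    def assignment(self) -> dict[str, int]:
        """node -> cluster map with ``case:``/``gene:`` namespacing."""
        out = {f"case:{c}": int(l) for c, l in zip(self.case_ids, self.case_labels)}
        out.update(
            {f"gene:{g}": int(l) for g, l in zip(self.gene_ids, self.gene_labels)}
        )
        return out

    def case_clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {c: [] for c in range(1, self.n_clusters + 1)}
        for cid, lab in zip(self.case_ids, self.case_labels):
            out[int(lab)].append(cid)
        return out

    def gene_clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {c: [] for c in range(1, self.n_clusters + 1)}
        for gid, lab in zip(self.gene_ids, self.gene_labels):
            out[int(lab)].append(gid)
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "assignment": {
                "cases": {c: int(l) for c, l in zip(self.case_ids, self.case_labels)},
                "genes": {g: int(l) for g, l in zip(self.gene_ids, self.gene_labels)},
            },
            "n_clusters": self.n_clusters,
            "Q": self.q,
            "single_sided_clusters": self.single_sided,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "BiclusterSolution":
        payload = json.loads(Path(path).read_text())
        cases = payload["assignment"]["cases"]
        genes = payload["assignment"]["genes"]
        return cls(
            case_ids=list(cases),
            gene_ids=list(genes),
            case_labels=np.array(list(cases.values()), dtype=int),
            gene_labels=np.array(list(genes.values()), dtype=int),
            q=float(payload["Q"]),
            single_sided=list(payload.get("single_sided_clusters", [])),
        )


def _labels_from_mapping(
    network: BipartiteNetwork, assignment: Mapping[str, int]
) -> tuple[np.ndarray, np.ndarray]:
    try:
        case_labels = np.array(
            [assignment[f"case:{c}"] for c in network.case_ids], dtype=int
        )
        gene_labels = np.array(
            [assignment[f"gene:{g}"] for g in network.gene_ids], dtype=int
        )
    except KeyError as exc:
        raise ValueError(f"assignment missing node {exc.args[0]!r}") from exc
    return case_labels, gene_labels


def modularity(
    network: BipartiteNetwork,
    case_labels: np.ndarray | Mapping[str, int],
    gene_labels: np.ndarray | None = None,
) -> float:
    """Weighted Barber bipartite modularity of a joint partition.

    Accepts either two label arrays aligned to the network orderings, or a
    single ``{"case:<id>"/"gene:<id>": label}`` mapping covering every node.
    """
    if gene_labels is None:
        case_labels, gene_labels = _labels_from_mapping(network, case_labels)  # type: ignore[arg-type]
    case_labels = np.asarray(case_labels, dtype=int)
    gene_labels = np.asarray(gene_labels, dtype=int)
    if case_labels.shape != (network.n_cases,) or gene_labels.shape != (
        network.n_genes,
    ):
        raise ValueError("label arrays do not match network dimensions")
    return _modularity_arrays(
        network.weights,
        network.case_strengths,
        network.gene_strengths,
        network.m,
        case_labels,
        gene_labels,
    )


def _modularity_arrays(
    weights: np.ndarray,
    s: np.ndarray,
    t: np.ndarray,
    m: float,
    case_labels: np.ndarray,
    gene_labels: np.ndarray,
) -> float:
    labels = np.union1d(case_labels, gene_labels)
    q = 0.0
    for lab in labels:
        rows = case_labels == lab
        cols = gene_labels == lab
        w_c = weights[np.ix_(rows, cols)].sum()
        q += w_c / m - (s[rows].sum() * t[cols].sum()) / m**2
    return float(q)


# -- optimizer --------------------------------------------------------------------


def _compact(case_labels: np.ndarray, gene_labels: np.ndarray) -> int:
    """Relabel in place to 0..K-1 (order of first appearance, cases then genes)."""
    combined = np.concatenate([case_labels, gene_labels])
    uniq, inv = np.unique(combined, return_inverse=True)
    # np.unique sorts; remap to order of first appearance for determinism
    first = {u: np.argmax(combined == u) for u in uniq}
    order = np.argsort([first[u] for u in uniq], kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    relab = rank[inv]
    case_labels[:] = relab[: len(case_labels)]
    gene_labels[:] = relab[len(case_labels):]
    return len(uniq)


def _one_sided_assign(
    within: np.ndarray, strengths: np.ndarray, other_totals: np.ndarray, m: float
) -> np.ndarray:
    """Optimal cluster per node on one side, the other side fixed.

    ``within[v, c]`` is node v's edge weight into cluster c's other-side nodes;
    score = within - strengths * other_totals / m. A trailing zero column
    stands for moving into a cluster with no other-side members (contribution
    exactly 0, same as a singleton). argmax breaks ties toward the lowest
    cluster label.
    """
    scores = within - np.outer(strengths, other_totals) / m
    scores = np.hstack([scores, np.zeros((scores.shape[0], 1))])
    return np.argmax(scores, axis=1)


def _brim_sweeps(
    weights: np.ndarray,
    s: np.ndarray,
    t: np.ndarray,
    m: float,
    case_labels: np.ndarray,
    gene_labels: np.ndarray,
) -> float:
    """Alternate one-sided optimal reassignments until Q stops improving."""
    k = _compact(case_labels, gene_labels)
    q = _modularity_cluster_sums(weights, s, t, m, case_labels, gene_labels, k)
    for _ in range(_MAX_SWEEPS):
        # genes, given case labels (labels may exceed k via the empty-cluster move)
        k_c = int(max(case_labels.max(), gene_labels.max())) + 1
        cmat = np.zeros((len(case_labels), k_c))
        cmat[np.arange(len(case_labels)), case_labels] = 1.0
        gene_labels[:] = _one_sided_assign(weights.T @ cmat, t, s @ cmat, m)
        # cases, given gene labels
        k_g = int(max(case_labels.max(), gene_labels.max())) + 1
        gmat = np.zeros((len(gene_labels), k_g))
        gmat[np.arange(len(gene_labels)), gene_labels] = 1.0
        case_labels[:] = _one_sided_assign(weights @ gmat, s, t @ gmat, m)
        k = _compact(case_labels, gene_labels)
        q_new = _modularity_cluster_sums(weights, s, t, m, case_labels, gene_labels, k)
        if q_new <= q + _Q_TOL:
            q = max(q, q_new)
            break
        q = q_new
    return q


def _modularity_cluster_sums(
    weights: np.ndarray,
    s: np.ndarray,
    t: np.ndarray,
    m: float,
    case_labels: np.ndarray,
    gene_labels: np.ndarray,
    k: int,
) -> float:
    cmat = np.zeros((len(case_labels), k))
    cmat[np.arange(len(case_labels)), case_labels] = 1.0
    gmat = np.zeros((len(gene_labels), k))
    gmat[np.arange(len(gene_labels)), gene_labels] = 1.0
    within = np.einsum("ic,ij,jc->c", cmat, weights, gmat)
    s_c = s @ cmat
    t_c = t @ gmat
    return float(np.sum(within / m - s_c * t_c / m**2))


def _merge_phase(
    weights: np.ndarray,
    s: np.ndarray,
    t: np.ndarray,
    m: float,
    case_labels: np.ndarray,
    gene_labels: np.ndarray,
) -> bool:
    """Greedily merge cluster pairs while any merge increases Q."""
    improved = False
    while True:
        k = _compact(case_labels, gene_labels)
        if k < 2:
            return improved
        cmat = np.zeros((len(case_labels), k))
        cmat[np.arange(len(case_labels)), case_labels] = 1.0
        gmat = np.zeros((len(gene_labels), k))
        gmat[np.arange(len(gene_labels)), gene_labels] = 1.0
        blocks = cmat.T @ weights @ gmat  # blocks[a, b]: cases in a -> genes in b
        s_c = s @ cmat
        t_c = t @ gmat
        # dQ of merging a and b: cross within-weight minus cross null terms
        cross_null = np.outer(s_c, t_c)
        dq = (blocks + blocks.T) / m - (cross_null + cross_null.T) / m**2
        np.fill_diagonal(dq, -np.inf)
        a, b = np.unravel_index(np.argmax(dq), dq.shape)
        if dq[a, b] <= _Q_TOL:
            return improved
        lo, hi = min(a, b), max(a, b)
        case_labels[case_labels == hi] = lo
        gene_labels[gene_labels == hi] = lo
        improved = True


def maximize_modularity(
    network: BipartiteNetwork,
    seed: int = 0,
    n_restarts: int = 20,
) -> BiclusterSolution:
    """Best-of-restarts search for the maximum-modularity joint partition.

    Restart 0 starts from the all-singleton case partition (each case its own
    cluster); subsequent restarts draw a random case partition from a child of
    the seed's SeedSequence, so the best Q over the first r restarts is
    non-decreasing in r. Never returns below the single-cluster baseline Q = 0.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    weights = network.weights
    s = network.case_strengths
    t = network.gene_strengths
    m = network.m
    if m <= 0:
        raise ValueError("network has zero total weight")
    n, d = weights.shape

    children = np.random.SeedSequence(seed).spawn(max(n_restarts - 1, 0))
    best_q = -np.inf
    best: tuple[np.ndarray, np.ndarray] | None = None
    for restart in range(n_restarts):
        if restart == 0:
            case_labels = np.arange(n)
        else:
            rng = np.random.default_rng(children[restart - 1])
            k0 = int(rng.integers(1, n + 1))
            case_labels = rng.integers(0, k0, size=n)
        gene_labels = np.zeros(d, dtype=int)
        case_labels = case_labels.astype(int)
        q = _brim_sweeps(weights, s, t, m, case_labels, gene_labels)
        while _merge_phase(weights, s, t, m, case_labels, gene_labels):
            q = _brim_sweeps(weights, s, t, m, case_labels, gene_labels)
        k = _compact(case_labels, gene_labels)
        q = _modularity_cluster_sums(weights, s, t, m, case_labels, gene_labels, k)
        if q > best_q + _Q_TOL:
            best_q = q
            best = (case_labels.copy(), gene_labels.copy())

    assert best is not None
    case_labels, gene_labels = best
    if best_q < 0.0:  # single-cluster baseline dominates
        case_labels = np.zeros(n, dtype=int)
        gene_labels = np.zeros(d, dtype=int)
        best_q = 0.0
    _compact(case_labels, gene_labels)
    case_labels += 1  # 1-based contiguous labels
    gene_labels += 1
    k = int(max(case_labels.max(), gene_labels.max()))
    single_sided = [
        c
        for c in range(1, k + 1)
        if not (np.any(case_labels == c) and np.any(gene_labels == c))
    ]
    return BiclusterSolution(
        case_ids=list(network.case_ids),
        gene_ids=list(network.gene_ids),
        case_labels=case_labels,
        gene_labels=gene_labels,
        q=float(best_q),
        single_sided=single_sided,
    )
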