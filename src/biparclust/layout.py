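"""Bipartite network visualization: force-directed layout, cluster explosion,
significance arrows.

``fruchterman_reingold`` is a standard force simulation (weighted attraction
d^2/k along edges, repulsion k^2/d between all node pairs, linear cooling).
``explode_layout`` then rigidly translates each bicluster so cluster
centroids sit on a circle, keeping within-cluster geometry intact — the
radial separation idea behind exploded network views. ``render`` draws cases
as circles colored by phenotype, genes as triangles, edge opacity scaled by
weight, and an arrow between every cluster pair whose Bonferroni-corrected
layer-profile difference is significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .bipartite import BipartiteNetwork, BiclusterSolution
from .io_metadata import SampleMetadata

PHENOTYPE_COLORS = {
    "TNIL": "#7fb8e6",
    "TIL": "#d62728",
    "PTB": "#e6b800",
    "PPROM": "#1f3f9e",
}


@dataclass
class Layout:
    """Node coordinates plus per-cluster centroids."""

    coordinates: dict[str, tuple[float, float]]
    cluster_centroids: dict[int, tuple[float, float]]
    explode_radius: float = 0.0

    def positions(self, node_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.coordinates[n] for n in node_ids])


def _node_names(network: BipartiteNetwork) -> list[str]:
    return [f"case:{c}" for c in network.case_ids] + [
        f"gene:{g}" for g in network.gene_ids
    ]


def fruchterman_reingold(
    network: BipartiteNetwork,
    iterations: int = 100,
    seed: int = 0,
    k: float | None = None,
) -> Layout:
    """Force-directed layout of the bipartite graph; deterministic at fixed seed.

    ``k`` is the ideal pairwise spacing (default sqrt(area / n_nodes) with unit
    area). Attraction acts along weighted edges with force w * d^2 / k;
    repulsion k^2 / d acts between every node pair; displacement per sweep is
    capped by a linearly cooling temperature.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    n_total = network.n_cases + network.n_genes
    if k is None:
        k = float(np.sqrt(1.0 / n_total))
    rng = np.random.default_rng(seed)
    pos = rng.random((n_total, 2)) - 0.5

    # symmetric weight matrix over the joint node ordering (cases then genes)
    w = network.weights / max(network.weights.max(), 1e-300)
    temperature = 0.1
    cooling = temperature / (iterations + 1)
    for _ in range(iterations):
        delta = pos[:, None, :] - pos[None, :, :]
        dist = np.linalg.norm(delta, axis=-1)
        np.fill_diagonal(dist, 1.0)
        dist = np.maximum(dist, 1e-9)
        # repulsion between all pairs
        force = (k * k) / (dist * dist)
        # attraction along case-gene edges (both blocks of the bipartite matrix)
        attract = np.zeros_like(force)
        attract[: network.n_cases, network.n_cases:] = w * dist[
            : network.n_cases, network.n_cases:
        ] / k
        attract[network.n_cases:, : network.n_cases] = attract[
            : network.n_cases, network.n_cases:
        ].T
        force -= attract
        displacement = (delta * force[..., None]).sum(axis=1)
        length = np.maximum(np.linalg.norm(displacement, axis=-1, keepdims=True), 1e-9)
        pos += displacement / length * np.minimum(length, temperature)
        temperature -= cooling
    names = _node_names(network)
    coords = {name: (float(x), float(y)) for name, (x, y) in zip(names, pos)}
    return Layout(coordinates=coords, cluster_centroids={})


def _centroids(
    layout: Layout, solution: BiclusterSolution
) -> dict[int, np.ndarray]:
    members: dict[int, list[str]] = {}
    for cid, lab in zip(solution.case_ids, solution.case_labels):
        members.setdefault(int(lab), []).append(f"case:{cid}")
    for gid, lab in zip(solution.gene_ids, solution.gene_labels):
        members.setdefault(int(lab), []).append(f"gene:{gid}")
    return {
        c: np.mean([layout.coordinates[n] for n in nodes], axis=0)
        for c, nodes in sorted(members.items())
    }


def explode_layout(
    layout: Layout, solution: BiclusterSolution, radius: float
) -> Layout:
    """Rigidly translate each cluster so centroids sit evenly on a circle.

    Cluster label order fixes the angular order (cluster 1 at angle 0, then
    counterclockwise). Within-cluster distances are preserved exactly.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    centroids = _centroids(layout, solution)
    labels = sorted(centroids)
    k = len(labels)
    new_coords = dict(layout.coordinates)
    new_centroids: dict[int, tuple[float, float]] = {}
    label_of = {
        f"case:{c}": int(l) for c, l in zip(solution.case_ids, solution.case_labels)
    }
    label_of.update(
        {f"gene:{g}": int(l) for g, l in zip(solution.gene_ids, solution.gene_labels)}
    )
    targets = {
        lab: radius * np.array([np.cos(2 * np.pi * i / k), np.sin(2 * np.pi * i / k)])
        for i, lab in enumerate(labels)
    }
    shifts = {lab: targets[lab] - centroids[lab] for lab in labels}
    for node, (x, y) in layout.coordinates.items():
        if node not in label_of:
            raise ValueError(f"laid-out node {node!r} has no cluster assignment")
        dx, dy = shifts[label_of[node]]
        new_coords[node] = (float(x + dx), float(y + dy))
    for lab in labels:
        new_centroids[lab] = (float(targets[lab][0]), float(targets[lab][1]))
    return Layout(
        coordinates=new_coords,
        cluster_centroids=new_centroids,
        explode_radius=float(radius),
    )


def render(
    layout: Layout,
    network: BipartiteNetwork,
    solution: BiclusterSolution,
    enrichment: pd.DataFrame,
    records: Sequence[SampleMetadata],
    out_path: str | Path,
    edge_quantile: float = 0.5,
) -> Path:
    """Write an SVG (or PNG) of the exploded bipartite network.

    Only edges at or above the ``edge_quantile`` weight quantile are drawn to
    keep dense networks readable. Every enrichment row with ``significant``
    True gets an arrow between the two cluster centroids, tagged with an SVG
    gid ``sig-arrow-<i>-<j>`` so renders are machine-checkable. Output is
    byte-stable for identical inputs.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import FancyArrowPatch

    out_path = Path(out_path)
    pheno_of = {r.sample_id: r.phenotype for r in records}
    fig, ax = plt.subplots(figsize=(8, 8))
    ax.set_aspect("equal")
    ax.axis("off")

    case_pos = layout.positions([f"case:{c}" for c in network.case_ids])
    gene_pos = layout.positions([f"gene:{g}" for g in network.gene_ids])
    w = network.weights
    w_max = w.max() if w.max() > 0 else 1.0
    threshold = float(np.quantile(w[w > 0], edge_quantile)) if np.any(w > 0) else 0.0
    edge_idx = np.argwhere(w >= threshold)
    for i, j in edge_idx:
        ax.plot(
            [case_pos[i, 0], gene_pos[j, 0]],
            [case_pos[i, 1], gene_pos[j, 1]],
            color="0.5",
            alpha=float(0.05 + 0.25 * w[i, j] / w_max),
            linewidth=0.3,
            zorder=1,
        )
    colors = [PHENOTYPE_COLORS.get(pheno_of.get(c, ""), "0.3") for c in network.case_ids]
    ax.scatter(
        case_pos[:, 0], case_pos[:, 1], s=60, c=colors, marker="o",
        edgecolors="black", linewidths=0.5, zorder=3, label="cases",
    )
    ax.scatter(
        gene_pos[:, 0], gene_pos[:, 1], s=18, c="0.35", marker="^",
        zorder=2, label="genes",
    )
    for _, row in enrichment.iterrows():
        if not bool(row["significant"]):
            continue
        a, b = int(row["Cluster_i"]), int(row["Cluster_j"])
        if a not in layout.cluster_centroids or b not in layout.cluster_centroids:
            continue
        arrow = FancyArrowPatch(
            layout.cluster_centroids[a],
            layout.cluster_centroids[b],
            arrowstyle="<->",
            color="red",
            mutation_scale=15,
            linewidth=1.5,
            zorder=4,
        )
        arrow.set_gid(f"sig-arrow-{a}-{b}")
        ax.add_patch(arrow)
    for lab, (x, y) in layout.cluster_centroids.items():
        ax.annotate(
            f"cluster {lab}", (x, y), fontsize=11, fontweight="bold",
            ha="center", va="bottom", zorder=5,
        )
    with matplotlib.rc_context({"svg.hashsalt": "biparclust"}):
        fig.savefig(out_path, format=out_path.suffix.lstrip("."), metadata=_stable_metadata(out_path))
    plt.close(fig)
    return out_path


def _stable_metadata(out_path: Path) -> dict | None:
    if out_path.suffix.lower() == ".svg":
        return {"Date": None, "Creator": None}
    return None


def count_significance_arrows(svg_path: str | Path) -> int:
    """Count the significance arrows a rendered SVG contains (by gid)."""
    text = Path(svg_path).read_text()
    return text.count('id="sig-arrow-')
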