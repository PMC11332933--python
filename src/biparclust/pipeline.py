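"""End-to-end orchestration: feature selection through enrichment and figures.

``run_all`` executes the whole analysis in order — log2/CV feature selection,
case/control split, bipartite network construction, modularity maximization,
permutation significance, layer-profile enrichment, control-inclusive
hierarchical clustering, and the exploded network figure — writing every
artifact plus a reproducibility manifest into one run directory. All
randomness flows from the single top-level seed through named child streams,
so a rerun with the manifest's config reproduces every numeric output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bipartite import build_network, maximize_modularity
from .enrichment import (
    ENRICHMENT_COLUMNS,
    cluster_profiles,
    pairwise_enrichment,
    profiles_frame,
)
from .hierclust import hierarchical_cluster
from .io_metadata import (
    ExpressionMatrix,
    SampleMetadata,
    read_matrix,
    read_metadata,
    split_cases_controls,
    validate_joint,
)
from .layout import explode_layout, fruchterman_reingold, render
from .preprocess import gene_cv, log2_transform, select_top_cv
from .significance import modularity_significance

logger = logging.getLogger("biparclust")


@dataclass
class PipelineConfig:
    """Everything a full run needs; defaults follow the published protocol."""

    matrix: str
    metadata: str
    outdir: str
    fraction: float = 0.10
    floor: float = 1.0
    restarts: int = 20
    n_perms: int = 1000
    seed: int = 0
    alpha: float = 0.05
    cv_cases_only: bool = False
    rescore_fixed_partition: bool = False
    fr_iterations: int = 100
    explode_radius: float = 1.0
    edge_quantile: float = 0.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _child_seed(seed: int, stream: str) -> int:
    """Deterministic per-stage seed derived from the top-level seed."""
    digest = hashlib.sha256(f"{seed}:{stream}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _setup_logging(outdir: Path) -> None:
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for handler in (
        logging.StreamHandler(sys.stderr),
        logging.FileHandler(outdir / "run.log"),
    ):
        handler.setFormatter(fmt)
        logger.addHandler(handler)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


def run_all(
    config: PipelineConfig,
    matrix: ExpressionMatrix | None = None,
    records: list[SampleMetadata] | None = None,
) -> Path:
    """Run the full pipeline; returns the run directory.

    ``matrix``/``records`` may be passed in memory (e.g. fresh from the
    synthetic generator); otherwise they are read from the configured paths.
    On a stage failure, partial outputs are kept and a ``<stage>.failed``
    marker is written.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    stage = "load"
    t0 = time.time()
    try:
        if matrix is None:
            matrix = read_matrix(config.matrix)
        if records is None:
            records = read_metadata(config.metadata)
        validate_joint(matrix, records)
        logger.info(
            "load: %d genes x %d samples, seed=%d", matrix.n_genes,
            matrix.n_samples, config.seed,
        )

        stage = "feature_selection"
        log2_all = log2_transform(matrix, floor=config.floor)
        cases, _controls = split_cases_controls(matrix, records)
        cv_input = log2_transform(cases, config.floor) if config.cv_cases_only else log2_all
        stats = gene_cv(cv_input)
        selected = select_top_cv(stats, fraction=config.fraction)
        stats.to_csv(outdir / "gene_stats.csv", index=False, float_format="%.10g")
        (outdir / "genes.txt").write_text("\n".join(selected) + "\n")
        logger.info("feature_selection: %d of %d genes", len(selected), matrix.n_genes)

        stage = "network"
        network = build_network(cases, selected, floor=config.floor)
        logger.info("network: %d cases x %d genes, m=%.4g",
                    network.n_cases, network.n_genes, network.m)

        stage = "biclustering"
        solution = maximize_modularity(
            network, seed=_child_seed(config.seed, "maximize"),
            n_restarts=config.restarts,
        )
        solution.to_json(outdir / "solution.json")
        logger.info("biclustering: %d clusters, Q=%.6f", solution.n_clusters, solution.q)

        stage = "significance"
        perm = modularity_significance(
            network,
            n_perms=config.n_perms,
            seed=_child_seed(config.seed, "significance"),
            n_restarts=config.restarts,
            rescore_fixed_partition=config.rescore_fixed_partition,
            solution=solution,
        )
        perm.to_json(outdir / "perm.json", perm_sidecar=outdir / "q_perm.csv")
        logger.info(
            "significance: Q_real=%.6f Q_random=%.6f z=%.2f p_emp=%.4g",
            perm.q_real, perm.q_random_mean, perm.z, perm.p_empirical,
        )

        stage = "enrichment"
        profiles = cluster_profiles(solution, records)
        profiles_frame(profiles).to_csv(outdir / "profiles.csv", index=False)
        if sum(p.n_cases > 0 for p in profiles) >= 2:
            table = pairwise_enrichment(profiles, alpha=config.alpha)
        else:
            logger.warning("enrichment skipped: fewer than 2 clusters hold cases")
            table = pd.DataFrame(columns=ENRICHMENT_COLUMNS)
        table.to_csv(outdir / "table1.csv", index=False, float_format="%.10g")
        logger.info("enrichment: %d pairs, %d significant",
                    len(table), int(table["significant"].sum()) if len(table) else 0)

        stage = "hierarchical"
        dendro = hierarchical_cluster(log2_all.subset_genes(selected), axis="samples")
        dendro.to_json(outdir / "dendro.json")
        (outdir / "dendro.nwk").write_text(dendro.to_newick() + "\n")

        stage = "figure"
        base = fruchterman_reingold(
            network, iterations=config.fr_iterations,
            seed=_child_seed(config.seed, "layout"),
        )
        exploded = explode_layout(base, solution, radius=config.explode_radius)
        render(exploded, network, solution, table, records,
               outdir / "fig.svg", edge_quantile=config.edge_quantile)

        stage = "manifest"
        manifest = {
            "package": "biparclust",
            "version": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "seed": config.seed,
            "config": asdict(config),
            "config_hash": config.config_hash(),
            "elapsed_s": round(time.time() - t0, 3),
            "artifacts": sorted(
                p.name for p in outdir.iterdir() if p.is_file() and p.suffix != ".log"
            ),
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True) + "\n"
        )
    except Exception as exc:
        (outdir / f"{stage}.failed").write_text(f"{type(exc).__name__}: {exc}\n")
        raise StageError(f"stage {stage!r} failed: {exc}") from exc
    logger.info("done in %.1fs -> %s", time.time() - t0, outdir)
    return outdir
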