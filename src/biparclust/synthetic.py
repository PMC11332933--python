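"""Synthetic GeoMx-like ROI x gene matrices with planted bicluster structure.

The generator emulates the study design this pipeline targets: 13 patients
across four phenotypes (TNIL n=4, TIL n=3, PTB n=3, PPROM n=3), one ROI per
patient x tissue layer (AEC, AMC, CTC, DEC), and four planted expression
programs mirroring the published cluster pattern — decidua genes active in
all labor phenotypes, amnion-epithelium genes in PPROM/PTB, chorion-
trophoblast genes in all labor phenotypes, and AMC+CTC genes in term labor.

Counts are negative-binomial around 2^(baseline + patient intercept +
planted effect), scaled to a common library size and rounded, standing in
for platform-normalized counts. A QC-dropout parameter removes ROIs at
random; :func:`study_shaped` instead drops 3 case and 5 control ROIs so the
surviving bookkeeping matches the published 44 samples = 33 cases + 11
controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .bipartite import BiclusterSolution
from .io_metadata import (
    CASE_PHENOTYPES,
    LAYERS,
    PHENOTYPES,
    ExpressionMatrix,
    SampleMetadata,
    validate_metadata,
)


@dataclass(frozen=True)
class PlantedProgram:
    """One planted expression program: which genes light up in which ROIs."""

    gene_fraction: float
    target_layers: frozenset[str]
    target_phenotypes: frozenset[str]
    log2_effect: float

    def targets(self, layer: str, phenotype: str) -> bool:
        return layer in self.target_layers and phenotype in self.target_phenotypes


def _default_programs(log2_effect: float = 4.0) -> list[PlantedProgram]:
    mk = lambda layers, phenos: PlantedProgram(  # noqa: E731
        gene_fraction=0.025,
        target_layers=frozenset(layers),
        target_phenotypes=frozenset(phenos),
        log2_effect=log2_effect,
    )
    return [
        mk({"DEC"}, CASE_PHENOTYPES),          # decidua, all labor phenotypes
        mk({"AEC"}, {"PPROM", "PTB"}),         # amnion epithelium, preterm
        mk({"CTC"}, CASE_PHENOTYPES),          # chorion trophoblast, all phenotypes
        mk({"AMC", "CTC"}, {"TIL"}),           # mesenchyme + trophoblast, term labor
    ]


@dataclass
class GeneratorConfig:
    """Study-shaped defaults, scaled down to 1,000 genes for fast pipelines."""

    n_patients_per_phenotype: dict[str, int] = field(
        default_factory=lambda: {"TNIL": 4, "TIL": 3, "PTB": 3, "PPROM": 3}
    )
    n_genes: int = 1000
    planted_programs: list[PlantedProgram] = field(default_factory=_default_programs)
    nb_dispersion: float = 10.0  # NB size parameter r; var = mu + mu^2 / r
    baseline_log2_mean: float = 6.0
    patient_log2_sd: float = 0.3
    qc_dropout: int = 8  # 52 ROIs generated -> 44 surviving
    seed: int = 0

    def validate(self) -> None:
        if set(self.n_patients_per_phenotype) - set(PHENOTYPES):
            raise ValueError(
                f"unknown phenotypes {set(self.n_patients_per_phenotype) - set(PHENOTYPES)}"
            )
        total_fraction = sum(p.gene_fraction for p in self.planted_programs)
        if total_fraction > 1.0 + 1e-12:
            raise ValueError(f"planted gene fractions sum to {total_fraction} > 1")
        for p in self.planted_programs:
            if not np.isfinite(p.log2_effect):
                raise ValueError("non-finite planted effect")
            if set(p.target_layers) - set(LAYERS):
                raise ValueError(f"unknown target layers {p.target_layers}")
            if set(p.target_phenotypes) - set(PHENOTYPES):
                raise ValueError(f"unknown target phenotypes {p.target_phenotypes}")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        n_rois = 4 * sum(self.n_patients_per_phenotype.values())
        if not 0 <= self.qc_dropout < n_rois:
            raise ValueError(f"qc_dropout must be in [0, {n_rois})")


def default_config(seed: int = 0, **overrides) -> GeneratorConfig:
    return replace(GeneratorConfig(seed=seed), **overrides)


def null_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Zero-effect configuration: same shape, no planted structure."""
    cfg = GeneratorConfig(seed=seed, planted_programs=[], **overrides)
    return cfg


def full_shape_config(seed: int = 0) -> GeneratorConfig:
    """The full published shape: 11,921 genes across the 52-ROI design."""
    return GeneratorConfig(seed=seed, n_genes=11921)


def _make_metadata(config: GeneratorConfig) -> list[SampleMetadata]:
    records = []
    for pheno in PHENOTYPES:
        for i in range(config.n_patients_per_phenotype.get(pheno, 0)):
            patient = f"{pheno}{i + 1}"
            for layer in LAYERS:
                records.append(
                    SampleMetadata(
                        sample_id=f"{patient}_{layer}",
                        patient_id=patient,
                        phenotype=pheno,
                        layer=layer,
                    )
                )
    validate_metadata(records)
    return records


def generate(
    config: GeneratorConfig,
) -> tuple[ExpressionMatrix, list[SampleMetadata], dict]:
    """Draw one synthetic dataset.

    Returns the normalized count matrix (genes x ROIs), the ROI metadata, and
    a truth dict with ``gene_program`` (gene_id -> program index, -1 for
    background) and ``programs`` (per-program target description).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    records = _make_metadata(config)
    n_samples = len(records)
    n_genes = config.n_genes

    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    gene_program = np.full(n_genes, -1, dtype=int)
    cursor = 0
    for k, prog in enumerate(config.planted_programs):
        n_prog = int(round(prog.gene_fraction * n_genes))
        gene_program[cursor : cursor + n_prog] = k
        cursor += n_prog

    patients = sorted({r.patient_id for r in records})
    intercepts = dict(
        zip(patients, rng.normal(0.0, config.patient_log2_sd, size=len(patients)))
    )
    log2_mu = np.full((n_genes, n_samples), config.baseline_log2_mean)
    for j, rec in enumerate(records):
        log2_mu[:, j] += intercepts[rec.patient_id]
        for k, prog in enumerate(config.planted_programs):
            if prog.targets(rec.layer, rec.phenotype):
                log2_mu[gene_program == k, j] += prog.log2_effect

    mu = 2.0 ** log2_mu
    r = config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu)).astype(float)

    # scale to a common library size, then round back to integer counts
    totals = counts.sum(axis=0)
    target = totals.mean()
    if np.any(totals == 0):
        raise RuntimeError("degenerate draw: an ROI with zero total counts")
    counts = np.rint(counts * (target / totals))

    if config.qc_dropout:
        drop = set(rng.choice(n_samples, size=config.qc_dropout, replace=False))
        keep = [j for j in range(n_samples) if j not in drop]
        counts = counts[:, keep]
        records = [records[j] for j in keep]

    matrix = ExpressionMatrix(counts, gene_ids, [r.sample_id for r in records])
    truth = {
        "gene_program": {g: int(p) for g, p in zip(gene_ids, gene_program)},
        "programs": [
            {
                "index": k,
                "target_layers": sorted(p.target_layers),
                "target_phenotypes": sorted(p.target_phenotypes),
                "log2_effect": p.log2_effect,
                "n_genes": int(np.sum(gene_program == k)),
            }
            for k, p in enumerate(config.planted_programs)
        ],
    }
    return matrix, records, truth


def study_shaped(
    seed: int = 0, **overrides
) -> tuple[ExpressionMatrix, list[SampleMetadata], dict]:
    """Generate with stratified QC dropout reproducing 44 samples = 33 cases + 11 TNIL.

    Uniform dropout cannot guarantee the published case/control split, so this
    helper removes 3 case ROIs and 5 TNIL ROIs at random instead.
    """
    config = default_config(seed=seed, qc_dropout=0, **overrides)
    matrix, records, truth = generate(config)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    case_idx = [j for j, r in enumerate(records) if r.is_case]
    control_idx = [j for j, r in enumerate(records) if not r.is_case]
    drop = set(rng.choice(case_idx, size=3, replace=False)) | set(
        rng.choice(control_idx, size=5, replace=False)
    )
    keep = [j for j in range(len(records)) if j not in drop]
    matrix = matrix.subset_samples([records[j].sample_id for j in keep])
    records = [records[j] for j in keep]
    return matrix, records, truth


def worked_toy() -> tuple[ExpressionMatrix, list[SampleMetadata]]:
    """Deterministic 8-case x 12-gene fixture with two exactly disjoint blocks.

    Cases C1-C4 connect only to genes TG01-TG06 (count 4, weight 2) and cases
    C5-C8 only to TG07-TG12; off-block counts are 1 (weight 0 after flooring).
    Both blocks carry equal weight, so the block partition has the closed-form
    modularity Q = 1 - 1/2 = 1/2 and is the unique optimum. Block-A cases are
    all decidua ROIs, block-B all amnion epithelium, giving a maximally
    contrasting layer profile for enrichment examples.
    """
    n_cases, n_genes = 8, 12
    counts = np.ones((n_genes, n_cases))
    counts[:6, :4] = 4.0
    counts[6:, 4:] = 4.0
    case_ids = [f"C{i + 1}" for i in range(n_cases)]
    gene_ids = [f"TG{j + 1:02d}" for j in range(n_genes)]
    phenos = ["TIL", "PTB", "PPROM", "TIL", "PTB", "PPROM", "TIL", "PTB"]
    layers = ["DEC"] * 4 + ["AEC"] * 4
    records = [
        SampleMetadata(
            sample_id=cid, patient_id=f"T{i + 1}", phenotype=phenos[i], layer=layers[i]
        )
        for i, cid in enumerate(case_ids)
    ]
    return ExpressionMatrix(counts, gene_ids, case_ids), records


def recovery_ari(
    solution: BiclusterSolution, truth: dict, selected_genes: Sequence[str] | None = None
) -> float:
    """Adjusted Rand Index between recovered gene clusters and planted programs.

    Scored on the gene side only (case ROIs can sit in two overlapping
    programs, so a case-side truth partition is ill-defined), restricted to
    planted genes present in the solution (i.e. surviving feature selection).
    """
    from sklearn.metrics import adjusted_rand_score

    gene_program = truth["gene_program"]
    labels_true = []
    labels_pred = []
    selected = set(selected_genes) if selected_genes is not None else None
    for gid, lab in zip(solution.gene_ids, solution.gene_labels):
        prog = gene_program.get(gid, -1)
        if prog < 0:
            continue
        if selected is not None and gid not in selected:
            continue
        labels_true.append(prog)
        labels_pred.append(int(lab))
    if len(set(labels_true)) < 2:
        raise ValueError("fewer than two planted programs present in the solution")
    return float(adjusted_rand_score(labels_true, labels_pred))
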