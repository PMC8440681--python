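"""Negative-binomial scRNA-seq simulator with planted structure.

Generates multi-cluster UMI counts for two conditions with cluster marker
genes, optional condition-specific mean shifts in one or more clusters,
organelle (mitochondrial/ribosomal) genes with a per-cell load, and an
injectable fraction of QC-failing outlier cells.  Ground truth is emitted
alongside the counts for parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .embed import Embedding
from .errors import ValidationError
from .io import CountMatrix


@dataclass(frozen=True)
class ClusterSpec:
    name: str
    proportion: float
    base_scale: float = 1.0  # multiplies the library-size target


@dataclass(frozen=True)
class ShiftSpec:
    """Condition perturbation planted in one cluster's case cells."""

    n_genes: int = 0
    fold: float = 1.0  # linear fold applied to shifted genes in case cells

    def __post_init__(self):
        if self.fold < 1:
            raise ValidationError("shift fold must be >= 1")
        if self.n_genes < 0:
            raise ValidationError("n_shift_genes must be >= 0")


@dataclass(frozen=True)
class OrganelleSpec:
    """Organelle gene block: fraction of the gene universe flagged MT-/RPS
    and the Beta-distributed per-cell share of UMIs they receive."""

    gene_fraction: float = 0.1
    load_mean: float = 0.03
    load_concentration: float = 200.0
    # lower bound 0.2: even a 50/50 mito/ribo split then exceeds 7% each
    outlier_load_range: tuple[float, float] = (0.20, 0.40)

    def __post_init__(self):
        if not (0 <= self.gene_fraction < 1):
            raise ValidationError("organelle gene_fraction must lie in [0, 1)")
        if not (0 < self.load_mean < 1):
            raise ValidationError("organelle load_mean must lie in (0, 1)")


def _default_clusters() -> tuple[ClusterSpec, ...]:
    return (
        ClusterSpec("A", 0.4),
        ClusterSpec("B", 0.35),
        ClusterSpec("C", 0.25),
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Full generative recipe; every draw is determined by ``seed``."""

    n_genes: int = 300
    n_cells_per_condition: int = 600
    clusters: tuple[ClusterSpec, ...] = field(default_factory=_default_clusters)
    de_genes_per_cluster: int = 10
    marker_fold: float = 4.0
    shift: dict[str, ShiftSpec] = field(default_factory=dict)
    dispersion: float = 2.0  # NB size; var = mu + mu^2/size
    library_mean_log: float = math.log(2000.0)
    library_sd_log: float = 0.2
    organelle: OrganelleSpec = field(default_factory=OrganelleSpec)
    outlier_fraction: float = 0.0
    case_proportions: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self):
        if abs(sum(c.proportion for c in self.clusters) - 1.0) > 1e-8:
            raise ValidationError("cluster proportions must sum to 1")
        names = [c.name for c in self.clusters]
        if len(set(names)) != len(names):
            raise ValidationError("cluster names must be unique")
        if self.marker_fold < 1:
            raise ValidationError("marker_fold must be >= 1")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be positive")
        if not (0 <= self.outlier_fraction <= 1):
            raise ValidationError("outlier_fraction must lie in [0, 1]")
        unknown = set(self.shift) - set(names)
        if unknown:
            raise ValidationError(f"shift targets unknown clusters: {sorted(unknown)}")
        if self.case_proportions is not None:
            if set(self.case_proportions) != set(names):
                raise ValidationError("case_proportions must cover every cluster")
            if abs(sum(self.case_proportions.values()) - 1.0) > 1e-8:
                raise ValidationError("case_proportions must sum to 1")
        n_org = round(self.organelle.gene_fraction * self.n_genes)
        n_regular = self.n_genes - n_org
        needed = len(self.clusters) * self.de_genes_per_cluster + sum(
            s.n_genes for s in self.shift.values()
        )
        if needed > n_regular:
            raise ValidationError(
                f"marker + shift genes ({needed}) exceed the {n_regular} "
                "non-organelle genes available"
            )


@dataclass
class SyntheticTruth:
    """Ground truth: per-cell assignments and per-gene planted roles."""

    cells: pd.DataFrame  # barcode, cluster, condition, qc_outlier
    genes: pd.DataFrame  # gene_id, gene_symbol, marker_of, shifted_in, is_organelle


def _partition_counts(n: int, proportions: list[float]) -> list[int]:
    """Largest-remainder apportionment of n cells over cluster proportions."""
    raw = [p * n for p in proportions]
    base = [int(math.floor(r)) for r in raw]
    short = n - sum(base)
    order = np.argsort([b - r for b, r in zip(base, raw)], kind="stable")
    for i in order[:short]:
        base[i] += 1
    return base


def generate_dataset(spec: SyntheticSpec) -> tuple[CountMatrix, pd.DataFrame, SyntheticTruth]:
    """Draw a dataset from the spec.

    Counts follow NB(mean = library x cluster/condition gene weights,
    size = dispersion); the condition shift multiplies the designated
    cluster's shift genes in case cells only.  Outlier cells receive an
    organelle load above the QC ceiling.  Same seed, same bytes.
    """
    rng = np.random.default_rng(spec.seed)
    n_org = round(spec.organelle.gene_fraction * spec.n_genes)
    n_regular = spec.n_genes - n_org
    n_mt = n_org // 2
    n_ribo = n_org - n_mt

    gene_ids = [f"G{i + 1:06d}" for i in range(n_regular)]
    gene_ids += [f"MT-{i + 1}" for i in range(n_mt)]
    gene_ids += [f"RPS{i + 1}" for i in range(n_ribo)]
    gene_symbols = list(gene_ids)

    cluster_names = [c.name for c in spec.clusters]
    marker_of = np.array([""] * spec.n_genes, dtype=object)
    cursor = 0
    marker_rows: dict[str, np.ndarray] = {}
    for name in cluster_names:
        rows = np.arange(cursor, cursor + spec.de_genes_per_cluster)
        marker_rows[name] = rows
        marker_of[rows] = name
        cursor += spec.de_genes_per_cluster
    shifted_in = np.array([""] * spec.n_genes, dtype=object)
    shift_rows: dict[str, np.ndarray] = {}
    for name in cluster_names:
        s = spec.shift.get(name)
        if s is None or s.n_genes == 0:
            continue
        rows = np.arange(cursor, cursor + s.n_genes)
        shift_rows[name] = rows
        shifted_in[rows] = name
        cursor += s.n_genes

    # baseline gene weights (relative expression propensities)
    w_regular = rng.lognormal(mean=0.0, sigma=1.0, size=n_regular)
    w_org = rng.lognormal(mean=0.0, sigma=1.0, size=n_org) if n_org else np.empty(0)

    # cell layout: case block then control block, clusters in spec order
    conditions, clusters_per_cell = [], []
    for condition in ("case", "control"):
        props = [c.proportion for c in spec.clusters]
        if condition == "case" and spec.case_proportions is not None:
            props = [spec.case_proportions[c.name] for c in spec.clusters]
        counts = _partition_counts(spec.n_cells_per_condition, props)
        for c, k in zip(spec.clusters, counts):
            conditions += [condition] * k
            clusters_per_cell += [c.name] * k
    n_cells = len(conditions)
    barcodes = [f"CELL{i + 1:06d}" for i in range(n_cells)]
    base_scale = {c.name: c.base_scale for c in spec.clusters}

    libraries = rng.lognormal(spec.library_mean_log, spec.library_sd_log, size=n_cells)
    outlier = rng.random(n_cells) < spec.outlier_fraction
    o = spec.organelle
    if n_org:
        a = o.load_mean * o.load_concentration
        b = (1 - o.load_mean) * o.load_concentration
        loads = rng.beta(a, b, size=n_cells)
        lo, hi = o.outlier_load_range
        loads[outlier] = rng.uniform(lo, hi, size=int(outlier.sum()))
    else:
        loads = np.zeros(n_cells)
        outlier &= False  # no mechanism to plant outliers without organelle genes

    mu = np.empty((spec.n_genes, n_cells))
    for j in range(n_cells):
        w = w_regular.copy()
        cl = clusters_per_cell[j]
        w[marker_rows[cl]] *= spec.marker_fold
        if conditions[j] == "case" and cl in shift_rows:
            w[shift_rows[cl]] *= spec.shift[cl].fold
        w /= w.sum()
        total = libraries[j] * base_scale[cl]
        mu[:n_regular, j] = total * (1 - loads[j]) * w
        if n_org:
            mu[n_regular:, j] = total * loads[j] * (w_org / w_org.sum())

    p = spec.dispersion / (spec.dispersion + mu)
    counts = rng.negative_binomial(spec.dispersion, p)
    matrix = CountMatrix(sp.csc_matrix(counts), gene_ids, barcodes, gene_symbols)

    annotation = pd.DataFrame(
        {
            "barcode": barcodes,
            "sample_id": [f"{c}_s1" for c in conditions],
            "condition": conditions,
            "cluster": clusters_per_cell,
        }
    )
    truth = SyntheticTruth(
        cells=pd.DataFrame(
            {
                "barcode": barcodes,
                "cluster": clusters_per_cell,
                "condition": conditions,
                "qc_outlier": outlier,
            }
        ),
        genes=pd.DataFrame(
            {
                "gene_id": gene_ids,
                "gene_symbol": gene_symbols,
                "marker_of": marker_of,
                "shifted_in": shifted_in,
                "is_organelle": [i >= n_regular for i in range(spec.n_genes)],
            }
        ),
    )
    return matrix, annotation, truth


def embed_shifted_gaussians(
    n_per_group: int, K: int, delta: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Two standard-Gaussian clouds in K dims; the second is mean-shifted by
    ``delta`` along the first coordinate.  Theoretical Bhattacharyya
    distance between the generating laws is delta^2 / 8."""
    if n_per_group < K + 1:
        raise ValidationError("n_per_group must be at least K + 1")
    rng = np.random.default_rng(seed)
    control = rng.standard_normal((n_per_group, K))
    case = rng.standard_normal((n_per_group, K))
    case[:, 0] += delta
    return control, case


def gaussian_pair_embedding(
    n_per_group: int, K: int, delta: float, seed: int
) -> tuple[Embedding, list[str], list[str]]:
    """Wrap :func:`embed_shifted_gaussians` as an Embedding plus the case
    and control barcode lists, for exercising the distance statistic in
    isolation."""
    control, case = embed_shifted_gaussians(n_per_group, K, delta, seed)
    control_bcs = [f"CTRL{i + 1:06d}" for i in range(n_per_group)]
    case_bcs = [f"CASE{i + 1:06d}" for i in range(n_per_group)]
    coords = np.vstack([control, case])
    emb = Embedding(
        coords=coords,
        explained_variance=np.sort(coords.var(axis=0, ddof=1))[::-1],
        barcodes=control_bcs + case_bcs,
    )
    return emb, case_bcs, control_bcs
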