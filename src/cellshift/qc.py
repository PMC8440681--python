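"""Cell and gene quality-control filters.

Pipeline order is fixed: a gene prevalence filter first, then cell filters
on detected-gene counts (a loose floor, then the hard window) and finally
the organelle-fraction rule.  Detected-gene counts for the cell filters are
recomputed after the gene filter.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyResultError, ValidationError
from .io import CountMatrix

DEFAULT_MITO_PREFIX = "MT-"
DEFAULT_RIBO_PREFIXES = ("RPS", "RPL")


@dataclass(frozen=True)
class QCThresholds:
    """Filter thresholds; defaults follow the standard droplet QC recipe
    (gene in >=3 cells; 200-gene floor; 500..3500 detected-gene window;
    7% organelle ceiling)."""

    min_cells_per_gene: int = 3
    min_genes_loose: int = 200
    min_genes: int = 500
    max_genes: int = 3500
    organelle_max: float = 0.07
    #: "either": a cell fails if mito OR ribo fraction exceeds the ceiling
    #: (each tested separately); "sum": their sum is tested instead.
    organelle_mode: str = "either"

    def __post_init__(self):
        if not (self.min_genes_loose <= self.min_genes < self.max_genes):
            raise ValidationError(
                "need min_genes_loose <= min_genes < max_genes, got "
                f"{self.min_genes_loose}/{self.min_genes}/{self.max_genes}"
            )
        if not (0 < self.organelle_max < 1):
            raise ValidationError("organelle_max must lie in (0, 1)")
        if self.organelle_mode not in ("either", "sum"):
            raise ValidationError("organelle_mode must be 'either' or 'sum'")


@dataclass
class QCReport:
    """Per-step accounting of what the filters removed."""

    n_genes_in: int = 0
    n_cells_in: int = 0
    genes_removed_low_prevalence: int = 0
    cells_removed_loose_floor: int = 0
    cells_removed_gene_window: int = 0
    cells_removed_organelle: int = 0
    n_genes_out: int = 0
    n_cells_out: int = 0
    thresholds: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def compute_qc_metrics(
    m: CountMatrix,
    mito_prefix: str = DEFAULT_MITO_PREFIX,
    ribo_prefixes: tuple[str, ...] = DEFAULT_RIBO_PREFIXES,
) -> pd.DataFrame:
    """Per-cell QC metrics: detected genes, total UMIs, organelle fractions.

    Fractions are organelle UMIs over total UMIs; an all-zero cell gets
    fractions of 0.  A prefix matching no gene symbol is legal and yields 0.
    """
    X = m.values.tocsc()
    n_umis = np.asarray(X.sum(axis=0)).ravel()
    n_genes = np.asarray((X > 0).sum(axis=0)).ravel()

    symbols = np.array(m.gene_symbols)
    mito_mask = np.char.startswith(symbols.astype(str), mito_prefix)
    ribo_mask = np.zeros(len(symbols), dtype=bool)
    for prefix in ribo_prefixes:
        ribo_mask |= np.char.startswith(symbols.astype(str), prefix)

    def _fraction(mask):
        if not mask.any():
            return np.zeros(m.n_cells)
        organelle = np.asarray(X[mask].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(n_umis > 0, organelle / np.maximum(n_umis, 1), 0.0)
        return frac

    return pd.DataFrame(
        {
            "barcode": m.barcodes,
            "n_genes_detected": n_genes.astype(int),
            "n_umis": n_umis.astype(int),
            "mito_fraction": _fraction(mito_mask),
            "ribo_fraction": _fraction(ribo_mask),
        }
    )


def apply_qc_filters(
    m: CountMatrix,
    t: QCThresholds = QCThresholds(),
    mito_prefix: str = DEFAULT_MITO_PREFIX,
    ribo_prefixes: tuple[str, ...] = DEFAULT_RIBO_PREFIXES,
) -> tuple[CountMatrix, QCReport]:
    """Apply the fixed filter cascade; returns survivors plus a report.

    Steps: (1) drop genes detected in fewer than ``min_cells_per_gene``
    cells; (2) drop cells below the loose detected-gene floor; (3) drop
    cells outside the [min_genes, max_genes] window; (4) drop cells whose
    organelle fraction exceeds ``organelle_max``.  Steps 2-4 use counts
    recomputed on the gene-filtered matrix; original ordering is preserved.
    """
    report = QCReport(
        n_genes_in=m.n_genes,
        n_cells_in=m.n_cells,
        thresholds={**asdict(t)},
    )

    cells_per_gene = np.asarray((m.values > 0).sum(axis=1)).ravel()
    gene_keep = cells_per_gene >= t.min_cells_per_gene
    report.genes_removed_low_prevalence = int((~gene_keep).sum())
    m1 = m.subset(gene_mask=gene_keep) if not gene_keep.all() else m

    metrics = compute_qc_metrics(m1, mito_prefix, ribo_prefixes)
    n_genes = metrics["n_genes_detected"].to_numpy()

    keep = n_genes >= t.min_genes_loose
    report.cells_removed_loose_floor = int((~keep).sum())
    if not keep.any():
        raise EmptyResultError("loose_floor")

    window_ok = (n_genes >= t.min_genes) & (n_genes <= t.max_genes)
    report.cells_removed_gene_window = int((keep & ~window_ok).sum())
    keep &= window_ok
    if not keep.any():
        raise EmptyResultError("gene_window")

    mito = metrics["mito_fraction"].to_numpy()
    ribo = metrics["ribo_fraction"].to_numpy()
    if t.organelle_mode == "either":
        organelle_ok = (mito <= t.organelle_max) & (ribo <= t.organelle_max)
    else:
        organelle_ok = (mito + ribo) <= t.organelle_max
    report.cells_removed_organelle = int((keep & ~organelle_ok).sum())
    keep &= organelle_ok
    if not keep.any():
        raise EmptyResultError("organelle")

    out = m1.subset(cell_mask=keep) if not keep.all() else m1
    report.n_genes_out = out.n_genes
    report.n_cells_out = out.n_cells
    return out, report
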