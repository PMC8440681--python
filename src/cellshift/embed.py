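"""Log-normalization, variable-gene selection, scaling, and PCA.

All matrices are genes x cells until :func:`pca_embed`, whose output is
cells x K (cells are the observations being embedded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA

from .errors import NumericalError, ValidationError
from .io import CountMatrix

DEFAULT_SCALE_TOTAL = 1e4
DEFAULT_N_HVGS = 2000
DEFAULT_N_PCS = 20
DEFAULT_CLIP = 10.0


@dataclass
class NormalizedMatrix:
    """Log-normalized expression (genes x cells) with identifiers."""

    values: sp.spmatrix
    gene_ids: list[str]
    gene_symbols: list[str]
    barcodes: list[str]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass
class Embedding:
    """Cells x K principal-component scores."""

    coords: np.ndarray
    explained_variance: np.ndarray
    barcodes: list[str]

    @property
    def K(self) -> int:
        return self.coords.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coords, columns=[f"PC{i + 1}" for i in range(self.K)]
        )
        df.insert(0, "barcode", self.barcodes)
        return df

    def rows_for(self, barcodes) -> np.ndarray:
        """Coordinates for the given barcodes, in sorted barcode order."""
        index = {bc: i for i, bc in enumerate(self.barcodes)}
        missing = [bc for bc in barcodes if bc not in index]
        if missing:
            raise ValidationError(f"barcodes absent from embedding: {missing[:5]}")
        return self.coords[[index[bc] for bc in sorted(barcodes)]]


def log_normalize(m: CountMatrix, scale_total: float = DEFAULT_SCALE_TOTAL) -> NormalizedMatrix:
    """Per cell: ``ln(1 + count * scale_total / cell_total)``.

    Cells with zero total counts map to all-zero columns.
    """
    if scale_total <= 0:
        raise ValidationError("scale_total must be positive")
    X = sp.csc_matrix(m.values, dtype=np.float64)
    totals = np.asarray(X.sum(axis=0)).ravel()
    factors = np.where(totals > 0, scale_total / np.maximum(totals, 1.0), 0.0)
    X = X @ sp.diags(factors)
    X.data = np.log1p(X.data)
    return NormalizedMatrix(X, list(m.gene_ids), list(m.gene_symbols), list(m.barcodes))


def select_hvgs(nm: NormalizedMatrix, n_top: int = DEFAULT_N_HVGS, n_bins: int = 20) -> list[str]:
    """Rank genes by binned dispersion and return the top ``n_top`` ids.

    Mean and dispersion (variance/mean) are computed on the de-logged
    normalized values; genes are placed in ``n_bins`` equal-width bins of
    log mean and ranked by the within-bin z-score of log dispersion.
    Deterministic: ties broken by input gene order.
    """
    if n_top < 1:
        raise ValidationError("n_top must be >= 1")
    X = sp.csr_matrix(nm.values, dtype=np.float64, copy=True)
    X.data = np.expm1(X.data)
    n = nm.n_cells
    mean = np.asarray(X.mean(axis=1)).ravel()
    sq = X.copy()
    sq.data **= 2
    ex2 = np.asarray(sq.mean(axis=1)).ravel()
    var = np.maximum(ex2 - mean**2, 0.0) * (n / max(n - 1, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(mean > 0, var / np.maximum(mean, 1e-300), 0.0)

    score = np.full(nm.n_genes, -np.inf)
    usable = (mean > 0) & (dispersion > 0)
    if usable.any():
        log_mean = np.log(mean[usable])
        log_disp = np.log(dispersion[usable])
        edges = np.linspace(log_mean.min(), log_mean.max(), n_bins + 1)
        bins = np.clip(np.digitize(log_mean, edges[1:-1]), 0, n_bins - 1)
        z = np.empty_like(log_disp)
        for b in range(n_bins):
            in_bin = bins == b
            if not in_bin.any():
                continue
            mu = log_disp[in_bin].mean()
            sd = log_disp[in_bin].std()
            z[in_bin] = (log_disp[in_bin] - mu) / sd if sd > 0 else 0.0
        score[np.flatnonzero(usable)] = z

    # stable sort on (-score, original order)
    order = np.argsort(-score, kind="stable")
    k = min(n_top, nm.n_genes)
    return [nm.gene_ids[i] for i in order[:k]]


def scale_center(
    nm: NormalizedMatrix, genes: list[str] | None = None, clip: float = DEFAULT_CLIP
) -> tuple[np.ndarray, list[str]]:
    """Z-score selected genes across cells (sample sd, ddof=1) and clip.

    Returns a dense (genes x cells) array plus the gene ids used, in the
    requested order.  Zero-variance genes map to all-zero rows.
    """
    if clip <= 0:
        raise ValidationError("clip must be positive")
    if genes is None:
        genes = list(nm.gene_ids)
    index = {g: i for i, g in enumerate(nm.gene_ids)}
    missing = [g for g in genes if g not in index]
    if missing:
        raise ValidationError(f"genes absent from matrix: {missing[:5]}")
    rows = [index[g] for g in genes]
    X = np.asarray(nm.values.tocsr()[rows].todense(), dtype=np.float64)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True) if X.shape[1] > 1 else np.zeros_like(mu)
    centered = X - mu
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = np.where(sd > 0, centered / np.maximum(sd, 1e-300), 0.0)
    return np.clip(scaled, -clip, clip), list(genes)


def pca_embed(
    scaled: np.ndarray,
    barcodes: list[str],
    K: int = DEFAULT_N_PCS,
    seed: int = 0,
) -> Embedding:
    """PC scores of cells from a scaled genes x cells matrix.

    Uses a full SVD (deterministic); each component's sign is fixed so the
    loading entry of largest magnitude is non-negative.  ``seed`` is kept
    in the signature for interface stability but the full solver does not
    consume randomness.
    """
    if K < 1:
        raise ValidationError("K must be >= 1")
    X = np.asarray(scaled, dtype=np.float64).T  # cells x genes
    feasible = min(X.shape[0], X.shape[1])
    if K > feasible:
        raise NumericalError(
            f"K={K} exceeds feasible maximum {feasible} "
            f"for {X.shape[0]} cells x {X.shape[1]} genes"
        )
    pca = PCA(n_components=K, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(X)
    # sign convention: largest-magnitude loading entry non-negative
    flip = np.empty(K)
    for k in range(K):
        j = np.argmax(np.abs(pca.components_[k]))
        flip[k] = 1.0 if pca.components_[k, j] >= 0 else -1.0
    scores = scores * flip
    return Embedding(
        coords=scores,
        explained_variance=pca.explained_variance_.copy(),
        barcodes=list(barcodes),
    )


def embed_counts(
    m: CountMatrix,
    scale_total: float = DEFAULT_SCALE_TOTAL,
    n_hvgs: int = DEFAULT_N_HVGS,
    clip: float = DEFAULT_CLIP,
    K: int = DEFAULT_N_PCS,
    seed: int = 0,
) -> tuple[NormalizedMatrix, Embedding]:
    """Convenience composition: normalize -> HVGs -> scale -> PCA."""
    nm = log_normalize(m, scale_total)
    hvgs = select_hvgs(nm, n_hvgs)
    scaled, _ = scale_center(nm, hvgs, clip)
    K_eff = min(K, min(scaled.shape))
    emb = pca_embed(scaled, nm.barcodes, K=K_eff, seed=seed)
    return nm, emb
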