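"""Condition-shift statistic for cell populations in an embedding.

For each cell type the separation between case and control cells is
summarized by the Bhattacharyya distance between Gaussians fitted to
repeated 500-cell subsamples of each group.  A matched null is built by
pooling both groups and drawing two disjoint subsamples of the same size;
observed distances are normalized by the null mean, and a two-sided
rank-sum test compares observed against null replicates.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats

from .errors import ClusterTooSmallError, NumericalError, ValidationError
from .embed import Embedding

RIDGE_EPS = 1e-6

_ROLE_CODES = {"case": 0, "control": 1, "null": 2}


@dataclass
class GaussianSummary:
    """Moment summary of a point cloud: mean, ridge-regularized covariance,
    and the sample size it was fitted on."""

    mean: np.ndarray
    covariance: np.ndarray
    n: int

    @property
    def K(self) -> int:
        return self.mean.shape[0]


@dataclass(frozen=True)
class SubsampleScheme:
    """Subsampling parameters: draw ``n_sub`` cells per group, ``n_reps``
    times; groups below ``min_cluster_size`` are skipped."""

    n_sub: int = 500
    n_reps: int = 100
    min_cluster_size: int = 500
    seed: int = 0
    cov_mode: str = "full"  # "full" or "diag"

    def __post_init__(self):
        if self.n_reps < 2:
            raise ValidationError("n_reps must be >= 2")
        if self.n_sub < 2:
            raise ValidationError("n_sub must be >= 2")
        if self.cov_mode not in ("full", "diag"):
            raise ValidationError("cov_mode must be 'full' or 'diag'")


@dataclass
class ShiftResult:
    """Observed and null distance replicates plus summary statistics."""

    cell_type: str
    observed: np.ndarray
    null: np.ndarray
    normalized_observed: np.ndarray = field(init=False)
    fold_change: float = field(init=False)
    p_value: float = field(init=False)

    def __post_init__(self):
        null_mean = float(np.mean(self.null))
        if null_mean == 0:
            raise ValidationError("degenerate null: mean null distance is 0")
        self.normalized_observed = np.asarray(self.observed) / null_mean
        self.fold_change = float(np.mean(self.observed) / null_mean)
        self.p_value = wilcoxon_rank_sum(self.observed, self.null)

    def replicate_frame(self) -> pd.DataFrame:
        """Long-format replicate table (for plotting/export)."""
        n_obs, n_null = len(self.observed), len(self.null)
        return pd.DataFrame(
            {
                "cell_type": self.cell_type,
                "role": ["observed"] * n_obs + ["null"] * n_null,
                "replicate": list(range(n_obs)) + list(range(n_null)),
                "distance": np.concatenate([self.observed, self.null]),
                "normalized_distance": np.concatenate(
                    [self.normalized_observed, self.null / np.mean(self.null)]
                ),
            }
        )


def gaussian_summary(points: np.ndarray, cov_mode: str = "full") -> GaussianSummary:
    """Fit mean and sample covariance (ddof=1) with a relative ridge.

    The ridge added to the diagonal is ``1e-6 * trace(cov)/K``, so it
    scales with the data and vanishes for an all-zero cloud.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim == 1:
        pts = pts[:, None]
    n, K = pts.shape
    if n < 2:
        raise ValidationError(f"need n >= 2 points to fit a covariance, got {n}")
    mean = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    if cov_mode == "diag":
        cov = np.diag(np.diag(cov))
    ridge = RIDGE_EPS * (np.trace(cov) / K)
    cov = cov + ridge * np.eye(K)
    return GaussianSummary(mean=mean, covariance=cov, n=n)


def bhattacharyya_gaussian(a: GaussianSummary, b: GaussianSummary) -> float:
    """Closed-form Bhattacharyya distance between two Gaussian summaries.

    D = 1/8 (mu_a-mu_b)' S^-1 (mu_a-mu_b) + 1/2 ln(det S / sqrt(det Sa det Sb))
    with S the average covariance; determinants are taken in log space.
    """
    if a.K != b.K:
        raise ValidationError(f"dimension mismatch: {a.K} vs {b.K}")
    avg = 0.5 * (a.covariance + b.covariance)
    sign_avg, logdet_avg = np.linalg.slogdet(avg)
    sign_a, logdet_a = np.linalg.slogdet(a.covariance)
    sign_b, logdet_b = np.linalg.slogdet(b.covariance)
    if sign_avg <= 0 or sign_a <= 0 or sign_b <= 0:
        cond = np.linalg.cond(avg)
        raise NumericalError(
            f"singular covariance in distance (cond number {cond:.3e})"
        )
    diff = a.mean - b.mean
    maha = float(diff @ scipy.linalg.solve(avg, diff, assume_a="sym"))
    log_term = 0.5 * (logdet_avg - 0.5 * (logdet_a + logdet_b))
    value = 0.125 * maha + log_term
    if not np.isfinite(value):
        raise NumericalError("non-finite Bhattacharyya distance")
    return float(max(value, 0.0))


def _rng(seed: int, label: str, rep: int, role: str) -> np.random.Generator:
    """Derived stream per (cell type, replicate, role): adding cell types or
    replicates never perturbs draws of existing ones."""
    key = zlib.crc32(label.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(key, rep, _ROLE_CODES[role]))
    return np.random.default_rng(ss)


def _coords(emb: Embedding, barcodes) -> np.ndarray:
    return emb.rows_for(barcodes)


def observed_distances(
    emb: Embedding,
    cells_case,
    cells_control,
    s: SubsampleScheme,
    label: str = "",
) -> np.ndarray:
    """Case-vs-control distances over ``n_reps`` independent subsamples.

    Each replicate draws ``n_sub`` cells without replacement from each
    group, fits Gaussian summaries, and evaluates the closed-form distance.
    """
    case = _coords(emb, cells_case)
    control = _coords(emb, cells_control)
    for name, grp in (("case", case), ("control", control)):
        if len(grp) < s.min_cluster_size:
            raise ClusterTooSmallError(
                f"{label or 'group'} {name}: {len(grp)} cells < "
                f"min_cluster_size {s.min_cluster_size}"
            )
        if len(grp) < s.n_sub:
            raise ClusterTooSmallError(
                f"{label or 'group'} {name}: {len(grp)} cells < n_sub {s.n_sub}"
            )
    out = np.empty(s.n_reps)
    for rep in range(s.n_reps):
        idx_case = _rng(s.seed, label, rep, "case").choice(
            len(case), size=s.n_sub, replace=False
        )
        idx_ctrl = _rng(s.seed, label, rep, "control").choice(
            len(control), size=s.n_sub, replace=False
        )
        ga = gaussian_summary(case[idx_case], s.cov_mode)
        gb = gaussian_summary(control[idx_ctrl], s.cov_mode)
        out[rep] = bhattacharyya_gaussian(ga, gb)
    return out


def null_distances(
    emb: Embedding,
    cells_case,
    cells_control,
    s: SubsampleScheme,
    label: str = "",
) -> np.ndarray:
    """Mixed-group null: pool both groups, draw two disjoint ``n_sub``-cell
    samples per replicate, and measure their distance."""
    pooled = np.vstack([_coords(emb, cells_case), _coords(emb, cells_control)])
    if len(pooled) < 2 * s.n_sub:
        raise ClusterTooSmallError(
            f"{label or 'group'}: pooled size {len(pooled)} < 2*n_sub {2 * s.n_sub}"
        )
    out = np.empty(s.n_reps)
    for rep in range(s.n_reps):
        rng = _rng(s.seed, label, rep, "null")
        idx = rng.choice(len(pooled), size=2 * s.n_sub, replace=False)
        ga = gaussian_summary(pooled[idx[: s.n_sub]], s.cov_mode)
        gb = gaussian_summary(pooled[idx[s.n_sub :]], s.cov_mode)
        out[rep] = bhattacharyya_gaussian(ga, gb)
    return out


def shift_statistic(observed, null, cell_type: str = "") -> ShiftResult:
    """Normalize observed distances by the null mean and test the contrast."""
    observed = np.asarray(observed, dtype=np.float64)
    null = np.asarray(null, dtype=np.float64)
    if observed.size == 0 or null.size == 0:
        raise ValidationError("observed and null vectors must be non-empty")
    return ShiftResult(cell_type=cell_type, observed=observed, null=null)


def wilcoxon_rank_sum(x, y, exact_max_n: int = 10) -> float:
    """Two-sided rank-sum p-value.

    Exact null enumeration (via the Mann-Whitney recurrence) when the
    smaller group has at most ``exact_max_n`` observations and there are no
    ties; otherwise the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return 1.0
    no_ties = len(np.unique(combined)) == combined.size
    method = "exact" if (min(x.size, y.size) <= exact_max_n and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    # continuity correction makes a perfectly balanced U slightly under 1
    if method == "asymptotic" and res.statistic == x.size * y.size / 2:
        return 1.0
    return float(min(res.pvalue, 1.0))


def shift_by_cell_type(
    emb: Embedding,
    annotation: pd.DataFrame,
    s: SubsampleScheme,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Run the statistic per cluster of an annotation table.

    Returns (summary table, long replicate table, skip reasons).  Clusters
    whose case or control side is below the scheme's minimum are skipped
    with a recorded reason rather than failing the run.
    """
    summaries, replicates, skipped = [], [], {}
    for cluster, sub in annotation.groupby("cluster", sort=True):
        cells_case = sub.loc[sub["condition"] == "case", "barcode"].tolist()
        cells_control = sub.loc[sub["condition"] == "control", "barcode"].tolist()
        try:
            obs = observed_distances(emb, cells_case, cells_control, s, label=str(cluster))
            nul = null_distances(emb, cells_case, cells_control, s, label=str(cluster))
        except ClusterTooSmallError as exc:
            skipped[str(cluster)] = str(exc)
            continue
        res = shift_statistic(obs, nul, cell_type=str(cluster))
        summaries.append(
            {
                "cell_type": res.cell_type,
                "n_case": len(cells_case),
                "n_control": len(cells_control),
                "fold_change": res.fold_change,
                "p_value": res.p_value,
                "n_obs_reps": len(res.observed),
                "n_null_reps": len(res.null),
            }
        )
        replicates.append(res.replicate_frame())
    summary = pd.DataFrame(
        summaries,
        columns=[
            "cell_type", "n_case", "n_control", "fold_change",
            "p_value", "n_obs_reps", "n_null_reps",
        ],
    )
    reps = (
        pd.concat(replicates, ignore_index=True)
        if replicates
        else pd.DataFrame(
            columns=["cell_type", "role", "replicate", "distance", "normalized_distance"]
        )
    )
    return summary, reps, skipped
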