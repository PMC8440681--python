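"""Per-cluster condition contrasts.

Differential-expression counting between conditions within each cluster,
gene-set mean-activity scoring with log fold changes between groups, and
cell-proportion shift testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .embed import NormalizedMatrix

DE_PSEUDOCOUNT = 1.0  # applied to de-logged group means
ACTIVITY_PSEUDOCOUNT = 0.01
DEFAULT_LFC_THRESHOLD = 0.5
DEFAULT_P_THRESHOLD = 0.05
DEFAULT_MIN_FRAC = 0.1


def _cell_indices(nm: NormalizedMatrix, barcodes) -> np.ndarray:
    index = {bc: i for i, bc in enumerate(nm.barcodes)}
    missing = [bc for bc in barcodes if bc not in index]
    if missing:
        raise ValidationError(f"barcodes absent from matrix: {missing[:5]}")
    return np.array([index[bc] for bc in barcodes], dtype=int)


def per_gene_de(
    nm: NormalizedMatrix,
    cells_case,
    cells_control,
    min_frac_expressing: float = DEFAULT_MIN_FRAC,
) -> pd.DataFrame:
    """Per-gene case-vs-control contrast on the normalized matrix.

    Genes expressed (value > 0) in at least ``min_frac_expressing`` of
    either group are tested.  log2FC compares de-logged group means with a
    pseudocount of 1; p-values come from a per-gene two-sided rank-sum
    test, adjusted by Benjamini-Hochberg over the tested genes.
    """
    if not (0 <= min_frac_expressing < 1):
        raise ValidationError("min_frac_expressing must lie in [0, 1)")
    idx_case = _cell_indices(nm, cells_case)
    idx_ctrl = _cell_indices(nm, cells_control)
    if idx_case.size == 0 or idx_ctrl.size == 0:
        raise ValidationError("both groups must be non-empty")

    X = sp.csr_matrix(nm.values)
    Xa = np.asarray(X[:, idx_case].todense())
    Xb = np.asarray(X[:, idx_ctrl].todense())

    frac_a = (Xa > 0).mean(axis=1)
    frac_b = (Xb > 0).mean(axis=1)
    tested = (frac_a >= min_frac_expressing) | (frac_b >= min_frac_expressing)
    rows = np.flatnonzero(tested)
    if rows.size == 0:
        return pd.DataFrame(
            columns=["gene_id", "gene_symbol", "log2_fold_change", "p_value", "adj_p_value"]
        )

    mean_a = np.expm1(Xa[rows]).mean(axis=1)
    mean_b = np.expm1(Xb[rows]).mean(axis=1)
    lfc = np.log2((mean_a + DE_PSEUDOCOUNT) / (mean_b + DE_PSEUDOCOUNT))

    pvals = np.ones(rows.size)
    for i, r in enumerate(rows):
        a, b = Xa[r], Xb[r]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            continue  # constant gene: no evidence, p stays 1
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        if np.isnan(res.pvalue) or res.statistic == a.size * b.size / 2:
            pvals[i] = 1.0  # perfectly balanced ranks: no evidence either way
        else:
            pvals[i] = min(float(res.pvalue), 1.0)

    adj = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene_id": [nm.gene_ids[r] for r in rows],
            "gene_symbol": [nm.gene_symbols[r] for r in rows],
            "log2_fold_change": lfc,
            "p_value": pvals,
            "adj_p_value": np.minimum(adj, 1.0),
        }
    )


def count_significant(
    degs: pd.DataFrame,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    use_adjusted: bool = False,
) -> int:
    """Number of genes with |log2FC| strictly above ``lfc_threshold`` AND
    p strictly below ``p_threshold``."""
    if lfc_threshold <= 0 or p_threshold <= 0:
        raise ValidationError("thresholds must be positive")
    if degs.empty:
        return 0
    p_col = "adj_p_value" if use_adjusted else "p_value"
    passing = (degs["log2_fold_change"].abs() > lfc_threshold) & (degs[p_col] < p_threshold)
    return int(passing.sum())


def deg_counts_per_cluster(
    nm: NormalizedMatrix,
    annotation: pd.DataFrame,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    use_adjusted: bool = False,
    min_frac_expressing: float = DEFAULT_MIN_FRAC,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Significant-gene count per cluster between conditions.

    Clusters with fewer than ``min_cells`` cells in either condition are
    reported with ``tested=False`` rather than dropped.
    """
    records = []
    for cluster, sub in annotation.groupby("cluster", sort=True):
        case = sub.loc[sub["condition"] == "case", "barcode"].tolist()
        ctrl = sub.loc[sub["condition"] == "control", "barcode"].tolist()
        if len(case) < min_cells or len(ctrl) < min_cells:
            records.append(
                {
                    "cluster": str(cluster), "n_case": len(case), "n_control": len(ctrl),
                    "tested": False, "n_genes_tested": 0, "n_deg": 0,
                }
            )
            continue
        degs = per_gene_de(nm, case, ctrl, min_frac_expressing)
        records.append(
            {
                "cluster": str(cluster), "n_case": len(case), "n_control": len(ctrl),
                "tested": True, "n_genes_tested": len(degs),
                "n_deg": count_significant(degs, lfc_threshold, p_threshold, use_adjusted),
            }
        )
    return pd.DataFrame(records)


@dataclass
class GeneSetActivity:
    """Mean log-normalized expression per (group, gene set) plus bookkeeping
    of sets skipped for lacking any gene in the matrix."""

    activity: pd.DataFrame  # columns: group, gene_set, mean_activity, n_genes
    group_by: str
    skipped_sets: list[str] = field(default_factory=list)

    def log_fold_change(self, group_a: str, group_b: str) -> pd.DataFrame:
        """Per-set log2 fold change of mean activity between two groups."""
        pivot = self.activity.pivot(index="gene_set", columns="group", values="mean_activity")
        for g in (group_a, group_b):
            if g not in pivot.columns:
                raise ValidationError(f"unknown group {g!r}")
        c = ACTIVITY_PSEUDOCOUNT
        lfc = np.log2((pivot[group_a] + c) / (pivot[group_b] + c))
        return pd.DataFrame(
            {"gene_set": pivot.index, "log2_fold_change": lfc.to_numpy()}
        ).reset_index(drop=True)


def geneset_activity(
    nm: NormalizedMatrix,
    annotation: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    group_by: str = "cluster",
) -> GeneSetActivity:
    """Mean expression of each gene set within each group of cells.

    Activity is the mean of log-normalized values over the set's genes
    (intersected with the matrix, matched by symbol) and the group's cells.
    Sets sharing no gene with the matrix are recorded as skipped.
    """
    if group_by not in ("cluster", "condition"):
        raise ValidationError("group_by must be 'cluster' or 'condition'")
    symbol_rows: dict[str, list[int]] = {}
    for i, sym in enumerate(nm.gene_symbols):
        symbol_rows.setdefault(sym, []).append(i)

    X = sp.csr_matrix(nm.values)
    records, skipped = [], []
    set_rows = {}
    for name, genes in gene_sets.items():
        rows = [r for g in genes for r in symbol_rows.get(g, [])]
        if not rows:
            skipped.append(name)
        else:
            set_rows[name] = np.array(rows)

    for group, sub in annotation.groupby(group_by, sort=True):
        cols = _cell_indices(nm, sub["barcode"].tolist())
        for name, rows in set_rows.items():
            block = X[rows][:, cols]
            denom = rows.size * cols.size
            mean = float(block.sum() / denom) if denom else 0.0
            records.append(
                {
                    "group": str(group), "gene_set": name,
                    "mean_activity": mean, "n_genes": int(rows.size),
                }
            )
    return GeneSetActivity(
        activity=pd.DataFrame(records, columns=["group", "gene_set", "mean_activity", "n_genes"]),
        group_by=group_by,
        skipped_sets=skipped,
    )


def proportion_shift(annotation: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster two-proportion z-test of composition between conditions.

    For each cluster the fraction of case cells belonging to it is compared
    with the control fraction using the pooled-variance z statistic,
    two-sided.  Proportions are normalized within condition.
    """
    counts = annotation.groupby(["cluster", "condition"], sort=True).size()
    n_case = int(annotation.eval("condition == 'case'").sum())
    n_ctrl = int(annotation.eval("condition == 'control'").sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValidationError("both conditions must have at least one cell")

    records = []
    for cluster in sorted(annotation["cluster"].astype(str).unique()):
        k_case = int(counts.get((cluster, "case"), 0))
        k_ctrl = int(counts.get((cluster, "control"), 0))
        p1, p2 = k_case / n_case, k_ctrl / n_ctrl
        pooled = (k_case + k_ctrl) / (n_case + n_ctrl)
        se = np.sqrt(pooled * (1 - pooled) * (1 / n_case + 1 / n_ctrl))
        if se == 0:
            z, p = 0.0, 1.0
        else:
            z = (p1 - p2) / se
            p = float(2 * stats.norm.sf(abs(z)))
        records.append(
            {
                "cluster": cluster,
                "n_case": k_case, "n_control": k_ctrl,
                "prop_case": p1, "prop_control": p2,
                "direction": "up" if p1 > p2 else ("down" if p1 < p2 else "none"),
                "z": float(z), "p_value": min(p, 1.0) if p > 0 else np.nextafter(0, 1),
            }
        )
    return pd.DataFrame(records)
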