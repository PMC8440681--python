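import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats

from cellshift.contrast import (
    count_significant,
    deg_counts_per_cluster,
    geneset_activity,
    per_gene_de,
    proportion_shift,
)
from cellshift.embed import NormalizedMatrix, log_normalize
from cellshift.errors import ValidationError
from cellshift.simulate import ShiftSpec, SyntheticSpec, generate_dataset
from conftest import make_counts


def nm_from_values(values, gene_ids=None, barcodes=None):
    values = np.asarray(values, dtype=float)
    n_genes, n_cells = values.shape
    gene_ids = gene_ids or [f"G{i}" for i in range(n_genes)]
    barcodes = barcodes or [f"C{i}" for i in range(n_cells)]
    return NormalizedMatrix(sp.csr_matrix(values), gene_ids, list(gene_ids), barcodes)


def annotation(barcodes, conditions, clusters, sample="s1"):
    return pd.DataFrame(
        {
            "barcode": barcodes,
            "sample_id": sample,
            "condition": conditions,
            "cluster": clusters,
        }
    )


class TestPerGeneDe:
    def test_identical_gene(self):
        vals = np.tile([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], (2, 1))
        nm = nm_from_values(vals)
        degs = per_gene_de(nm, ["C0", "C1", "C2"], ["C3", "C4", "C5"], 0.0)
        assert degs["log2_fold_change"].abs().max() == pytest.approx(0.0)
        assert (degs["p_value"] == 1.0).all()

    def test_threefold_mean_large_counts(self):
        # de-logged means ~3000 vs ~1000: pseudocount 1 is negligible
        case_vals = np.log1p(np.full(20, 3000.0))
        ctrl_vals = np.log1p(np.full(20, 1000.0))
        vals = np.concatenate([case_vals, ctrl_vals])[None, :]
        nm = nm_from_values(vals)
        degs = per_gene_de(nm, [f"C{i}" for i in range(20)],
                           [f"C{i}" for i in range(20, 40)], 0.0)
        assert degs.loc[0, "log2_fold_change"] == pytest.approx(np.log2(3), abs=0.01)

    def test_null_simulation_false_positive_rate(self):
        rng = np.random.default_rng(42)
        n_genes, n_per_group = 200, 100
        vals = rng.gamma(2.0, 1.0, size=(n_genes, 2 * n_per_group))
        nm = nm_from_values(vals)
        case = [f"C{i}" for i in range(n_per_group)]
        ctrl = [f"C{i}" for i in range(n_per_group, 2 * n_per_group)]
        degs = per_gene_de(nm, case, ctrl, 0.0)
        n_sig = int((degs["p_value"] < 0.05).sum())
        lo, hi = stats.binom.interval(0.99, n_genes, 0.05)
        assert lo <= n_sig <= hi

    def test_swapping_groups_negates_lfc_keeps_p(self, rng):
        vals = rng.gamma(2.0, size=(30, 40))
        nm = nm_from_values(vals)
        case = [f"C{i}" for i in range(20)]
        ctrl = [f"C{i}" for i in range(20, 40)]
        fwd = per_gene_de(nm, case, ctrl, 0.0)
        rev = per_gene_de(nm, ctrl, case, 0.0)
        np.testing.assert_allclose(
            fwd["log2_fold_change"], -rev["log2_fold_change"], atol=1e-12
        )
        np.testing.assert_allclose(fwd["p_value"], rev["p_value"], atol=1e-12)

    def test_min_frac_expressing_excludes_rare_genes(self):
        vals = np.zeros((2, 20))
        vals[0, :] = 1.0          # expressed everywhere
        vals[1, 0] = 1.0          # expressed in 1/10 of one group only
        nm = nm_from_values(vals)
        case = [f"C{i}" for i in range(10)]
        ctrl = [f"C{i}" for i in range(10, 20)]
        degs = per_gene_de(nm, case, ctrl, min_frac_expressing=0.25)
        assert degs["gene_id"].tolist() == ["G0"]

    def test_bh_adjustment_monotone(self, rng):
        vals = rng.gamma(1.5, size=(50, 30))
        nm = nm_from_values(vals)
        degs = per_gene_de(nm, [f"C{i}" for i in range(15)],
                           [f"C{i}" for i in range(15, 30)], 0.0)
        s = degs.sort_values("p_value")
        assert (np.diff(s["adj_p_value"]) >= -1e-12).all()
        assert (degs["adj_p_value"] >= degs["p_value"] - 1e-12).all()

    def test_empty_group_rejected(self):
        nm = nm_from_values(np.ones((2, 4)))
        with pytest.raises(ValidationError):
            per_gene_de(nm, [], ["C0"], 0.0)


class TestCountSignificant:
    def test_brute_force_fixture(self):
        degs = pd.DataFrame(
            {
                "log2_fold_change": [0.9, -0.6, 0.4, 1.2, -0.2],
                "p_value": [0.01, 0.20, 0.01, 0.04, 0.001],
                "adj_p_value": [0.05, 0.40, 0.05, 0.10, 0.01],
            }
        )
        # pass both rules: rows 0 (0.9, 0.01) and 3 (1.2, 0.04)
        assert count_significant(degs) == 2

    def test_boundary_lfc_excluded(self):
        degs = pd.DataFrame(
            {"log2_fold_change": [0.5], "p_value": [0.001], "adj_p_value": [0.001]}
        )
        assert count_significant(degs) == 0

    def test_empty_table(self):
        assert count_significant(pd.DataFrame()) == 0

    def test_matches_row_scan_random(self, rng):
        degs = pd.DataFrame(
            {
                "log2_fold_change": rng.normal(0, 1, 100),
                "p_value": rng.uniform(0, 1, 100),
            }
        )
        degs["adj_p_value"] = np.minimum(degs["p_value"] * 2, 1.0)
        expected = sum(
            1
            for _, r in degs.iterrows()
            if abs(r["log2_fold_change"]) > 0.5 and r["p_value"] < 0.05
        )
        assert count_significant(degs) == expected


class TestDegCountsPerCluster:
    def test_planted_cluster_has_most_degs(self):
        spec = SyntheticSpec(
            n_genes=200,
            n_cells_per_condition=150,
            shift={"A": ShiftSpec(n_genes=30, fold=3.0)},
            seed=5,
        )
        counts, ann, _ = generate_dataset(spec)
        nm = log_normalize(counts)
        table = deg_counts_per_cluster(nm, ann).set_index("cluster")
        assert table.loc["A", "n_deg"] > table.drop("A")["n_deg"].max()

    def test_permuted_labels_give_small_counts(self):
        spec = SyntheticSpec(
            n_genes=200,
            n_cells_per_condition=150,
            shift={"A": ShiftSpec(n_genes=30, fold=3.0)},
            seed=5,
        )
        counts, ann, _ = generate_dataset(spec)
        nm = log_normalize(counts)
        rng = np.random.default_rng(0)
        ann = ann.copy()
        ann["condition"] = rng.permutation(ann["condition"].to_numpy())
        table = deg_counts_per_cluster(nm, ann)
        # under permutation the |lfc|>0.5 AND p<0.05 intersection is rare
        assert (table["n_deg"] <= 10).all()

    def test_single_cluster(self):
        rng = np.random.default_rng(1)
        m = make_counts(rng.integers(0, 6, size=(30, 20)))
        nm = log_normalize(m)
        ann = annotation(
            nm.barcodes, ["case"] * 10 + ["control"] * 10, ["only"] * 20
        )
        table = deg_counts_per_cluster(nm, ann)
        assert len(table) == 1
        assert bool(table.loc[0, "tested"])

    def test_undersized_cluster_flagged_not_dropped(self):
        rng = np.random.default_rng(1)
        m = make_counts(rng.integers(0, 6, size=(30, 10)))
        nm = log_normalize(m)
        ann = annotation(
            nm.barcodes,
            ["case"] * 2 + ["control"] * 8,
            ["small"] * 10,
        )
        table = deg_counts_per_cluster(nm, ann)
        assert not bool(table.loc[0, "tested"])
        assert table.loc[0, "n_deg"] == 0


class TestGenesetActivity:
    def test_single_gene_single_cell_identity(self):
        nm = nm_from_values(np.array([[1.7]]))
        ann = annotation(["C0"], ["case"], ["X"])
        act = geneset_activity(nm, ann, {"S": ["G0"]})
        assert act.activity.loc[0, "mean_activity"] == pytest.approx(1.7)

    def test_identical_clusters_zero_lfc(self):
        vals = np.tile(np.array([[1.0], [2.0]]), (1, 6))
        nm = nm_from_values(vals)
        ann = annotation(nm.barcodes, ["case"] * 6, ["X"] * 3 + ["Y"] * 3)
        act = geneset_activity(nm, ann, {"S": ["G0", "G1"]})
        lfc = act.log_fold_change("X", "Y")
        assert lfc.loc[0, "log2_fold_change"] == pytest.approx(0.0)

    def test_lfc_antisymmetric(self, rng):
        vals = rng.gamma(2.0, size=(10, 12))
        nm = nm_from_values(vals)
        ann = annotation(nm.barcodes, ["case"] * 12, ["X"] * 6 + ["Y"] * 6)
        act = geneset_activity(nm, ann, {"S1": ["G0", "G3"], "S2": ["G5"]})
        ab = act.log_fold_change("X", "Y")["log2_fold_change"]
        ba = act.log_fold_change("Y", "X")["log2_fold_change"]
        np.testing.assert_allclose(ab, -ba, atol=1e-12)

    def test_unmatched_set_skipped(self):
        nm = nm_from_values(np.ones((2, 3)))
        ann = annotation(nm.barcodes, ["case"] * 3, ["X"] * 3)
        act = geneset_activity(nm, ann, {"good": ["G0"], "alien": ["ZZZ"]})
        assert act.skipped_sets == ["alien"]
        assert set(act.activity["gene_set"]) == {"good"}

    def test_planted_upshift_recovered(self):
        hits = 0
        for seed in range(5):
            spec = SyntheticSpec(
                n_genes=150,
                n_cells_per_condition=120,
                shift={"B": ShiftSpec(n_genes=20, fold=2.0)},
                seed=seed,
            )
            counts, ann, truth = generate_dataset(spec)
            nm = log_normalize(counts)
            shifted_genes = truth.genes.loc[
                truth.genes["shifted_in"] == "B", "gene_symbol"
            ].tolist()
            case_b = ann[(ann.cluster == "B") & (ann.condition == "case")]
            ctrl_b = ann[(ann.cluster == "B") & (ann.condition == "control")]
            sub = pd.concat([case_b, ctrl_b])
            act = geneset_activity(nm, sub, {"S": shifted_genes}, group_by="condition")
            lfc = act.log_fold_change("case", "control").loc[0, "log2_fold_change"]
            hits += lfc > 0
        assert hits == 5


class TestProportionShift:
    def test_hand_computed_z(self):
        bcs = [f"C{i}" for i in range(200)]
        conds = ["case"] * 100 + ["control"] * 100
        clusters = (["X"] * 60 + ["Y"] * 40) + (["X"] * 40 + ["Y"] * 60)
        table = proportion_shift(annotation(bcs, conds, clusters)).set_index("cluster")
        assert table.loc["X", "prop_case"] == pytest.approx(0.6)
        assert table.loc["X", "prop_control"] == pytest.approx(0.4)
        assert table.loc["X", "z"] == pytest.approx(2.828427, abs=1e-5)
        assert table.loc["X", "p_value"] == pytest.approx(0.004678, abs=1e-5)
        assert table.loc["X", "direction"] == "up"

    def test_identical_composition(self):
        bcs = [f"C{i}" for i in range(40)]
        conds = ["case"] * 20 + ["control"] * 20
        clusters = (["X"] * 10 + ["Y"] * 10) * 2
        table = proportion_shift(annotation(bcs, conds, clusters))
        assert (table["p_value"] == 1.0).all()

    def test_cluster_absent_from_one_condition(self):
        bcs = [f"C{i}" for i in range(30)]
        conds = ["case"] * 15 + ["control"] * 15
        clusters = ["X"] * 15 + (["X"] * 10 + ["Z"] * 5)
        table = proportion_shift(annotation(bcs, conds, clusters)).set_index("cluster")
        assert table.loc["Z", "prop_case"] == 0.0
        assert 0 < table.loc["Z", "p_value"] <= 1.0

    def test_proportions_sum_to_one(self, rng):
        n = 300
        bcs = [f"C{i}" for i in range(n)]
        conds = rng.choice(["case", "control"], size=n).tolist()
        clusters = rng.choice(list("ABCDE"), size=n).tolist()
        table = proportion_shift(annotation(bcs, conds, clusters))
        assert table["prop_case"].sum() == pytest.approx(1.0, abs=1e-12)
        assert table["prop_control"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_missing_condition_rejected(self):
        with pytest.raises(ValidationError):
            proportion_shift(annotation(["C0"], ["case"], ["X"]))
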