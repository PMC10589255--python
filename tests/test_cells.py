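"""Cell-type-resolved counting, QC filters, marker tests, aggregates."""

import numpy as np
import pandas as pd
import pytest

import paraquant as pq
from paraquant.cells import load_annotation, read_matrix

from oracles import rank_sum_two_sided_p


def qc_matrix(rng, n_cells=30, n_genes=250):
    """Counts matrix where every gene passes and every cell detects ~all
    genes (used as a base for boundary manipulations)."""
    mat = pd.DataFrame(rng.poisson(5, (n_cells, n_genes)) + 1,
                       index=[f"c{i}" for i in range(n_cells)],
                       columns=[f"g{j}" for j in range(n_genes)])
    return mat


class TestFilterCellsGenes:
    @pytest.mark.parametrize("n_detected,kept", [
        (199, False), (200, True), (8000, True), (8001, False)])
    def test_cell_detection_boundaries(self, n_detected, kept):
        # two overlapping cell groups keep every gene detected in >=3
        # cells while each group stays inside the [200, 8000] window
        n_genes = 8100
        rows = {}
        for i in range(3):
            row = np.zeros(n_genes, dtype=int)
            row[:8000] = 1
            rows[f"a{i}"] = row
        for i in range(3):
            row = np.zeros(n_genes, dtype=int)
            row[100:] = 1
            rows[f"b{i}"] = row
        probe = np.zeros(n_genes, dtype=int)
        probe[:n_detected] = 1
        rows["probe"] = probe
        mat = pd.DataFrame(rows).T
        mat.columns = [f"g{j}" for j in range(n_genes)]
        out = pq.filter_cells_genes(mat, min_genes=200, max_genes=8000)
        assert ("probe" in out.index) == kept

    @pytest.mark.parametrize("n_cells_detected,kept", [(2, False), (3, True)])
    def test_gene_detection_boundary(self, rng, n_cells_detected, kept):
        mat = qc_matrix(rng)
        probe = np.zeros(len(mat), dtype=int)
        probe[:n_cells_detected] = 1
        mat["probe"] = probe
        out = pq.filter_cells_genes(mat)
        assert ("probe" in out.columns) == kept

    def test_all_pass_matrix_unchanged(self, rng):
        mat = qc_matrix(rng)
        out = pq.filter_cells_genes(mat)
        pd.testing.assert_frame_equal(out, mat)

    def test_empty_result_raises(self, rng):
        mat = qc_matrix(rng, n_cells=5, n_genes=50)  # cells detect <200
        with pytest.raises(ValueError, match="empty"):
            pq.filter_cells_genes(mat)

    def test_gene_filter_applied_before_cell_filter(self):
        # cell detects exactly 200 genes, but one of them is a gene seen
        # in <3 cells: after the gene filter the cell drops to 199 -> out
        n_genes = 220
        cells = {f"c{i}": [1] * n_genes for i in range(5)}
        probe = [1] * 200 + [0] * 20
        probe_gene = [0] * 5
        mat = pd.DataFrame(cells).T
        mat.columns = [f"g{j}" for j in range(n_genes)]
        mat.loc["probe"] = probe
        mat["rare"] = [0, 0, 0, 0, 0, 1]  # detected only in probe cell
        mat.loc["probe", "g199"] = 0      # probe: 199 common + rare = 200
        out = pq.filter_cells_genes(mat, min_genes=200, max_genes=8000)
        assert "rare" not in out.columns
        assert "probe" not in out.index


class TestScreenCells:
    @pytest.fixture()
    def sc_inputs(self, panel, catalog, tmp_path):
        spec = pq.StrainSpec("S5", 5, [0.2] * 5, divergence_sites=5)
        sc = pq.SimScenario(seed=31, strains=[spec], library_size=100)
        profiles = [
            pq.CellTypeProfile("spermatogonia", 0.5,
                               {"S5_p1": 2.0, "decoy": 5.0}),
            pq.CellTypeProfile("late_spermatocytes", 0.5,
                               {"S5_p1": 20.0, "S5_p2": 20.0, "decoy": 5.0}),
        ]
        paths, truth = pq.simulate_cells(panel, profiles, 80, sc, tmp_path)
        return paths, truth

    def test_totals_invariant(self, sc_inputs, catalog):
        paths, _ = sc_inputs
        ann = load_annotation(paths["annotation"])
        res = pq.screen_cells(paths["r1"], paths["r2"], catalog, ann)
        assert res.reads_per_type.sum() + res.discarded_reads == res.total_reads
        assert res.discarded_reads == 0

    def test_unannotated_barcodes_all_discarded(self, sc_inputs, catalog):
        paths, _ = sc_inputs
        ann = pd.Series({"T" * 16: "sometype", "G" * 16: "othertype"})
        res = pq.screen_cells(paths["r1"], paths["r2"], catalog, ann)
        assert res.discarded_reads == res.total_reads
        assert (res.counts.to_numpy() == 0).all()

    def test_enriched_type_dominates_counts(self, sc_inputs, catalog):
        paths, _ = sc_inputs
        ann = load_annotation(paths["annotation"])
        res = pq.screen_cells(paths["r1"], paths["r2"], catalog, ann)
        p1 = res.counts["S5_p1"]
        assert p1["late_spermatocytes"] > p1["spermatogonia"]

    def test_short_r1_raises(self, catalog, tmp_path):
        r1 = tmp_path / "r1.fastq"
        r2 = tmp_path / "r2.fastq"
        r1.write_text("@r0\nACGT\n+\nIIII\n")
        r2.write_text("@r0\n" + "A" * 50 + "\n+\n" + "I" * 50 + "\n")
        ann = pd.Series({"A" * 16: "t"})
        with pytest.raises(ValueError, match="barcode length"):
            pq.screen_cells(r1, r2, catalog, ann)

    def test_duplicate_annotation_barcodes_raise(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("AAAA\tt1\nAAAA\tt2\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_annotation(p)


class TestMarkerTest:
    def test_identical_expression_flags_nothing(self):
        mat = pd.DataFrame(dict(g=np.ones(40)))
        labels = pd.Series(["a"] * 20 + ["b"] * 20, index=mat.index)
        out = pq.marker_test(mat, labels)
        assert not out["higher"].any()

    def test_shifted_type_flagged(self, rng):
        n = 500
        x = rng.normal(5, 1, n)
        x[:50] += 10
        mat = pd.DataFrame(dict(g=x))
        labels = pd.Series(["hot"] * 50 + ["rest1"] * 225 + ["rest2"] * 225,
                           index=mat.index)
        out = pq.marker_test(mat, labels)
        row = out.set_index("cell_type").loc["hot"]
        assert row["higher"] and row["peak"]

    def test_p_matches_exact_rank_oracle_on_toy(self):
        x = np.array([1.0, 2.0, 9.0, 10.0, 11.0, 3.0])
        labels = pd.Series(["a", "a", "b", "b", "b", "a"])
        mat = pd.DataFrame(dict(g=x), index=labels.index)
        out = pq.marker_test(mat, labels)
        p_b = out.set_index("cell_type").loc["b", "p"]
        expected = rank_sum_two_sided_p(x[[2, 3, 4]], x[[0, 1, 5]])
        assert p_b == pytest.approx(expected)

    def test_zero_expressing_type_has_zero_percent(self):
        mat = pd.DataFrame(dict(g=[0.0, 0, 1, 2]))
        labels = pd.Series(["a", "a", "b", "b"], index=mat.index)
        out = pq.marker_test(mat, labels)
        assert out.set_index("cell_type").loc["a", "pct_expressing"] == 0.0
        assert out.set_index("cell_type").loc["b", "pct_expressing"] == 100.0

    def test_tiny_type_reported_missing(self):
        mat = pd.DataFrame(dict(g=[1.0, 2, 3, 4]))
        labels = pd.Series(["solo", "x", "x", "x"], index=mat.index)
        out = pq.marker_test(mat, labels)
        assert np.isnan(out.set_index("cell_type").loc["solo", "p"])

    def test_label_permutation_type_one_control(self, rng):
        """Permuted labels on a null matrix: flag rate stays near alpha."""
        n_cells, n_reps = 120, 120
        base = rng.poisson(3.0, (n_cells, 3)).astype(float)
        mat = pd.DataFrame(base, columns=list("abc"))
        flags = 0
        tests = 0
        for i in range(n_reps):
            labels = pd.Series(rng.permutation(
                ["t1"] * 40 + ["t2"] * 40 + ["t3"] * 40), index=mat.index)
            out = pq.marker_test(mat, labels)
            flags += out["higher"].sum()
            tests += out["p"].notna().sum()
        rate = flags / tests
        se = np.sqrt(0.05 * 0.95 / tests)
        assert rate <= 0.05 + 3 * se


class TestAggregateFamily:
    def test_single_member_equals_member(self):
        mat = pd.DataFrame(dict(a=[1, 2, 3], b=[4, 5, 6]))
        out = pq.aggregate_family(mat, ["a"])
        assert (out["family_aggregate"] == mat["a"]).all()

    def test_disjoint_members_union_percent(self):
        mat = pd.DataFrame(dict(a=[1, 0, 0, 0], b=[0, 2, 0, 0],
                                c=[5, 5, 5, 5]))
        labels = pd.Series(["t"] * 4, index=mat.index)
        agg = pq.aggregate_family(mat, ["a", "b"])
        pct = 100.0 * (agg["family_aggregate"] > 0).mean()
        pct_a = 100.0 * (mat["a"] > 0).mean()
        pct_b = 100.0 * (mat["b"] > 0).mean()
        assert pct == pct_a + pct_b  # disjoint expressing cells: union adds

    def test_zero_members_zero_aggregate(self):
        mat = pd.DataFrame(dict(a=[0, 0], b=[0, 0]))
        out = pq.aggregate_family(mat, ["a", "b"])
        assert (out["family_aggregate"] == 0).all()

    def test_aggregate_at_least_each_member_per_type(self, rng):
        mat = pd.DataFrame(rng.poisson(2, (30, 3)), columns=list("abc"))
        labels = pd.Series(["t1"] * 15 + ["t2"] * 15, index=mat.index)
        agg = pq.aggregate_family(mat, ["a", "b", "c"])
        per_type = agg.groupby(labels).sum()
        for g in "abc":
            assert (per_type["family_aggregate"] >= per_type[g]).all()

    def test_empty_family_raises(self):
        with pytest.raises(ValueError, match="empty"):
            pq.aggregate_family(pd.DataFrame(dict(a=[1])), [])


class TestMatrixIO:
    def test_round_trip(self, rng, tmp_path):
        mat = pd.DataFrame(rng.poisson(2, (8, 4)),
                           index=[f"bc{i}" for i in range(8)],
                           columns=[f"g{j}" for j in range(4)])
        from paraquant.cells import write_matrix
        write_matrix(mat, tmp_path / "m")
        back = read_matrix(tmp_path / "m")
        pd.testing.assert_frame_equal(back.astype(int), mat)
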