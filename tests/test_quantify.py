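"""Quantification: spot assignment, matrix building, QC filter semantics,
replicate correlation and clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from plantfish import quantify_cluster as qc
from plantfish.segmentation import SegmentationMask


@pytest.fixture
def toy_mask():
    """Two cells side by side: label 1 in x<8, label 2 in x>=8, all z/y."""
    labels = np.zeros((4, 8, 16), dtype=np.int32)
    labels[:, :, :8] = 1
    labels[:, :, 8:] = 2
    labels[:, 0, :] = 0  # a background stripe
    return SegmentationMask(labels, (0.42, 0.57, 0.57))


def _spots(rows):
    return pd.DataFrame(
        rows, columns=["z_um", "y_um", "x_um", "round", "channel", "intensity", "sigma", "gene"]
    )


def _matrix_from_totals(totals):
    counts = sparse.csr_matrix(np.asarray(totals, dtype=np.int64)[:, None])
    cells = pd.DataFrame({"label": np.arange(1, len(totals) + 1)})
    return qc.CellByGeneMatrix(counts, ["g"], cells)


class TestAssignSpots:
    def test_cell_interior_background_and_outside(self, toy_mask):
        spots = _spots(
            [
                (0.84, 1.71, 2.0, 1, 1, 1.0, 0.5, "gA"),   # inside cell 1
                (0.84, 1.71, 6.0, 1, 1, 1.0, 0.5, "gA"),   # inside cell 2
                (0.84, 0.0, 2.0, 1, 1, 1.0, 0.5, "gB"),    # background stripe
                (50.0, 1.71, 2.0, 1, 1, 1.0, 0.5, "gB"),   # outside the volume
            ]
        )
        out = qc.assign_spots(spots, toy_mask)
        assert list(out["cell"]) == [1, 2, 0, 0]
        assert list(out["assigned"]) == [True, True, False, False]
        assert list(out["in_volume"]) == [True, True, True, False]
        assert out.attrs["n_outside_volume"] == 1
        assert len(out) == len(spots)  # conservation: nothing dropped

    def test_matched_true_positives_land_in_their_cell(self, small_experiment):
        from plantfish import validation as val
        from plantfish.pipeline import run_pipeline

        exp = small_experiment
        res = run_pipeline(exp.acquisitions, exp.codebook, seed=0, cluster=False)
        truth_mask = SegmentationMask(exp.tissue.label_volume, exp.tissue.voxel_size)
        assignments = qc.assign_spots(res.spots, truth_mask)
        truth = exp.truth.true_spots[exp.truth.true_spots["in_fov"]]
        matches = val.match_spots(res.spots, truth, exp.tissue.voxel_size)
        acc = val.assignment_accuracy(assignments, matches, exp.truth.true_spots)
        assert acc >= 0.90


class TestBuildMatrix:
    def test_matches_groupby_oracle(self, rng, toy_mask):
        genes = ["gA", "gB", "gC"]
        n = 200
        table = pd.DataFrame(
            {
                "cell": rng.integers(0, 3, n),
                "gene": rng.choice(genes, n),
            }
        )
        table["assigned"] = table["cell"] > 0
        m = qc.build_matrix(table, genes, toy_mask)
        oracle = (
            table[table.assigned].groupby(["cell", "gene"]).size().unstack(fill_value=0)
        )
        for cell_label in (1, 2):
            for g in genes:
                row = m.cells.index[m.cells["label"] == cell_label][0]
                assert m.dense()[row, genes.index(g)] == oracle.loc[cell_label].get(g, 0)
        assert m.counts.sum() == int(table.assigned.sum())

    def test_empty_assignments_give_zero_matrix(self, toy_mask):
        table = pd.DataFrame({"cell": [], "gene": [], "assigned": []})
        m = qc.build_matrix(table, ["gA"], toy_mask)
        assert m.counts.sum() == 0 and m.n_cells == 2


class TestFilterCells:
    def test_paper_threshold_semantics(self):
        m = _matrix_from_totals(np.arange(21))  # totals 0..20
        kept = qc.filter_cells(m, min_spots=6)
        totals = np.asarray(kept.counts.sum(axis=1)).ravel()
        assert totals.min() == 6
        assert kept.n_cells == 15  # cells with 6..20

    def test_five_dropped_six_kept(self):
        m = _matrix_from_totals([5, 6])
        kept = qc.filter_cells(m)
        assert list(kept.cells["label"]) == [2]

    def test_zero_threshold_is_identity_and_idempotent(self):
        m = _matrix_from_totals([0, 3, 9])
        assert qc.filter_cells(m, 0).n_cells == 3
        once = qc.filter_cells(m, 6)
        twice = qc.filter_cells(once, 6)
        assert np.array_equal(once.dense(), twice.dense())


class TestQCSummaries:
    def test_zero_matrix(self):
        m = _matrix_from_totals([0, 0])
        s = qc.qc_summaries(m)
        assert s["total_molecules"] == 0
        assert s["median_molecules_per_cell"] == 0.0

    def test_molecule_and_gene_counts(self):
        counts = sparse.csr_matrix(np.array([[2, 1], [0, 0]]))
        m = qc.CellByGeneMatrix(counts, ["gA", "gB"], pd.DataFrame({"label": [1, 2]}))
        s = qc.qc_summaries(m)
        assert list(s["per_cell"]["molecules"]) == [3, 0]
        assert list(s["per_cell"]["genes_detected"]) == [2, 0]
        assert s["median_molecules_per_cell"] == 1.5
        assert s["per_gene_totals"].to_dict() == {"gA": 2, "gB": 1}


class TestReplicateCorrelation:
    def _sim_matrix(self, seed, n_cells=120, n_genes=12):
        rng = np.random.default_rng(seed)
        mu = np.linspace(0.5, 8.0, n_genes)
        counts = rng.poisson(mu, size=(n_cells, n_genes))
        return qc.CellByGeneMatrix(
            sparse.csr_matrix(counts), [f"g{i}" for i in range(n_genes)],
            pd.DataFrame({"label": np.arange(1, n_cells + 1)}),
        )

    def test_identical_samples_correlate_perfectly(self):
        m = self._sim_matrix(0)
        table = qc.replicate_correlation([m, m])
        assert table.iloc[0, 1] == pytest.approx(1.0)

    def test_replicates_from_one_program_correlate_highly(self):
        ms = [self._sim_matrix(s) for s in range(5)]
        table = qc.replicate_correlation(ms)
        off_diag = table.to_numpy()[~np.eye(5, dtype=bool)]
        assert off_diag.min() > 0.9

    def test_symmetric_unit_diagonal(self):
        ms = [self._sim_matrix(s) for s in (1, 2, 3)]
        table = qc.replicate_correlation(ms).to_numpy()
        assert np.allclose(table, table.T)
        assert np.allclose(np.diag(table), 1.0)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            qc.replicate_correlation([self._sim_matrix(0)])


class TestLogNormalize:
    def test_zero_preserving_and_monotone(self):
        counts = sparse.csr_matrix(np.array([[0, 1], [4, 9]]))
        m = qc.CellByGeneMatrix(counts, ["a", "b"], pd.DataFrame({"label": [1, 2]}))
        out = qc.log_normalize(m)
        assert out[0, 0] == 0.0
        assert np.allclose(out, np.log1p([[0, 1], [4, 9]]))


class TestCluster:
    def _two_program_matrix(self, seed=0, n=60, n_genes=10):
        rng = np.random.default_rng(seed)
        types = np.repeat(["A", "B"], n // 2)
        mu = np.where(
            (types[:, None] == "A") ^ (np.arange(n_genes)[None, :] >= n_genes // 2), 20.0, 0.0
        )
        counts = rng.poisson(mu)
        m = qc.CellByGeneMatrix(
            sparse.csr_matrix(counts), [f"g{i}" for i in range(n_genes)],
            pd.DataFrame({"label": np.arange(1, n + 1)}),
        )
        return m, types

    def test_two_programs_recovered_with_high_purity(self):
        from plantfish.validation import cluster_purity

        m, types = self._two_program_matrix()
        result = qc.embed_and_cluster(m, seed=0)
        assert result.cluster.nunique() >= 2
        assert cluster_purity(result.cluster.to_numpy(), types) >= 0.95
        # no cluster mixes the two programs
        df = pd.DataFrame({"c": result.cluster.to_numpy(), "t": types})
        mix = df.groupby("c")["t"].nunique()
        assert (mix == 1).all()

    def test_identical_cells_single_cluster(self):
        counts = sparse.csr_matrix(np.ones((20, 4), dtype=np.int64))
        m = qc.CellByGeneMatrix(
            counts, ["a", "b", "c", "d"], pd.DataFrame({"label": np.arange(1, 21)})
        )
        result = qc.embed_and_cluster(m, seed=0)
        assert result.cluster.nunique() == 1

    def test_cell_order_permutation_up_to_relabelling(self):
        m, types = self._two_program_matrix(seed=3)
        result = qc.embed_and_cluster(m, seed=0)
        perm = np.random.default_rng(1).permutation(m.n_cells)
        m2 = qc.CellByGeneMatrix(
            m.counts[perm], m.genes, m.cells.iloc[perm].reset_index(drop=True)
        )
        result2 = qc.embed_and_cluster(m2, seed=0)
        # partitions agree up to label names
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(
            result.cluster.to_numpy()[perm], result2.cluster.to_numpy()
        ) == pytest.approx(1.0)

    def test_heatmap_single_cluster_all_zero(self):
        counts = sparse.csr_matrix(np.ones((8, 3), dtype=np.int64))
        m = qc.CellByGeneMatrix(counts, ["a", "b", "c"], pd.DataFrame({"label": np.arange(1, 9)}))
        result = qc.embed_and_cluster(m, seed=0)
        table = qc.cluster_heatmap_table(result, m)
        assert np.allclose(table.to_numpy(), 0.0)

    def test_marker_genes_peak_in_their_program_cluster(self):
        m, types = self._two_program_matrix(seed=4)
        result = qc.embed_and_cluster(m, seed=0)
        table = qc.cluster_heatmap_table(result, m)
        cluster_type = (
            pd.DataFrame({"c": result.cluster.to_numpy(), "t": types})
            .groupby("c")["t"].agg(lambda s: s.mode()[0])
        )
        # genes 0..4 mark type A in this construction, 5..9 mark type B
        for g in range(5):
            assert cluster_type[table[f"g{g}"].idxmax()] == "A"
        for g in range(5, 10):
            assert cluster_type[table[f"g{g}"].idxmax()] == "B"
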