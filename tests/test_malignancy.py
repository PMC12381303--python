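"""CNV smoothing, instability/malignancy scoring and threshold search."""

import numpy as np
import pandas as pd
import pytest

from pdotme.core import ValidationError, normalize_log1p
from pdotme.malignancy import (
    CNVMatrix,
    call_tumor,
    genomic_instability,
    infer_cnv,
    malignancy_score,
    pam_silhouette_k,
)
from pdotme.simulate import design_cnv_benchmark, simulate_counts

from conftest import make_expr


def _toy_cnv(values: np.ndarray) -> CNVMatrix:
    n_cells, n_loci = values.shape
    return CNVMatrix(
        values=values.astype(float),
        locus_table=pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(n_loci)],
             "chromosome": ["chr1"] * n_loci,
             "position": np.arange(n_loci)}
        ),
        cell_ids=np.array([f"c{i}" for i in range(n_cells)]),
    )


class TestInferCnv:
    def test_identical_cells_give_exact_zeros(self):
        counts = np.tile(np.array([[4], [2], [8], [1], [6], [3]]), (1, 10))
        expr = make_expr(counts, chromosomes=["chr1"] * 6)
        cnv = infer_cnv(expr, list(expr.cell_ids[:3]), window=3)
        np.testing.assert_allclose(cnv.values, 0.0, atol=1e-12)

    def test_smoothing_matches_brute_force_shrinking_window(self):
        """Centered moving average with edge-shrinking span, per chromosome."""
        rng = np.random.default_rng(0)
        counts = rng.poisson(5, (9, 12)) + 1
        expr = make_expr(counts, chromosomes=["chr1"] * 9)
        normalize_log1p(expr)
        window = 9
        cnv = infer_cnv(expr, list(expr.cell_ids[:4]), window=window)
        norm = expr.dense_normalized()
        rel = (norm - norm[:, :4].mean(axis=1, keepdims=True)) / np.log(2)
        half = window // 2
        brute = np.empty((12, 9))
        for c in range(12):
            for j in range(9):
                lo, hi = max(0, j - half), min(8, j + half)
                brute[c, j] = rel[lo : hi + 1, c].mean()
            brute[c] -= np.median(brute[c])
        np.testing.assert_allclose(cnv.values, brute, atol=1e-12)

    def test_gene_order_permutation_invariant(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(4, (30, 15)) + 1
        chroms = ["chr1"] * 15 + ["chr2"] * 15
        expr = make_expr(counts, chromosomes=chroms)
        cnv = infer_cnv(expr, list(expr.cell_ids[:5]), window=5)

        perm = rng.permutation(30)
        expr2 = make_expr(counts[perm], chromosomes=[chroms[i] for i in perm],
                          starts=(np.arange(1, 31) * 100)[perm])
        expr2.gene_table["gene_id"] = [f"G{i:04d}" for i in perm]
        expr2.gene_table["symbol"] = expr2.gene_table["gene_id"]
        cnv2 = infer_cnv(expr2, list(expr2.cell_ids[:5]), window=5)
        np.testing.assert_allclose(cnv.values, cnv2.values, atol=1e-12)
        assert list(cnv.locus_table["gene_id"]) == list(cnv2.locus_table["gene_id"])

    def test_empty_reference_rejected(self, small_expr):
        with pytest.raises(ValidationError, match="reference"):
            infer_cnv(small_expr, [], window=3)

    def test_window_larger_than_every_chromosome_rejected(self, small_expr):
        with pytest.raises(ValidationError, match="window"):
            infer_cnv(small_expr, list(small_expr.cell_ids[:3]), window=51)


class TestGenomicInstability:
    def test_identical_cells_score_zero(self):
        cnv = _toy_cnv(np.ones((4, 5)))
        np.testing.assert_allclose(genomic_instability(cnv), 0.0)

    def test_two_cells_single_variable_locus(self):
        # with sample-SD (ddof=1) scaling the two z values at the variable
        # locus are -1/sqrt(2) and +1/sqrt(2); squared 0.5, averaged over
        # the two loci (the constant one contributes 0) -> 0.25 per cell
        cnv = _toy_cnv(np.array([[-1.0, 0.0], [1.0, 0.0]]))
        np.testing.assert_allclose(genomic_instability(cnv), [0.25, 0.25])

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(7)
        values = rng.normal(size=(5, 4))
        values[:, 2] = 3.0  # zero-variance locus contributes 0
        cnv = _toy_cnv(values)
        scores = genomic_instability(cnv)

        brute = np.zeros(5)
        for c in range(5):
            acc = 0.0
            for l in range(4):
                col = values[:, l]
                sd = col.std(ddof=1)
                if sd > 0:
                    acc += ((values[c, l] - col.mean()) / sd) ** 2
            brute[c] = acc / 4
        np.testing.assert_allclose(scores, brute, atol=1e-12)

    def test_single_cell_rejected(self):
        with pytest.raises(ValidationError):
            genomic_instability(_toy_cnv(np.ones((1, 5))))

    def test_mean_score_equals_sample_variance_normalization(self):
        """With ddof=1 z-scaling, each variable locus' squared z values
        average to (n-1)/n over cells, hence so does the mean score."""
        rng = np.random.default_rng(3)
        values = rng.normal(size=(12, 6))
        scores = genomic_instability(_toy_cnv(values))
        assert scores.mean() == pytest.approx((12 - 1) / 12, abs=1e-12)


class TestMalignancyScore:
    def test_profile_matching_cell_scores_one(self):
        rng = np.random.default_rng(0)
        profile = rng.normal(size=20)
        values = np.vstack([profile, profile * 2 + 1, -profile, rng.normal(size=20)])
        cnv = _toy_cnv(values)
        gis = np.array([10.0, 9.0, 0.1, 0.2])  # top-2 cells define the profile
        scores = malignancy_score(cnv, gis, top_fraction=0.5)
        # cells 0 and 1 are both affine images of the profile -> correlation 1
        assert scores[0] == pytest.approx(1.0)
        assert scores[1] == pytest.approx(1.0)
        assert scores[2] == pytest.approx(-1.0)

    def test_zero_variance_row_scores_zero(self):
        values = np.vstack([np.ones(10), np.arange(10.0), -np.arange(10.0)])
        cnv = _toy_cnv(values)
        scores = malignancy_score(cnv, np.array([0.0, 5.0, 4.0]), top_fraction=0.5)
        assert scores[0] == 0.0

    def test_small_patient_skipped_with_nan(self):
        values = np.random.default_rng(1).normal(size=(5, 8))
        cnv = _toy_cnv(values)
        patient = np.array(["a", "a", "a", "a", "b"])
        scores = malignancy_score(cnv, np.arange(5.0), patient=patient)
        assert np.isnan(scores[4])
        assert np.all(np.isfinite(scores[:4]))

    def test_tumor_cells_score_higher_than_normal(self):
        wins = 0
        for seed in range(6):
            d = design_cnv_benchmark(seed=seed, n_genes=800, n_epithelial=200, n_immune=50)
            expr, truth = simulate_counts(d)
            pop = truth.cell_table["population"].to_numpy()
            cnv = infer_cnv(expr, list(expr.cell_ids[pop == "immune"]), window=51)
            gis = genomic_instability(cnv)
            mal = malignancy_score(cnv, gis)
            is_tumor = truth.cell_table["is_tumor"].to_numpy()
            if mal[is_tumor].mean() > mal[~is_tumor].mean():
                wins += 1
        assert wins == 6


class TestCallTumor:
    def test_separated_blobs_recovered_exactly(self):
        rng = np.random.default_rng(2)
        n = 120
        member = rng.uniform(size=n) < 0.4
        gis = np.where(member, 6.0, 0.0) + rng.normal(0, 1, n)
        mal = np.where(member, 6.0, 0.0) + rng.normal(0, 1, n)
        call = call_tumor(gis, mal)
        assert call.silhouette > 0.7
        np.testing.assert_array_equal(call.label == "tumor", member)

    def test_selected_silhouette_is_grid_maximum(self):
        rng = np.random.default_rng(3)
        gis = rng.normal(size=60) + np.repeat([0, 3], 30)
        mal = rng.normal(size=60) + np.repeat([0, 3], 30)
        call = call_tumor(gis, mal, keep_grid=True)
        assert call.grid_silhouettes["silhouette"].max() == pytest.approx(call.silhouette)

    def test_constant_scores_rejected(self):
        with pytest.raises(ValidationError):
            call_tumor(np.ones(20), np.ones(20))

    def test_labels_consistent_with_cutoffs(self):
        rng = np.random.default_rng(4)
        gis = rng.normal(size=80) + np.repeat([0, 4], 40)
        mal = rng.normal(size=80) + np.repeat([0, 4], 40)
        call = call_tumor(gis, mal)
        expected = (gis > call.cutoffs[0]) & (mal > call.cutoffs[1])
        np.testing.assert_array_equal(call.label == "tumor", expected)

    def test_end_to_end_recovery_on_simulated_gain(self):
        from sklearn.metrics import balanced_accuracy_score

        d = design_cnv_benchmark(seed=11)
        expr, truth = simulate_counts(d)
        pop = truth.cell_table["population"].to_numpy()
        cnv = infer_cnv(expr, list(expr.cell_ids[pop == "immune"]))
        gis = genomic_instability(cnv)
        mal = malignancy_score(cnv, gis)
        call = call_tumor(gis, mal)
        acc = balanced_accuracy_score(truth.cell_table["is_tumor"], call.label == "tumor")
        assert acc >= 0.95


class TestPamSilhouetteK:
    def test_three_tight_clusters_select_k3(self):
        rng = np.random.default_rng(5)
        pts = np.concatenate(
            [rng.normal(c, 0.05, size=(15, 2)) for c in ((0, 0), (5, 0), (0, 5))]
        )
        k, labels = pam_silhouette_k(pts, range(2, 6))
        assert k == 3
        # exhaustive check on cluster purity: each true block uniform
        for block in range(3):
            assert len(set(labels[block * 15 : (block + 1) * 15])) == 1

    def test_pairs_stay_together_at_k2(self):
        pts = np.array([[0, 0], [0.1, 0], [5, 5], [5.1, 5]])
        k, labels = pam_silhouette_k(pts, [2])
        assert k == 2
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_duplicated_dataset_selects_same_k(self):
        rng = np.random.default_rng(6)
        pts = np.concatenate([rng.normal(c, 0.1, size=(10, 2)) for c in ((0, 0), (4, 4))])
        k1, _ = pam_silhouette_k(pts, range(2, 5))
        k2, _ = pam_silhouette_k(np.vstack([pts, pts]), range(2, 5))
        assert k1 == k2 == 2

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            pam_silhouette_k(np.zeros((2, 2)), [2])
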