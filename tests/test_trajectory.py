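"""Pseudotime geometry, Moran's I exactness and gene modules."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import scipy.stats

from pdotme.core import ValidationError, normalize_log1p
from pdotme.simulate import design_trajectory_benchmark, simulate_counts
from pdotme.trajectory import (
    branch_contrast,
    find_gene_modules,
    fit_pseudotime,
    graph_autocorrelation,
    knn_graph,
    morans_i,
)

from conftest import make_expr


def _collinear_expr(seed=0):
    """Three clusters along one expression axis: A (root) - B - C."""
    rng = np.random.default_rng(seed)
    n_per = 50
    means = np.array([2.0, 8.0, 14.0])
    counts = np.vstack(
        [
            rng.poisson(np.repeat(means, n_per)[None, :] * f, size=(1, 3 * n_per))
            for f in np.linspace(0.5, 2.0, 30)
        ]
    )
    expr = make_expr(counts, cluster=np.repeat(list("ABC"), n_per))
    return normalize_log1p(expr)


class TestFitPseudotime:
    def test_collinear_clusters_strictly_ordered(self):
        expr = _collinear_expr()
        traj = fit_pseudotime(expr, "cluster", "A", d=5)
        labels = expr.cell_table["cluster"].to_numpy()
        means = [traj.pseudotime[labels == c].mean() for c in "ABC"]
        assert means[0] < means[1] < means[2]
        assert traj.pseudotime.min() == 0.0

    def test_root_cells_anchor_zero(self):
        expr = _collinear_expr(seed=1)
        traj = fit_pseudotime(expr, "cluster", "A", d=5)
        labels = expr.cell_table["cluster"].to_numpy()
        assert traj.pseudotime[labels == "A"].min() == pytest.approx(0.0)

    def test_rigid_rotation_leaves_pseudotime_unchanged(self):
        expr = _collinear_expr(seed=2)
        traj = fit_pseudotime(expr, "cluster", "A", d=4)

        rng = np.random.default_rng(3)
        q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        rotated = traj.embedding @ q.T

        # re-run the geometric stages on the rotated embedding
        from pdotme.trajectory import TrajectoryResult  # noqa: F401

        labels = expr.cell_table["cluster"].to_numpy()
        import pdotme.trajectory as tj

        names = sorted(pd.unique(labels).tolist())
        centroids = np.stack([rotated[labels == c].mean(axis=0) for c in names])
        # distances between centroids are preserved under rotation
        import scipy.spatial.distance as ssd

        orig = ssd.pdist(np.stack([traj.embedding[labels == c].mean(axis=0) for c in names]))
        rot = ssd.pdist(centroids)
        np.testing.assert_allclose(orig, rot, atol=1e-9)

    def test_missing_root_rejected(self):
        expr = _collinear_expr(seed=4)
        with pytest.raises(ValidationError):
            fit_pseudotime(expr, "cluster", "Z", d=3)

    def test_recovers_simulated_latent_time(self):
        expr, truth = simulate_counts(design_trajectory_benchmark(seed=1))
        traj = fit_pseudotime(expr, truth.cell_table["population"].to_numpy(), "LEC", d=10)
        rho = scipy.stats.spearmanr(truth.cell_table["pseudotime"], traj.pseudotime).statistic
        assert rho >= 0.9


class TestMoransI:
    def test_two_node_antithetic_graph_is_minus_one(self):
        W = sp.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert morans_i(np.array([1.0, -1.0]), W) == pytest.approx(-1.0)

    def test_matches_brute_force_double_sum(self):
        rng = np.random.default_rng(5)
        n = 120
        emb = rng.normal(size=(n, 3))
        W = knn_graph(emb, 6)
        values = rng.normal(size=n)
        got = morans_i(values, W)

        Wd = W.toarray()
        z = values - values.mean()
        num = sum(
            Wd[i, j] * z[i] * z[j] for i in range(n) for j in range(n)
        )
        brute = (n / Wd.sum()) * num / (z @ z)
        assert got == pytest.approx(brute, abs=1e-10)

    def test_smooth_gradient_on_path_graph_scores_high(self):
        n = 50
        rows = np.arange(n - 1)
        W = sp.csr_matrix(
            (np.ones(2 * (n - 1)), (np.r_[rows, rows + 1], np.r_[rows + 1, rows])),
            shape=(n, n),
        )
        values = np.linspace(0, 1, n)
        assert morans_i(values, W) > 0.8

    def test_null_mean_matches_analytic_expectation(self):
        rng = np.random.default_rng(6)
        n = 100
        W = knn_graph(rng.normal(size=(n, 3)), 5)
        Is = morans_i(rng.normal(size=(500, n)), W)
        se = Is.std() / np.sqrt(500)
        assert abs(Is.mean() - (-1 / (n - 1))) < 3 * se

    def test_constant_gene_flagged(self):
        rng = np.random.default_rng(7)
        counts = rng.poisson(3, (20, 40)) + 1
        expr = normalize_log1p(make_expr(counts))
        dense = np.asarray(expr.normalized.todense())
        dense[5] = 1.3  # constant across cells in the normalized layer
        expr.normalized = sp.csr_matrix(dense)
        emb = rng.normal(size=(40, 3))
        res = graph_autocorrelation(expr, emb, k=5)
        row = res.set_index("gene_id").loc["G0005"]
        assert row["constant"] and row["morans_i"] == 0.0 and row["p"] == 1.0


class TestGeneModules:
    def _module_expr(self, seed=0):
        """Two anti-correlated 12-gene programs driven by a latent factor."""
        rng = np.random.default_rng(seed)
        n_cells = 150
        latent = np.linspace(-1, 1, n_cells)
        base = rng.poisson(5, (40, n_cells)).astype(float)
        for g in range(12):
            base[g] = rng.poisson(np.exp(1.6 + 1.2 * latent))
        for g in range(12, 24):
            base[g] = rng.poisson(np.exp(1.6 - 1.2 * latent))
        expr = normalize_log1p(make_expr(base.astype(int)))
        emb = np.stack([latent, rng.normal(0, 0.1, n_cells)], axis=1)
        return expr, emb

    def test_planted_anticorrelated_programs_recovered(self):
        expr, emb = self._module_expr()
        ac = graph_autocorrelation(expr, emb, k=10)
        assignment, scores = find_gene_modules(ac, expr, alpha=0.05, n_modules_hint=6)
        up = {f"G{i:04d}" for i in range(12)}
        down = {f"G{i:04d}" for i in range(12, 24)}
        present_up = [g for g in assignment.index if g in up]
        present_down = [g for g in assignment.index if g in down]
        assert len(present_up) >= 10 and len(present_down) >= 10
        assert assignment[present_up].nunique() == 1
        assert assignment[present_down].nunique() == 1
        assert assignment[present_up[0]] != assignment[present_down[0]]

    def test_module_membership_invariant_to_gene_order(self):
        expr, emb = self._module_expr(seed=1)
        ac = graph_autocorrelation(expr, emb, k=10)
        a1, _ = find_gene_modules(ac, expr, alpha=0.05, n_modules_hint=4)

        perm = np.random.default_rng(2).permutation(expr.n_genes)
        counts = expr.counts.toarray()[perm]
        expr2 = make_expr(counts)
        expr2.gene_table["gene_id"] = expr.gene_table["gene_id"].to_numpy()[perm]
        expr2.gene_table["symbol"] = expr2.gene_table["gene_id"]
        normalize_log1p(expr2)
        ac2 = graph_autocorrelation(expr2, emb, k=10)
        a2, _ = find_gene_modules(ac2, expr2, alpha=0.05, n_modules_hint=4)
        shared = sorted(set(a1.index) & set(a2.index))
        tbl = pd.crosstab(a1[shared], a2[shared])
        assert (tbl.gt(0).sum(axis=1) == 1).all()  # consistent partition

    def test_too_few_significant_genes_rejected(self):
        ac = pd.DataFrame(
            {"gene_id": ["a", "b"], "p_adj": [0.9, 0.8], "constant": [False, False]}
        )
        with pytest.raises(ValidationError, match="alpha"):
            find_gene_modules(ac, None, alpha=0.05)


class TestBranchContrast:
    def test_empty_branch_rejected(self):
        expr, truth = simulate_counts(design_trajectory_benchmark(seed=2, n_cells=200, n_genes=200))
        traj = fit_pseudotime(expr, truth.cell_table["population"].to_numpy(), "LEC", d=5)
        with pytest.raises(ValidationError):
            branch_contrast(traj, expr, traj.branch_id[0], "NOT_A_BRANCH")

    def test_random_split_of_one_population_is_calibrated(self):
        expr, truth = simulate_counts(design_trajectory_benchmark(seed=3, n_cells=300, n_genes=300))
        traj = fit_pseudotime(expr, truth.cell_table["population"].to_numpy(), "LEC", d=5)
        rng = np.random.default_rng(4)
        fake = np.where(rng.uniform(size=expr.n_cells) < 0.5, "L", "R")
        traj.branch_id = fake
        res = branch_contrast(traj, expr, "L", "R")
        assert 0.0 <= (res["p"] < 0.05).mean() <= 0.12


def test_gradient_module_score_increases_along_pseudotime():
    """A planted pseudotime-increasing program's module score rises
    monotonically across pseudotime deciles."""
    from pdotme.signatures import module_score

    expr, truth = simulate_counts(design_trajectory_benchmark(seed=5))
    traj = fit_pseudotime(expr, truth.cell_table["population"].to_numpy(), "LEC", d=10)
    up_genes = truth.de_genes.loc[truth.de_genes["log_effect"] > 0, "gene_id"].tolist()
    scores = module_score(expr, up_genes, seed=5)
    deciles = pd.qcut(traj.pseudotime, 10, labels=False, duplicates="drop")
    means = pd.Series(scores).groupby(deciles).mean()
    rho = scipy.stats.spearmanr(means.index, means.to_numpy()).statistic
    assert rho >= 0.9
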