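"""Module scoring controls, composite signature and group statistics."""

import numpy as np
import pytest
import scipy.stats

from pdotme.core import ValidationError, normalize_log1p
from pdotme.diffexpr import hurdle_de
from pdotme.signatures import (
    build_composite_signature,
    cross_signature_correlation,
    module_score,
    score_group_test,
)
from pdotme.simulate import Population, SimulationDesign, simulate_counts

from conftest import make_expr


class TestModuleScore:
    def test_full_gene_universe_scores_zero(self, small_expr):
        genes = list(small_expr.gene_table["symbol"])
        scores = module_score(small_expr, genes, n_bins=5, n_ctrl=10, seed=0)
        np.testing.assert_allclose(scores, 0.0, atol=1e-12)

    def test_constant_matrix_scores_zero(self):
        expr = normalize_log1p(make_expr(np.full((30, 10), 2)))
        scores = module_score(expr, ["G0001", "G0002"], n_bins=5, n_ctrl=20, seed=0)
        np.testing.assert_allclose(scores, 0.0, atol=1e-12)

    def test_invariant_to_per_cell_offsets(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(4, (40, 25)) + 1
        expr = normalize_log1p(make_expr(counts))
        base = module_score(expr, ["G0003", "G0010", "G0020"], n_bins=4, n_ctrl=30, seed=1)
        shifted = expr
        shifted.normalized = shifted.normalized.tocsr()
        dense = np.asarray(shifted.normalized.todense()) + rng.uniform(0, 2, 25)[None, :]
        import scipy.sparse as sp

        shifted.normalized = sp.csr_matrix(dense)
        after = module_score(shifted, ["G0003", "G0010", "G0020"], n_bins=4, n_ctrl=30, seed=1)
        np.testing.assert_allclose(after - base, (after - base)[0], atol=1e-9)

    def test_planted_program_scores_higher_in_its_population(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed + 100)
            program = {int(g): 1.0 for g in rng.choice(200, 50, replace=False)}
            design = SimulationDesign(
                n_genes=200, n_chromosomes=2, n_patients=1, conditions=("UT",),
                populations=(
                    Population("A", False, {"UT": 0.5}, program),
                    Population("B", False, {"UT": 0.5}),
                ),
                cells_per_sample=200, seed=seed,
            )
            expr, truth = simulate_counts(design)
            genes = [f"G{g:05d}" for g in program]
            scores = module_score(expr, genes, seed=seed)
            pop = truth.cell_table["population"].to_numpy()
            if scores[pop == "A"].mean() - scores[pop == "B"].mean() > 0.5:
                hits += 1
        assert hits == 20

    def test_missing_genes_rejected(self, small_expr):
        with pytest.raises(ValidationError, match="missing"):
            module_score(small_expr, ["NOT_A_GENE"])


class TestCompositeSignature:
    def _de_table(self, log_fcs, ps):
        import pandas as pd

        return pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(len(log_fcs))], "log_fc": log_fcs, "p": ps}
        )

    def test_exactly_n_positive_genes_all_returned_by_p(self):
        de = self._de_table([0.5] * 100 + [-0.2] * 20, list(np.linspace(0.001, 0.1, 120)))
        up, down = build_composite_signature(de, n_top=100)
        assert len(up) == 100
        assert up == [f"g{i}" for i in range(100)]

    def test_all_negative_gives_empty_up_list(self):
        de = self._de_table([-0.5, -0.1], [0.01, 0.02])
        up, down = build_composite_signature(de, n_top=100)
        assert up == []
        assert down == ["g0", "g1"]

    def test_lists_are_disjoint(self):
        rng = np.random.default_rng(1)
        de = self._de_table(rng.normal(size=300), rng.uniform(size=300))
        up, down = build_composite_signature(de, n_top=50)
        assert not set(up) & set(down)

    def test_recovers_planted_up_genes(self):
        design = SimulationDesign(
            n_genes=500, n_chromosomes=5, n_patients=1, conditions=("NDexo", "T2Dexo"),
            populations=(
                Population("nd", False, {"NDexo": 1.0, "T2Dexo": 0.0}),
                Population("t2d", False, {"NDexo": 0.0, "T2Dexo": 1.0},
                           {g: 1.5 for g in range(150)}),
            ),
            cells_per_sample=1000, seed=2,
        )
        expr, truth = simulate_counts(design)
        de = hurdle_de(expr, "treatment", group_levels=("NDexo", "T2Dexo"))
        up, _ = build_composite_signature(de, n_top=100)
        true_up = {f"G{i:05d}" for i in range(150)}
        assert len(set(up) & true_up) >= 90


class TestScoreGroupTest:
    def test_single_batch_equals_plain_linear_model(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=200)
        group = np.repeat(["a", "b"], 100)
        scores[100:] += 0.5
        eff1, p1 = score_group_test(scores, group)
        eff2, p2 = score_group_test(scores, group, batch=np.repeat("x", 200))
        assert eff1 == pytest.approx(eff2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_recovers_unit_shift_with_batches(self):
        rng = np.random.default_rng(4)
        n = 6000  # SE of the contrast ~0.037, so the 0.1 band is ~2.7 sigma
        batch = np.tile(["b1", "b2", "b3"], n // 3)
        batch_eff = {"b1": -0.3, "b2": 0.0, "b3": 0.3}
        group = np.repeat(["g1", "g2"], n // 2)
        scores = rng.normal(0, 1, n) + np.vectorize(batch_eff.get)(batch)
        scores[group == "g2"] += 1.0
        eff, p = score_group_test(scores, group, batch)
        assert eff == pytest.approx(1.0, abs=0.1)
        assert p < 1e-10

    def test_null_permutations_calibrated(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=120)
        batch = np.tile(["b1", "b2", "b3"], 40)
        ps = []
        for _ in range(300):
            group = rng.permutation(np.repeat(["a", "b"], 60))
            ps.append(score_group_test(scores, group, batch)[1])
        assert scipy.stats.kstest(ps, "uniform").pvalue > 0.01

    def test_constant_scores_flagged(self):
        eff, p = score_group_test(np.ones(50), np.repeat(["a", "b"], 25))
        assert (eff, p) == (0.0, 1.0)


class TestCrossSignatureCorrelation:
    def test_identity_and_reversal(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=30)
        assert cross_signature_correlation(a, a)[0] == pytest.approx(1.0)
        assert cross_signature_correlation(a, -a)[0] == pytest.approx(-1.0)

    def test_matches_brute_force_rank_correlation(self):
        a = np.array([3.1, 1.2, 5.5, 2.2, 9.9, 0.1, 4.4, 7.7, 6.6, 8.8, 2.2, 5.5])
        b = np.array([1.0, 2.0, 1.5, 4.0, 0.5, 6.0, 3.3, 2.5, 1.1, 0.9, 4.0, 1.5])
        rho, _ = cross_signature_correlation(a, b)

        def avg_ranks(x):
            order = np.argsort(x, kind="stable")
            ranks = np.empty(len(x))
            i = 0
            sx = x[order]
            while i < len(x):
                j = i
                while j < len(x) and sx[j] == sx[i]:
                    j += 1
                ranks[order[i:j]] = (i + j - 1) / 2 + 1
                i = j
            return ranks

        ra, rb = avg_ranks(a), avg_ranks(b)
        brute = np.corrcoef(ra, rb)[0, 1]
        assert rho == pytest.approx(brute, abs=1e-12)

    def test_constant_vector_flagged(self):
        rho, p = cross_signature_correlation(np.ones(20), np.arange(20.0))
        assert np.isnan(rho) and p == 1.0
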