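import numpy as np
import pytest

import dtni
from dtni.inference import (DOSE_EQ, TIME_EQ, assemble_system,
                            estimate_interactions, reduce_dimension)


class TestAssembly:
    def test_row_count_matches_design(self, noise_tensor):
        """n-independent row count: n_time_grid rows per dose-course plus
        n_dose_grid rows per time-course, per compound and replicate."""
        system = assemble_system(noise_tensor, n_time_grid=20, n_dose_grid=10)
        n_time_rows = 20 * 3 * 1 * 2     # grid x doses x compounds x reps
        n_dose_rows = 10 * 3 * 1 * 2     # grid x times x compounds x reps
        assert int((system.block_labels == TIME_EQ).sum()) == n_time_rows
        assert int((system.block_labels == DOSE_EQ).sum()) == n_dose_rows
        assert system.n_rows == n_time_rows + n_dose_rows

    def test_time_only_system_equals_tsni_assembly(self, noise_tensor):
        dose_off = assemble_system(noise_tensor, include_dose_equations=False)
        assert not dose_off.has_dose_block
        assert np.all(dose_off.block_labels == TIME_EQ)
        # one u column per compound, no exposure-time columns
        assert dose_off.X.shape[1] == noise_tensor.n_genes + 1

    def test_constant_in_dose_gives_zero_dose_responses(self):
        values = np.ones((2, 3, 3, 1, 1)) * np.array(
            [1.0, 2.0, 3.0])[None, :, None, None, None]
        tensor = dtni.ExpressionTensor(["g1", "g2"], [2, 8, 24],
                                       [[1, 5, 25]], ["c"], values)
        system = assemble_system(tensor)
        dose_rows = system.block_labels == DOSE_EQ
        assert np.allclose(system.Y[dose_rows], 0.0, atol=1e-12)

    def test_dose_equations_need_three_doses(self):
        rng = np.random.default_rng(0)
        tensor = dtni.ExpressionTensor(["g1"], [2, 8, 24], [[1, 5]], ["c"],
                                       rng.normal(size=(1, 3, 2, 1, 1)))
        with pytest.raises(ValueError, match="3 dose"):
            assemble_system(tensor)
        assemble_system(tensor, include_dose_equations=False)  # TSNI path ok


class TestReduction:
    def test_rank_one_state_reconstructed_exactly(self, noise_tensor):
        system = assemble_system(noise_tensor)
        G = system.gene_block()
        # force a rank-1 gene block
        u, s, vt = np.linalg.svd(G, full_matrices=False)
        system.X[:, :system.n_genes] = s[0] * np.outer(u[:, 0], vt[0])
        reduced = reduce_dimension(system, 1)
        back = reduced.design[:, :1] @ reduced.V_k.T
        assert np.allclose(back, system.gene_block(), atol=1e-10)

    def test_full_rank_equals_minimum_norm_least_squares(self, dense_cascade_tensor):
        system = assemble_system(dense_cascade_tensor, smoothing=None,
                                 include_dose_equations=False)
        model = estimate_interactions(reduce_dimension(system, "full"))
        coef = np.linalg.pinv(system.X) @ system.Y
        direct_A = coef[:system.n_genes].T
        assert np.allclose(model.A, direct_A, atol=1e-8)

    def test_k_clamped_to_rank_with_warning(self, noise_tensor, caplog):
        system = assemble_system(noise_tensor)
        with caplog.at_level("WARNING", logger="dtni.inference"):
            reduced = reduce_dimension(system, 999)
        assert reduced.k <= min(system.n_rows, system.n_genes)
        assert any("clamp" in r.message for r in caplog.records)

    def test_auto_keeps_dominant_variance(self, noise_tensor):
        system = assemble_system(noise_tensor)
        reduced = reduce_dimension(system, "auto")
        s = reduced.singular_values
        kept = np.sum(s[: reduced.k] ** 2) / np.sum(s ** 2)
        assert kept >= 0.999


class TestEstimation:
    def test_single_gene_decay_rate_recovered(self):
        times = np.linspace(0.1, 5.0, 60)
        values = np.exp(-times)[None, :, None, None, None]
        tensor = dtni.ExpressionTensor(["g1"], times, [[1.0]], ["c"], values)
        res = dtni.TSNI(tensor, smoothing=None, n_time_grid=120).fit(permute=False)
        assert abs(res.A[0, 0] + 1.0) < 0.02

    def test_all_zero_responses_give_zero_model(self):
        values = np.zeros((2, 3, 3, 1, 1))
        tensor = dtni.ExpressionTensor(["g1", "g2"], [2, 8, 24],
                                       [[1, 5, 25]], ["c"], values)
        res = dtni.DTNI(tensor).fit(permute=False)
        assert np.allclose(res.A, 0.0)
        assert np.allclose(res.model.b, 0.0)
        assert np.allclose(res.model.h, 0.0)

    def test_cascade_recovered_from_dense_noiseless_data(
            self, cascade, dense_cascade_tensor):
        A, _, _ = cascade
        res = dtni.TSNI(dense_cascade_tensor, smoothing=None,
                        n_time_grid=80, k="full").fit(permute=False)
        rel = np.linalg.norm(res.A - A) / np.linalg.norm(A)
        assert rel < 0.05

    def test_residuals_consistent_with_fit(self, noise_tensor):
        system = assemble_system(noise_tensor)
        model = estimate_interactions(reduce_dimension(system, "auto"))
        assert np.allclose(model.residuals,
                           system.Y - model.fitted_values, atol=1e-12)

    def test_grid_refinement_stability(self, cascade):
        """Doubling the interpolation grid changes the estimate by < 5%
        relative Frobenius norm on noiseless linear-ODE data."""
        A, b, _ = cascade
        tensor = dtni.simulate_linear_dataset(
            A, b, times=np.linspace(0.2, 8, 40), doses=[1, 5, 25],
            noise=dtni.NoiseModel(0.0, 1))
        res1 = dtni.TSNI(tensor, smoothing=None, n_time_grid=60,
                         k="full").fit(permute=False)
        res2 = dtni.TSNI(tensor, smoothing=None, n_time_grid=120,
                         k="full").fit(permute=False)
        rel = (np.linalg.norm(res1.A - res2.A) / np.linalg.norm(res1.A))
        assert rel < 0.05


class TestModelInterface:
    def test_tsni_equals_dtni_without_dose_block(self, noise_tensor):
        a = dtni.TSNI(noise_tensor).fit(n_perm=20, seed=0)
        b = dtni.DTNI(noise_tensor, dose_equations=False).fit(n_perm=20, seed=0)
        assert np.allclose(a.A, b.A)
        assert np.allclose(a.p_values, b.p_values)

    def test_multi_compound_pooling_single_shared_matrix(self):
        rng = np.random.default_rng(0)
        tensor = dtni.ExpressionTensor(
            ["g1", "g2"], [2, 8, 24], [[1, 5, 25], [2, 10, 50]], ["a", "b"],
            rng.normal(size=(2, 3, 3, 2, 2)))
        res = dtni.DTNI(tensor).fit(permute=False)
        assert res.A.shape == (2, 2)
        assert res.model.b.shape == (2, 2)   # one input coefficient per compound
        assert res.model.h.shape == (2, 2)

    def test_scale_equivariance_of_edge_ranking(self, nfkb_tensor):
        res1 = dtni.DTNI(nfkb_tensor).fit(permute=False)
        scaled = dtni.ExpressionTensor(
            list(nfkb_tensor.genes), nfkb_tensor.times.copy(),
            nfkb_tensor.doses.copy(), list(nfkb_tensor.compounds),
            nfkb_tensor.values * 7.5)
        res2 = dtni.DTNI(scaled).fit(permute=False)
        off = ~np.eye(len(res1.genes), dtype=bool)
        order1 = np.argsort(-np.abs(res1.A[off]))
        order2 = np.argsort(-np.abs(res2.A[off]))
        assert np.array_equal(order1, order2)

    def test_summary_mentions_method_and_edges(self, noise_tensor):
        res = dtni.TSNI(noise_tensor).fit(n_perm=20, seed=1)
        text = res.summary()
        assert "TSNI results" in text
        assert "significant interactions" in text

    def test_run_log_records_choices(self, noise_tensor, tmp_path):
        import json
        res = dtni.DTNI(noise_tensor).fit(n_perm=20, seed=3)
        res.save_run_log(tmp_path / "log.json")
        log = json.loads((tmp_path / "log.json").read_text())
        for key in ("method", "k_used", "n_perm", "seed", "scale_factors"):
            assert key in log
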