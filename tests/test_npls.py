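import numpy as np
import pytest

from smoothpls.npls import (materialize_coefficients, npls_fit, npls_predict,
                            rank_one_approx)
from smoothpls.synthetic import (SyntheticConfig, gen_feature_tensor,
                                 gen_trajectory)

from _oracles import als_rank_one_objective, matrix_pls_coefficients


class TestRankOneApprox:
    def test_exact_rank_one_input_recovered(self, rng):
        a, b, c = rng.standard_normal(4), rng.standard_normal(5), rng.standard_normal(3)
        Z = np.einsum("i,j,k->ijk", a, b, c)
        w1, w2, w3 = rank_one_approx(Z)
        for w, v in ((w1, a), (w2, b), (w3, c)):
            assert abs(abs(w @ (v / np.linalg.norm(v)))) == pytest.approx(1.0, abs=1e-10)
        obj = abs(np.einsum("ijk,i,j,k->", Z, w1, w2, w3))
        assert obj == pytest.approx(
            np.linalg.norm(a) * np.linalg.norm(b) * np.linalg.norm(c), rel=1e-10)

    def test_single_nonzero_cell_gives_basis_vectors(self):
        Z = np.zeros((3, 4, 5))
        Z[1, 2, 3] = -2.0
        w1, w2, w3 = rank_one_approx(Z)
        assert np.allclose(np.abs(w1), np.eye(3)[1])
        assert np.allclose(np.abs(w2), np.eye(4)[2])
        assert np.allclose(np.abs(w3), np.eye(5)[3])

    def test_matches_multirestart_als_oracle(self):
        Z = np.random.default_rng(42).standard_normal((3, 4, 5))
        w1, w2, w3 = rank_one_approx(Z)
        obj = abs(np.einsum("ijk,i,j,k->", Z, w1, w2, w3))
        assert obj == pytest.approx(als_rank_one_objective(Z), abs=1e-6)

    def test_sign_convention_first_nonzero_positive(self, rng):
        Z = rng.standard_normal((3, 4, 5))
        for w in rank_one_approx(Z):
            nz = np.flatnonzero(np.abs(w) > 1e-12)
            assert w[nz[0]] > 0

    def test_all_zero_block_raises(self):
        with pytest.raises(ValueError, match="zero"):
            rank_one_approx(np.zeros((2, 2, 2)))


class TestNplsFit:
    def test_noiseless_rank_one_training_correlation_is_one(self, rng):
        a = rng.standard_normal(5); b = rng.standard_normal(4); c = rng.standard_normal(3)
        y = rng.standard_normal(40)
        X = np.einsum("n,i,j,k->nijk", y, a, b, c)
        model = npls_fit(X, y[:, None], 1)
        pred = npls_predict(model, X)[:, 0]
        assert np.corrcoef(pred, y)[0, 1] == pytest.approx(1.0, abs=1e-8)
        for w, v in ((model.W1[:, 0], a), (model.W2[:, 0], b), (model.W3[:, 0], c)):
            assert abs(w @ (v / np.linalg.norm(v))) == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("F", [1, 2, 3])
    def test_singleton_modes_match_matrix_pls_oracle(self, rng, F):
        X = rng.standard_normal((50, 24))
        Y = rng.standard_normal((50, 3))
        model = npls_fit(X[:, :, None, None], Y, F)
        B_ref = matrix_pls_coefficients(X, Y, F)
        assert np.allclose(model.B_full.reshape(24, 3), B_ref, atol=1e-8)

    def test_recovery_easy_heldout_correlation(self):
        # full-rank mixing (3 factors onto 3 coordinates) so a correct fit
        # can explain every coordinate
        cfg = SyntheticConfig(n_epochs=400, dims=(6, 5, 8), n_factors=3,
                              snr=10.0, noise_ar=0.2)
        traj = gen_trajectory(cfg, 0)
        tensor = gen_feature_tensor(traj, cfg, 0)
        X, Y = tensor.values, traj.values
        model = npls_fit(X[:280], Y[:280], 3)
        pred = npls_predict(model, X[280:])
        rs = [np.corrcoef(pred[:, j], Y[280:, j])[0, 1] for j in range(3)]
        assert np.mean(rs) >= 0.9

    def test_training_y_residual_non_increasing_in_factors(self, random_pair):
        X, Y = random_pair
        norms = [npls_fit(X, Y, F).residual_norms["y"] for F in range(0, 5)]
        assert all(n2 <= n1 + 1e-10 for n1, n2 in zip(norms, norms[1:]))

    def test_score_matrix_is_well_conditioned(self, random_pair):
        # rank-one weight deflation does not orthogonalise scores, but the
        # score matrix must stay full rank for the inner regression to be
        # well-posed
        X, Y = random_pair
        T = npls_fit(X, Y, 4).T_scores
        assert np.linalg.matrix_rank(T) == 4
        assert np.linalg.cond(T) < 1e6

    def test_projector_norms_and_signs(self, random_pair):
        X, Y = random_pair
        model = npls_fit(X, Y, 3)
        for W in (model.W1, model.W2, model.W3, model.Q):
            assert np.allclose(np.linalg.norm(W, axis=0), 1.0, atol=1e-10)
            for f in range(W.shape[1]):
                nz = np.flatnonzero(np.abs(W[:, f]) > 1e-12)
                assert W[nz[0], f] > 0

    def test_channel_permutation_equivariance(self, random_pair):
        X, Y = random_pair
        perm = np.array([2, 0, 1])
        m1 = npls_fit(X, Y, 2)
        m2 = npls_fit(X[:, :, :, perm], Y, 2)
        # the sign convention keys on the first entry, which the permutation
        # moves, so projectors match up to a per-factor sign
        for f in range(2):
            assert (np.allclose(m2.W3[:, f], m1.W3[perm, f], atol=1e-8)
                    or np.allclose(m2.W3[:, f], -m1.W3[perm, f], atol=1e-8))
            assert (np.allclose(m2.W1[:, f], m1.W1[:, f], atol=1e-8)
                    or np.allclose(m2.W1[:, f], -m1.W1[:, f], atol=1e-8))
        # predictions are exactly permutation-invariant
        assert np.allclose(npls_predict(m2, X[:5, :, :, perm]),
                           npls_predict(m1, X[:5]), atol=1e-8)

    def test_zero_factor_model_predicts_the_mean(self, random_pair):
        X, Y = random_pair
        model = npls_fit(X, Y, 0)
        pred = npls_predict(model, X[:5])
        assert np.allclose(pred, Y.mean(axis=0))
        assert np.allclose(model.B_full, 0.0)

    def test_too_few_observations_raises(self, rng):
        X = rng.standard_normal((3, 2, 2, 2))
        Y = rng.standard_normal((3, 2))
        with pytest.raises(ValueError, match="observations"):
            npls_fit(X, Y, 3)

    def test_degenerate_rank_one_data_truncates_with_warning(self, rng):
        y = rng.standard_normal(30)
        a, b, c = rng.standard_normal(4), rng.standard_normal(3), rng.standard_normal(2)
        X = np.einsum("n,i,j,k->nijk", y, a, b, c)
        with pytest.warns(RuntimeWarning):
            model = npls_fit(X, y[:, None], 5)
        assert model.truncated
        assert model.n_factors < 5


class TestNplsPredict:
    def test_training_mean_input_predicts_response_mean(self, random_pair):
        X, Y = random_pair
        model = npls_fit(X, Y, 3)
        pred = npls_predict(model, model.x_mean[None])
        assert np.allclose(pred[0], model.y_mean, atol=1e-10)

    def test_sequential_and_materialized_predictions_agree(self, rng, random_pair):
        X, Y = random_pair
        model = npls_fit(X, Y, 3)
        Xnew = rng.standard_normal((100,) + X.shape[1:])
        seq = npls_predict(model, Xnew)
        B = model.B_full.reshape(-1, Y.shape[1])
        mat = (Xnew - model.x_mean).reshape(100, -1) @ B + model.y_mean
        assert np.allclose(seq, mat, atol=1e-10)

    def test_mode_mismatch_raises(self, random_pair):
        X, Y = random_pair
        model = npls_fit(X, Y, 1)
        with pytest.raises(ValueError, match="mode shape"):
            npls_predict(model, np.zeros((2, 9, 9, 9)))


class TestMaterializeCoefficients:
    def test_identity_push_oracle(self, random_pair):
        """B_full equals the prediction operator applied to the basis tensors."""
        X, Y = random_pair
        model = npls_fit(X, Y, 3)
        n = int(np.prod(model.mode_shape))
        basis = np.eye(n).reshape((n,) + model.mode_shape) + model.x_mean
        pushed = npls_predict(model, basis) - model.y_mean
        assert np.allclose(pushed.reshape(model.mode_shape + (Y.shape[1],)),
                           model.B_full, atol=1e-10)

    def test_linearity_of_the_prediction_map(self, rng, random_pair):
        X, Y = random_pair
        model = npls_fit(X, Y, 2)
        x1 = rng.standard_normal(X.shape[1:])
        x2 = rng.standard_normal(X.shape[1:])
        a, b = 0.7, -1.3
        combo = npls_predict(model, (a * x1 + b * x2 + model.x_mean)[None])
        parts = (a * (npls_predict(model, (x1 + model.x_mean)[None]) - model.y_mean)
                 + b * (npls_predict(model, (x2 + model.x_mean)[None]) - model.y_mean)
                 + model.y_mean)
        assert np.allclose(combo, parts, atol=1e-10)

    def test_recompute_matches_stored(self, random_pair):
        X, Y = random_pair
        model = npls_fit(X, Y, 3)
        assert np.allclose(materialize_coefficients(model), model.B_full)
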