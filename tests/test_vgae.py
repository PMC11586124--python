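import numpy as np
import pytest
from scipy.integrate import quad

from spatialcci import (
    VGAE,
    Adjacency,
    decode,
    encode,
    kl_loss,
    reconstruction_loss,
    reparameterize,
    standardize,
)
from spatialcci.vgae import (
    DiscriminatorParams,
    EncoderParams,
    _disc_bce_grads,
    adversarial_step,
)


def tiny_params(n_features, hidden, latent, seed=0):
    return EncoderParams.init(n_features, hidden, latent, np.random.default_rng(seed))


class TestEncoder:
    def test_edgeless_graph_is_pointwise_network(self, rng):
        """With A-hat = I, permuting the nodes permutes outputs identically."""
        X = rng.normal(size=(8, 5))
        params = tiny_params(5, (4, 4, 3), 2)
        I = np.eye(8)
        enc = encode(X, I, params)
        perm = rng.permutation(8)
        enc_p = encode(X[perm], I, params)
        np.testing.assert_allclose(enc_p.mu, enc.mu[perm], atol=1e-12)

    def test_zero_input_zero_weights_gives_zero(self):
        params = EncoderParams(
            trunk=[np.zeros((5, 4)), np.zeros((4, 4)), np.zeros((4, 3))],
            w_mu=np.zeros((3, 2)),
            w_logsig=np.zeros((3, 2)),
        )
        enc = encode(np.zeros((6, 5)), np.eye(6), params)
        np.testing.assert_array_equal(enc.mu, 0)
        np.testing.assert_array_equal(enc.log_sigma, 0)

    def test_two_node_hand_arithmetic(self):
        """1-wide weights on a 2-node edge graph: mu equals the hand-chained
        A-hat products."""
        A = Adjacency(np.array([[0, 1], [1, 0]], float))
        Ahat = A.normalized  # all entries 0.5
        w = 2.0
        params = EncoderParams(
            trunk=[np.array([[w]])] * 3, w_mu=np.array([[w]]), w_logsig=np.array([[0.0]])
        )
        X = np.array([[1.0], [3.0]])
        h = X
        for _ in range(3):
            h = np.maximum(Ahat @ h * w, 0)
        expected_mu = Ahat @ h * w
        enc = encode(X, Ahat, params)
        np.testing.assert_allclose(enc.mu, expected_mu, atol=1e-10)

    def test_dimension_mismatch_names_layer(self):
        params = tiny_params(5, (4, 4, 3), 2)
        with pytest.raises(ValueError, match="adjacency"):
            encode(np.zeros((3, 5)), np.eye(4), params)


class TestReparameterize:
    def test_same_seed_identical(self):
        mu = np.ones((10, 3))
        ls = np.zeros((10, 3))
        a = reparameterize(mu, ls, seed=5)
        b = reparameterize(mu, ls, seed=5)
        np.testing.assert_array_equal(a.z, b.z)

    def test_z_identity_holds_exactly(self, rng):
        mu = rng.normal(size=(6, 2))
        ls = rng.normal(size=(6, 2)) * 0.3
        enc = reparameterize(mu, ls, seed=1)
        np.testing.assert_array_equal(enc.z, mu + np.exp(ls) * enc.epsilon)

    def test_sampling_moments(self):
        enc = reparameterize(np.full((100_000, 1), 2.0),
                             np.full((100_000, 1), np.log(3.0)), seed=7)
        assert 1.97 <= enc.z.mean() <= 2.03
        assert 2.97 <= enc.z.std() <= 3.03


class TestDecoder:
    def test_zero_latent_gives_half(self):
        probs = decode(np.zeros((4, 2))).probs
        np.testing.assert_allclose(probs, 0.5)

    def test_opposite_unit_latents(self):
        probs = decode(np.array([[1.0], [-1.0]])).probs
        assert abs(probs[0, 1] - 1 / (1 + np.e)) < 1e-12

    def test_matches_explicit_gram_logistic(self, rng):
        z = rng.normal(size=(9, 4))
        probs = decode(z).probs
        gram = z @ z.T
        np.testing.assert_allclose(probs, 1 / (1 + np.exp(-gram)), atol=1e-12)
        np.testing.assert_allclose(probs, probs.T, atol=1e-15)


class TestLosses:
    def test_bce_at_half_is_ln2(self):
        A = Adjacency(np.array([[0, 1], [1, 0]], float))
        assert abs(reconstruction_loss(A, np.full((2, 2), 0.5)) - np.log(2)) < 1e-12

    def test_bce_limit_confident_correct(self):
        A = Adjacency(np.array([[0, 1], [1, 0]], float))
        probs = np.full((2, 2), 1 - 1e-9)
        assert reconstruction_loss(A, probs) < 1e-6

    def test_bce_matches_naive_sum(self, rng):
        M = (rng.random((5, 5)) < 0.4).astype(float)
        M = np.triu(M, 1); M = M + M.T
        probs = rng.uniform(0.05, 0.95, size=(5, 5))
        probs = (probs + probs.T) / 2
        got = reconstruction_loss(Adjacency(M), probs)
        acc = n = 0
        for i in range(5):
            for j in range(5):
                if i == j:
                    continue
                y, p = M[i, j], probs[i, j]
                acc += -(y * np.log(p) + (1 - y) * np.log(1 - p))
                n += 1
        assert abs(got - acc / n) < 1e-12

    def test_kl_zero_at_standard_normal(self):
        assert kl_loss(np.zeros((3, 4)), np.zeros((3, 4))) == 0.0

    def test_kl_closed_form_unit_mean(self):
        assert abs(kl_loss(np.ones((1, 1)), np.zeros((1, 1))) - 0.5) < 1e-12

    def test_kl_matches_quadrature(self, rng):
        mu = rng.normal(size=(2, 3))
        ls = rng.normal(size=(2, 3)) * 0.4
        got = kl_loss(mu, ls)

        def kl_1d(m, s):
            q = lambda x: np.exp(-((x - m) ** 2) / (2 * s**2)) / (s * np.sqrt(2 * np.pi))
            p = lambda x: np.exp(-(x**2) / 2) / np.sqrt(2 * np.pi)
            f = lambda x: q(x) * (np.log(q(x)) - np.log(p(x)))
            return quad(f, m - 12 * s, m + 12 * s, limit=200)[0]

        expected = np.mean([
            sum(kl_1d(mu[i, j], np.exp(ls[i, j])) for j in range(3)) for i in range(2)
        ])
        assert abs(got - expected) < 1e-6

    def test_kl_nonnegative_property(self, rng):
        for _ in range(50):
            mu = rng.normal(scale=3, size=(4, 2))
            ls = rng.normal(scale=1, size=(4, 2))
            assert kl_loss(mu, ls) >= 0


class TestAdversarial:
    def test_prior_samples_indistinguishable(self):
        rng = np.random.default_rng(0)
        disc = DiscriminatorParams.init(4, 32, rng)
        from spatialcci.vgae import Adam
        opt = Adam([disc.w1, disc.b1, disc.w2], lr=0.01)
        for _ in range(100):
            z = rng.standard_normal((512, 4))
            prior = rng.standard_normal((512, 4))
            adversarial_step(z, prior, disc, optimizer=opt)
        z = rng.standard_normal((10_000, 4))
        prior = rng.standard_normal((10_000, 4))
        both = np.vstack([prior, z])
        labels = np.r_[np.ones(10_000), np.zeros(10_000)]
        from spatialcci.vgae import _disc_forward
        _, _, logit = _disc_forward(both, disc)
        acc = ((logit > 0).astype(int) == labels).mean()
        assert abs(acc - 0.5) <= 0.05

    def test_shifted_latents_are_separable(self):
        rng = np.random.default_rng(1)
        disc = DiscriminatorParams.init(4, 32, rng)
        from spatialcci.vgae import Adam, _disc_forward
        opt = Adam([disc.w1, disc.b1, disc.w2], lr=0.05)
        for _ in range(50):
            z = rng.standard_normal((256, 4)) + 10.0
            prior = rng.standard_normal((256, 4))
            adversarial_step(z, prior, disc, optimizer=opt)
        z = rng.standard_normal((2000, 4)) + 10.0
        prior = rng.standard_normal((2000, 4))
        _, _, lz = _disc_forward(z, disc)
        _, _, lp = _disc_forward(prior, disc)
        acc = ((lz <= 0).mean() + (lp > 0).mean()) / 2
        assert acc > 0.95

    def test_disc_input_gradient_matches_finite_difference(self, rng):
        disc = DiscriminatorParams.init(3, 8, rng)
        z = rng.normal(size=(5, 3))
        labels = np.ones(5)
        _, _, dz = _disc_bce_grads(z, labels, disc)
        h = 1e-6
        for i, j in [(0, 0), (2, 1), (4, 2)]:
            zp = z.copy(); zp[i, j] += h
            zm = z.copy(); zm[i, j] -= h
            lp, _, _ = _disc_bce_grads(zp, labels, disc)
            lm, _, _ = _disc_bce_grads(zm, labels, disc)
            assert abs((lp - lm) / (2 * h) - dz[i, j]) < 1e-6


class TestTraining:
    def test_encoder_gradients_match_finite_difference(self, small_tissue):
        X = standardize(small_tissue.expression)
        model = VGAE(X, small_tissue.true_adjacency, hidden_dims=(4, 4, 3), latent_dim=2)
        rng = np.random.default_rng(0)
        params = EncoderParams.init(X.n_genes, (4, 4, 3), 2, rng)
        eps = rng.standard_normal((X.n_cells, 2))
        recon, kl, grads, _, _ = model._forward_backward(params, eps, beta=1.0)

        def loss_at():
            r, k, _, _, _ = model._forward_backward(params, eps, beta=1.0)
            return r + k

        h = 1e-6
        flat = params.flat()
        for pi, P in enumerate(flat):
            i, j = P.shape[0] // 2, P.shape[1] // 2
            orig = P[i, j]
            P[i, j] = orig + h
            lp = loss_at()
            P[i, j] = orig - h
            lm = loss_at()
            P[i, j] = orig
            fd = (lp - lm) / (2 * h)
            assert abs(fd - grads[pi][i, j]) < 1e-5 * max(1.0, abs(fd))

    def test_loss_decreases_over_training(self, small_tissue):
        X = standardize(small_tissue.expression)
        res = VGAE(X, small_tissue.true_adjacency).fit(epochs=30, seed=0)
        assert res.history[-1].total < res.history[0].total

    def test_same_seed_bitwise_identical_history(self, small_tissue):
        X = standardize(small_tissue.expression)
        model = VGAE(X, small_tissue.true_adjacency)
        h1 = model.fit(epochs=5, seed=3).loss_history
        h2 = model.fit(epochs=5, seed=3).loss_history
        assert (h1 == h2).all().all()

    def test_beta_zero_relaxes_kl(self, small_tissue):
        X = standardize(small_tissue.expression)
        model = VGAE(X, small_tissue.true_adjacency)
        free = model.fit(epochs=30, beta=0.0, adv_weight=0.0, seed=1)
        reg = model.fit(epochs=30, beta=1.0, adv_weight=0.0, seed=1)
        assert free.history[-1].kl >= reg.history[-1].kl

    def test_permutation_equivariance_untrained(self, rng, small_tissue):
        X = standardize(small_tissue.expression).values
        A = small_tissue.true_adjacency
        params = tiny_params(X.shape[1], (4, 4, 3), 2, seed=2)
        perm = rng.permutation(X.shape[0])
        P = np.eye(X.shape[0])[perm]
        Ahat = A.normalized
        enc = encode(X, Ahat, params)
        enc_p = encode(X[perm], P @ Ahat @ P.T, params)
        np.testing.assert_allclose(enc_p.mu, enc.mu[perm], atol=1e-10)
        probs = decode(enc.mu).probs
        probs_p = decode(enc_p.mu).probs
        np.testing.assert_allclose(probs_p, probs[np.ix_(perm, perm)], atol=1e-10)

    def test_nonpositive_epochs_rejected(self, small_tissue):
        X = standardize(small_tissue.expression)
        with pytest.raises(ValueError):
            VGAE(X, small_tissue.true_adjacency).fit(epochs=0)

    def test_summary_mentions_dimensions(self, small_tissue):
        X = standardize(small_tissue.expression)
        res = VGAE(X, small_tissue.true_adjacency).fit(epochs=2, seed=0)
        text = res.summary()
        assert "latent" in text and str(small_tissue.coords.n_cells) in text


class TestCheckpoint:
    def test_roundtrip_preserves_weights_and_predictions(self, small_tissue, tmp_path):
        X = standardize(small_tissue.expression)
        res = VGAE(X, small_tissue.true_adjacency).fit(epochs=3, seed=0)
        path = tmp_path / "ckpt.json"
        res.save(path)
        from spatialcci.vgae import VGAEResults
        params, config = VGAEResults.load_params(path)
        assert config["seed"] == 0
        enc = encode(X.values, small_tissue.true_adjacency.normalized, params)
        np.testing.assert_allclose(
            decode(enc.mu).probs, res.predict_proba().probs, atol=1e-12
        )

    def test_non_checkpoint_file_rejected(self, tmp_path):
        bad = tmp_path / "bad.json"
        bad.write_text('{"format": "something-else"}')
        from spatialcci.vgae import VGAEResults
        with pytest.raises(ValueError):
            VGAEResults.load_params(bad)
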