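"""Face branch: cropping, PCA, the feedforward network, grid search."""

import numpy as np
import pytest

from emofuse import face_pipeline as fp
from emofuse.labels import EmotionState, STATE_ORDER
from emofuse.synthetic_data import place_on_canvas, render_face

from conftest import make_clusters


class TestCropFace:
    def test_pass_through_48x48(self):
        img = np.random.default_rng(0).uniform(size=(48, 48))
        out = fp.crop_face(img, detector=lambda g: None)
        assert out.shape == (48, 48)
        assert np.allclose(out, img)

    def test_uint8_input_scaled_to_unit_range(self):
        img = np.full((48, 48), 128, dtype=np.uint8)
        out = fp.crop_face(img)
        assert np.allclose(out, 128 / 255)

    def test_downsampling_contract(self):
        # a 2x nearest upsample of a smooth image downsamples back to ~itself
        base = np.random.default_rng(1).uniform(0.2, 0.8, size=(24, 24))
        smooth = fp._sk_resize(base, (48, 48), order=1, anti_aliasing=False)
        big = np.repeat(np.repeat(smooth, 2, axis=0), 2, axis=1)
        out = fp.crop_face(big)
        assert out.shape == (48, 48)
        assert np.abs(out - smooth).mean() < 0.02

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fp.crop_face(np.empty((0, 0)))

    def test_color_input_uses_luma(self):
        rgb = np.zeros((48, 48, 3))
        rgb[:, :, 1] = 1.0  # pure green
        out = fp.crop_face(rgb)
        assert np.allclose(out, 0.587)

    def test_blob_detector_finds_offcenter_synthetic_face(self):
        face = render_face(EmotionState.HAPPINESS, noise_sd=0.0)
        canvas, mask = place_on_canvas(face, (128, 128), (20, 55), background=0.02)
        box = fp.brightest_blob_detector(canvas)
        assert box is not None
        r0, r1, c0, c1 = box
        covered = mask[r0:r1, c0:c1].sum() / mask.sum()
        assert covered >= 0.90
        out = fp.crop_face(canvas, detector=fp.brightest_blob_detector)
        assert out.shape == (48, 48)


class TestPCA:
    @staticmethod
    def _subspace_images(n=40, dim=5, seed=0):
        g = np.random.default_rng(seed)
        basis = np.linalg.qr(g.standard_normal((fp.N_PIXELS, dim)))[0]
        offset = g.uniform(0.2, 0.4, size=fp.N_PIXELS)
        coords = g.standard_normal((n, dim))
        return [(offset + basis @ c).reshape(48, 48) for c in coords]

    def test_exact_low_rank_data_reconstructs_perfectly(self):
        images = self._subspace_images()
        pca = fp.fit_pca(images, D=5)
        for img in images[:10]:
            z = fp.project(pca, img)
            recon = pca.mean + pca.basis.T @ z
            assert np.abs(recon - img.reshape(-1)).max() < 1e-8

    def test_components_match_eigendecomposition_oracle(self):
        g = np.random.default_rng(2)
        images = [g.uniform(size=(48, 48)) for _ in range(30)]
        pca = fp.fit_pca(images, D=6)
        X = np.stack([im.reshape(-1) for im in images])
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        top = evecs[:, np.argsort(evals)[::-1][:6]].T.copy()
        for ref in top:  # apply the same sign convention as the implementation
            if ref[np.argmax(np.abs(ref))] < 0:
                ref *= -1.0
        assert np.allclose(pca.basis, top, atol=1e-8)
        # projections agree too
        z = fp.project(pca, images[0])
        assert np.allclose(z, top @ Xc[0], atol=1e-8)

    def test_basis_is_orthonormal_with_positive_sign_convention(self):
        images = self._subspace_images(n=60, dim=10, seed=3)
        pca = fp.fit_pca(images, D=8)
        assert np.allclose(pca.basis @ pca.basis.T, np.eye(8), atol=1e-8)
        for row in pca.basis:
            assert row[np.argmax(np.abs(row))] > 0

    def test_refit_deterministic(self):
        images = self._subspace_images(seed=4)
        p1 = fp.fit_pca(images, D=5)
        p2 = fp.fit_pca(images, D=5)
        assert np.array_equal(p1.basis, p2.basis)

    def test_projection_dimensionality(self):
        images = self._subspace_images(n=200, dim=180, seed=5)
        pca = fp.fit_pca(images, D=169)
        assert fp.project(pca, images[0]).shape == (169,)

    def test_d_exceeding_sample_count_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            fp.fit_pca(self._subspace_images(n=4), D=5)

    def test_zero_variance_data_rejected(self):
        img = np.full((48, 48), 0.5)
        with pytest.raises(ValueError, match="rank"):
            fp.fit_pca([img] * 10, D=2)

    def test_projection_identities(self):
        images = self._subspace_images(seed=6)
        pca = fp.fit_pca(images, D=5)
        mean_img = pca.mean.reshape(48, 48)
        assert np.allclose(fp.project(pca, mean_img), 0.0, atol=1e-10)
        shifted = pca.mean + 2.5 * pca.basis[0]
        z = fp.project(pca, shifted.reshape(48, 48))
        assert np.allclose(z, [2.5, 0, 0, 0, 0], atol=1e-8)
        # Bessel: projection norm bounded by centered-image norm
        z = fp.project(pca, images[0])
        centered = images[0].reshape(-1) - pca.mean
        assert np.linalg.norm(z) <= np.linalg.norm(centered) + 1e-12


class TestNetwork:
    @staticmethod
    def _clusters_169(seed=9):
        centers = np.zeros((4, 169))
        for k in range(4):
            centers[k, 40 * k] = 10.0
        X, y = make_clusters(40, centers, noise_sd=1.0, seed=seed)
        return X, [STATE_ORDER[k] for k in y]

    def test_separable_classes_learned(self):
        X, labels = self._clusters_169()
        hp = fp.HyperParams(D=169, N=150, R=0.1)
        nn = fp.train_nn(X, labels, hp=hp, epochs=200, seed=1)
        preds = [fp.score_faces(nn, x).r1 for x in X]
        acc = np.mean([p == l for p, l in zip(preds, labels)])
        assert acc >= 0.95

    def test_zero_epochs_returns_initialization(self):
        X, labels = self._clusters_169()
        hp = fp.HyperParams(D=169, N=50, R=0.1)
        m0 = fp.train_nn(X, labels, hp=hp, epochs=0, seed=5)
        m0b = fp.train_nn(X[::40], labels[::40], hp=hp, epochs=0, seed=5)
        assert np.array_equal(m0.W1, m0b.W1)  # init depends only on seed/shape
        m1 = fp.train_nn(X, labels, hp=hp, epochs=1, seed=5)
        assert not np.array_equal(m0.W1, m1.W1)

    def test_same_seed_same_weights(self):
        X, labels = self._clusters_169()
        hp = fp.HyperParams(D=169, N=50, R=0.1)
        m1 = fp.train_nn(X, labels, hp=hp, epochs=3, seed=2)
        m2 = fp.train_nn(X, labels, hp=hp, epochs=3, seed=2)
        for a, b in [(m1.W1, m2.W1), (m1.b1, m2.b1), (m1.W2, m2.W2), (m1.b2, m2.b2)]:
            assert np.array_equal(a, b)

    def test_dimension_mismatch_rejected(self):
        X, labels = self._clusters_169()
        with pytest.raises(ValueError, match="features"):
            fp.train_nn(X, labels, hp=fp.HyperParams(D=121, N=50, R=0.1), epochs=1)

    def test_backprop_matches_finite_differences(self):
        g = np.random.default_rng(7)
        hp = fp.HyperParams(D=12, N=9, R=0.1)
        model = fp.NNModel(
            W1=g.uniform(-0.5, 0.5, (hp.N, hp.D)),
            b1=g.uniform(-0.5, 0.5, hp.N),
            W2=g.uniform(-0.5, 0.5, (4, hp.N)),
            b2=g.uniform(-0.5, 0.5, 4),
            learning_rate=hp.R,
        )
        eps = 1e-6
        for _ in range(5):
            x = g.standard_normal(hp.D)
            t = np.zeros(4)
            t[g.integers(4)] = 1.0
            _, grads = fp.nn_loss_and_grads(model, x, t)
            for name in ("W1", "b1", "W2", "b2"):
                arr = getattr(model, name)
                flat_idx = g.integers(arr.size, size=6)
                for fi in flat_idx:
                    orig = arr.flat[fi]
                    arr.flat[fi] = orig + eps
                    lp, _ = fp.nn_loss_and_grads(model, x, t)
                    arr.flat[fi] = orig - eps
                    lm, _ = fp.nn_loss_and_grads(model, x, t)
                    arr.flat[fi] = orig
                    num = (lp - lm) / (2 * eps)
                    ana = grads[name].flat[fi]
                    denom = max(abs(num), abs(ana), 1e-8)
                    assert abs(num - ana) / denom < 1e-5

    def test_outputs_in_unit_interval(self):
        g = np.random.default_rng(8)
        hp = fp.HyperParams(D=10, N=5, R=0.1)
        nn = fp.train_nn(
            g.standard_normal((20, 10)),
            [STATE_ORDER[i % 4] for i in range(20)],
            hp=hp, epochs=2, seed=0,
        )
        for _ in range(10):
            o = nn.forward(g.standard_normal(10) * 10)
            assert np.all((o > 0) & (o < 1))


class TestScoreFaces:
    @staticmethod
    def _fixed_output_model(outputs):
        # W2 = 0 makes the output layer ignore the input: o = sigmoid(b2)
        logits = np.log(np.asarray(outputs) / (1 - np.asarray(outputs)))
        return fp.NNModel(
            W1=np.zeros((3, 6)), b1=np.zeros(3),
            W2=np.zeros((4, 3)), b2=logits, learning_rate=0.1,
        )

    def test_argmax_decision(self):
        nn = self._fixed_output_model([0.9, 0.1, 0.1, 0.1])
        fs = fp.score_faces(nn, np.zeros(6))
        assert fs.r1 is EmotionState.HAPPINESS
        assert np.allclose(fs.s1, [0.9, 0.1, 0.1, 0.1])

    def test_all_equal_scores_fall_back_to_first_state(self):
        nn = self._fixed_output_model([0.5, 0.5, 0.5, 0.5])
        assert fp.score_faces(nn, np.zeros(6)).r1 is EmotionState.HAPPINESS


class TestGridSearch:
    def test_full_grid_enumerates_64_combinations(self):
        g = np.random.default_rng(10)
        images = [g.uniform(size=(48, 48)) for _ in range(230)]
        labels = [STATE_ORDER[i % 4] for i in range(230)]
        res = fp.grid_search(images, labels, images[:8], labels[:8], epochs=0, seed=0)
        assert len(res.scores) == 64
        assert set(hp.D for hp in res.scores) == {121, 144, 169, 225}

    def test_tie_breaks_toward_smallest_hyperparams(self, monkeypatch):
        # force every combination to score identically
        monkeypatch.setattr(
            fp, "score_faces",
            lambda nn, f: fp.FaceScores(s1=np.zeros(4), r1=EmotionState.HAPPINESS),
        )
        g = np.random.default_rng(11)
        images = [g.uniform(size=(48, 48)) for _ in range(230)]
        labels = [STATE_ORDER[i % 4] for i in range(230)]
        res = fp.grid_search(images, labels, images[:4], labels[:4], epochs=0, seed=0)
        assert res.best == fp.HyperParams(D=121, N=150, R=0.001)
        assert len(set(res.scores.values())) == 1

    def test_empty_validation_rejected(self):
        with pytest.raises(ValueError, match="validation"):
            fp.grid_search([np.zeros((48, 48))], [EmotionState.HAPPINESS], [], [])
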