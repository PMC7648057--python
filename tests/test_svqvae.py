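"""S-VQ-VAE codebook lookup, loss arithmetic, straight-through gradients,
training recovery and class-conditional generation."""

import numpy as np
import pandas as pd
import pytest

from perturbvae import (
    SVQVAEConfig,
    SVQVAEModel,
    generate_class_conditional,
    nearest_embedding,
    straight_through_check,
    svqvae_forward,
    svqvae_loss,
    train_svqvae,
)
from perturbvae.data_model import ExpressionDataset
from perturbvae.svqvae import (
    LabelError,
    StateError,
    codebook_accuracy,
    load_checkpoint,
    save_checkpoint,
)


def _toy_model(D=2, Y=3, input_dim=4, seed=0, beta=0.25, gamma=0.1):
    cfg = SVQVAEConfig(input_dim=input_dim, hidden_sizes=(3,),
                       embedding_dim=D, n_classes=Y, beta=beta, gamma=gamma,
                       seed=seed)
    return SVQVAEModel(cfg, class_labels=[f"c{i}" for i in range(Y)])


class TestNearestEmbedding:
    def test_exact_row_maps_to_itself(self):
        E = np.arange(12.0).reshape(4, 3)
        assert nearest_embedding(E, E[3]) == 3

    def test_two_point_comparison(self):
        E = np.array([[0.0, 0.0], [10.0, 10.0]])
        assert nearest_embedding(E, np.array([1.0, 1.0])) == 0

    def test_tie_breaks_to_lowest_index(self):
        E = np.array([[1.0, 0.0], [-1.0, 0.0]])
        assert nearest_embedding(E, np.array([0.0, 5.0])) == 0

    def test_empty_codebook_raises(self):
        with pytest.raises(StateError):
            nearest_embedding(np.empty((0, 2)), np.zeros(2))


class TestForward:
    def test_train_mode_uses_label_lookup_not_nearest(self):
        model = _toy_model()
        x = np.random.default_rng(0).normal(size=4)
        # make the nearest code definitely differ from the label's code
        model.E[...] = np.array([[100.0, 100.0], [0.0, 0.0], [-100.0, -100.0]])
        _, z_e, z_q, k = svqvae_forward(model, x, "c0", mode="train")
        np.testing.assert_array_equal(z_q, model.E[0])
        assert k == 1  # nearest is still reported

    def test_test_mode_uses_nearest(self):
        model = _toy_model()
        x = np.random.default_rng(0).normal(size=4)
        z_e = model.encode(x)[0]
        model.E[2] = z_e
        _, _, z_q, k = svqvae_forward(model, x, mode="test")
        assert k == 2
        np.testing.assert_array_equal(z_q, model.E[2])

    def test_unknown_label_raises(self):
        model = _toy_model()
        with pytest.raises(LabelError):
            svqvae_forward(model, np.zeros(4), "nope", mode="train")


class TestLossArithmetic:
    def _pinned_model(self, z_e_target, e_y, e_other):
        """Toy model whose encoder output is forced to z_e_target for a
        zero input (weights zeroed, bias set)."""
        model = _toy_model(D=2, Y=2)
        for layer in model.enc_hidden.layers:
            if hasattr(layer, "W"):
                layer.W[...] = 0.0
                layer.b[...] = 0.0
        model.enc_head.W[...] = 0.0
        model.enc_head.b[...] = z_e_target
        model.E[0] = e_y
        model.E[1] = e_other
        return model

    def test_hand_computed_dictionary_and_commitment(self):
        # z_e = (1,0), e_y = (0,0): dictionary 1.0, commitment 0.25 at beta=0.25
        model = self._pinned_model([1.0, 0.0], [0.0, 0.0], [50.0, 50.0])
        br = svqvae_loss(model, np.zeros(4), "c0")
        assert br.dictionary == pytest.approx(1.0, abs=1e-8)
        assert br.commitment == pytest.approx(0.25, abs=1e-8)
        # nearest is e_0 = e_y, so the misclass-gated terms vanish
        assert br.misclass_dictionary == 0.0
        assert br.divergence == 0.0

    def test_misclass_terms_subtract_when_nearest_is_wrong(self):
        # nearest code is e_1 = (1,0) = z_e while the label is c0
        model = self._pinned_model([1.0, 0.0], [0.0, 0.0], [1.0, 0.0])
        br = svqvae_loss(model, np.zeros(4), "c0")
        assert br.misclass_dictionary == pytest.approx(0.0, abs=1e-12)
        # push z_e away from e_k: increasing the distance lowers the total
        model2 = self._pinned_model([1.0, 0.0], [0.0, 0.0], [1.5, 0.0])
        br2 = svqvae_loss(model2, np.zeros(4), "c0")
        gated = br2.misclass_dictionary + br2.divergence
        assert gated == pytest.approx((1 + model2.cfg.gamma) * 0.25, abs=1e-8)
        assert br2.total == pytest.approx(
            br2.reconstruction + br2.dictionary + br2.commitment - gated)

    def test_perfect_setup_gives_zero_total(self):
        model = self._pinned_model([0.0, 0.0], [0.0, 0.0], [50.0, 50.0])
        # decoder to exact zero output reconstructs the zero input
        for layer in model.dec_hidden.layers:
            if hasattr(layer, "W"):
                layer.W[...] = 0.0
                layer.b[...] = 0.0
        model.out_head.W[...] = 0.0
        model.out_head.b[...] = 0.0
        br = svqvae_loss(model, np.zeros(4), "c0")
        assert br.total == pytest.approx(0.0, abs=1e-12)

    def test_components_nonnegative(self):
        model = _toy_model()
        x = np.random.default_rng(1).uniform(-5, 5, size=(6, 4))
        br = svqvae_loss(model, x, ["c0", "c1", "c2", "c0", "c1", "c2"])
        for term in (br.reconstruction, br.dictionary, br.commitment,
                     br.misclass_dictionary, br.divergence):
            assert term >= 0


class TestStraightThrough:
    def test_finite_difference_matches_backward_on_toy(self):
        cfg = SVQVAEConfig(input_dim=5, hidden_sizes=(4,), embedding_dim=3,
                           n_classes=3, seed=2)
        model = SVQVAEModel(cfg, class_labels=["a", "b", "c"])
        x = np.random.default_rng(0).normal(size=(4, 5))
        err = straight_through_check(model, x, ["a", "b", "c", "a"])
        assert err < 1e-4

    def test_codebook_gradient_zero_at_fixed_point(self):
        from perturbvae.svqvae import _svqvae_backward
        model = _toy_model(D=2, Y=2)
        for layer in model.enc_hidden.layers:
            if hasattr(layer, "W"):
                layer.W[...] = 0.0
                layer.b[...] = 0.0
        model.enc_head.W[...] = 0.0
        model.enc_head.b[...] = [0.5, 0.5]
        model.E[0] = [0.5, 0.5]       # e_y = z_e, and k = y
        model.E[1] = [90.0, 90.0]
        _svqvae_backward(model, np.zeros((1, 4)), np.array([0]))
        np.testing.assert_allclose(model.gE, 0.0, atol=1e-12)


class TestTraining:
    def test_recovers_separable_classes(self, trained_svqvae, synth):
        data, _ = synth
        model, log = trained_svqvae
        assert log["val_code_accuracy"].iloc[-1] >= 0.8  # chance is 0.125
        # codebook rows correlate with class-mean encodings
        y = model.label_to_index(data.sample_meta["pcl_label"].to_numpy())
        z = model.encode(data.matrix)
        for c in range(model.cfg.n_classes):
            r = np.corrcoef(model.E[c], z[y == c].mean(0))[0, 1]
            assert r >= 0.9

    def test_same_seed_identical_codebook(self, synth):
        data, _ = synth
        cfg = SVQVAEConfig(input_dim=100, hidden_sizes=(8,), embedding_dim=8,
                           n_classes=8, epochs=3, batch_size=256, seed=4)
        m1, _ = train_svqvae(data, cfg)
        m2, _ = train_svqvae(data, cfg)
        np.testing.assert_array_equal(m1.E, m2.E)

    def test_zero_coefficients_still_train(self, synth):
        data, _ = synth
        cfg = SVQVAEConfig(input_dim=100, hidden_sizes=(8,), embedding_dim=8,
                           n_classes=8, beta=0.0, gamma=0.0, epochs=2,
                           batch_size=256, seed=0)
        model, log = train_svqvae(data, cfg)
        assert np.isfinite(log["total"]).all()

    def test_every_class_in_training_split(self, synth):
        from perturbvae.svqvae import _stratified_split
        data, _ = synth
        y = np.repeat(np.arange(5), [2, 3, 11, 50, 7])
        rng = np.random.default_rng(0)
        train, val = _stratified_split(y, 0.9, rng)
        assert set(y[train]) == set(range(5))


class TestGeneration:
    def test_zero_variance_gives_identical_decodes(self, trained_svqvae):
        model, _ = trained_svqvae
        gen = generate_class_conditional(model, "PCL00", 4,
                                         sigma2_hat=np.zeros(32), seed=0)
        decoded = model.decode(model.E[model.label_to_index("PCL00")[0]])
        for row in gen.matrix:
            np.testing.assert_allclose(row, np.ravel(decoded), atol=1e-9)

    def test_nonpositive_n_rejected(self, trained_svqvae):
        model, _ = trained_svqvae
        with pytest.raises(ValueError):
            generate_class_conditional(model, "PCL00", 0)

    def test_generated_samples_nearest_to_own_class(self, trained_svqvae, synth):
        from perturbvae.representations import nearest_real_neighbor
        data, _ = synth
        model, _ = trained_svqvae
        hits = []
        for lbl in ("PCL00", "PCL03", "PCL07"):
            gen = generate_class_conditional(model, lbl, 50, seed=1)
            gen.gene_ids = data.gene_ids
            _, comp = nearest_real_neighbor(gen, data)
            hits.append(comp.get(lbl, 0.0))
        assert np.mean(hits) >= 0.7


def test_checkpoint_round_trip(tmp_path, trained_svqvae):
    model, _ = trained_svqvae
    save_checkpoint(model, tmp_path / "m.ckpt")
    back = load_checkpoint(tmp_path / "m.ckpt")
    np.testing.assert_array_equal(model.E, back.E)
    assert back.class_labels == model.class_labels
    np.testing.assert_array_equal(model.class_sigma2, back.class_sigma2)
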