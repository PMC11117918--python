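"""Feature adapter: residual map contract, analytic gradients, training loop."""

import numpy as np
import pytest

from promptad.adapter import (AdapterState, TrainConfig, _adapt_rows,
                              _batch_loss_and_grads, adapt_text_bank,
                              apply_adapter, init_adapter, load_adapter,
                              save_adapter, train_adapter)
from promptad.encoders import EncoderSpec, encode_image_hierarchical, toy_encoder_pair
from promptad.losses import LossConfig
from promptad.phantom import PhantomConfig, generate_dataset
from promptad.prompts import PromptSet, TextBank, build_text_bank

from .oracles import random_unit_rows


@pytest.fixture
def spec():
    return EncoderSpec(feature_dim=32, levels=(12, 24), patch_sizes=(16, 8))


@pytest.fixture
def tiny_train_setup(spec):
    """A handful of small phantoms plus an aligned encoder pair."""
    ph = PhantomConfig(size=(32, 32), organ_axes=(11.0, 9.0), organ_center_jitter=1.0,
                       lesion_radius=(4.0, 6.0))
    samples = generate_dataset(ph, 8, 0, seed=99)
    img_enc, txt_enc = toy_encoder_pair(4, spec)
    prompts = PromptSet(normal_prompts=["a healthy organ", "a normal organ"],
                        abnormal_prompts=["an organ with lesions", "a diseased organ"])
    bank = build_text_bank(prompts, txt_enc)
    return samples, img_enc, txt_enc, prompts, bank


def _quick_cfg(**kw):
    base = dict(epochs=3, batch_size=4, seed=5, patches_per_level=2)
    base.update(kw)
    return TrainConfig(**base)


class TestApplyAdapter:
    def test_alpha_zero_is_identity(self, spec, small_image_encoder, rng):
        img = rng.uniform(size=(32, 32))
        feats = encode_image_hierarchical(img, small_image_encoder, spec)
        state = AdapterState(w_img=rng.standard_normal((32, 32)), alpha=0.0)
        out = apply_adapter(feats, state)
        np.testing.assert_allclose(out.global_feat, feats.global_feat, atol=1e-12)
        for lv in spec.levels:
            np.testing.assert_allclose(out.level_feats[lv], feats.level_feats[lv],
                                       atol=1e-12)

    def test_near_identity_init_is_a_near_noop(self, spec, small_image_encoder, rng):
        img = rng.uniform(size=(32, 32))
        feats = encode_image_hierarchical(img, small_image_encoder, spec)
        state = init_adapter(32, _quick_cfg())
        out = apply_adapter(feats, state)
        assert np.linalg.norm(out.global_feat - feats.global_feat) < 1e-3

    def test_outputs_unit_norm(self, spec, small_image_encoder, rng):
        img = rng.uniform(size=(32, 32))
        feats = encode_image_hierarchical(img, small_image_encoder, spec)
        state = AdapterState(w_img=np.eye(32) + 0.3 * rng.standard_normal((32, 32)),
                             alpha=0.6)
        out = apply_adapter(feats, state)
        assert np.linalg.norm(out.global_feat) == pytest.approx(1.0, abs=1e-6)
        for lv in spec.levels:
            norms = np.linalg.norm(out.level_feats[lv], axis=-1)
            np.testing.assert_allclose(norms, 1.0, atol=1e-6)

    def test_dimension_mismatch_rejected(self, spec, small_image_encoder, rng):
        img = rng.uniform(size=(32, 32))
        feats = encode_image_hierarchical(img, small_image_encoder, spec)
        with pytest.raises(ValueError):
            apply_adapter(feats, AdapterState(w_img=np.eye(16)))

    def test_identity_text_map_leaves_bank_alone(self, rng):
        v = random_unit_rows(rng, 2, 8)
        bank = TextBank(f_normal=v[0], f_abnormal=v[1])
        out = adapt_text_bank(bank, AdapterState(w_img=np.eye(8)))
        np.testing.assert_array_equal(out.f_normal, bank.f_normal)


class TestAnalyticGradients:
    def test_matches_finite_differences(self, rng):
        """The hand-derived gradient of the training objective w.r.t. W."""
        n, d = 5, 12
        u = random_unit_rows(rng, n, d)
        u_aug = random_unit_rows(rng, n, d)
        f_n = random_unit_rows(rng, 1, d)[0]
        f_a = random_unit_rows(rng, 1, d)[0]
        w = np.eye(d) + 0.05 * rng.standard_normal((d, d))
        state = AdapterState(w_img=w.copy(), alpha=0.4)
        lc = LossConfig(tau=0.3, beta=0.4)

        def loss_of(w_mat):
            comps, _, _ = _batch_loss_and_grads(u, u_aug, state, w_mat, f_n, f_a, lc, False)
            return comps["total"]

        _, grad, _ = _batch_loss_and_grads(u, u_aug, state, w, f_n, f_a, lc, False)
        eps = 1e-6
        for _ in range(20):
            i, j = rng.integers(0, d, size=2)
            w_hi, w_lo = w.copy(), w.copy()
            w_hi[i, j] += eps
            w_lo[i, j] -= eps
            fd = (loss_of(w_hi) - loss_of(w_lo)) / (2 * eps)
            assert grad[i, j] == pytest.approx(fd, abs=1e-5)

    def test_text_anchor_gradients_match_finite_differences(self, rng):
        n, d = 4, 10
        u = random_unit_rows(rng, n, d)
        u_aug = random_unit_rows(rng, n, d)
        f_n = random_unit_rows(rng, 1, d)[0]
        f_a = random_unit_rows(rng, 1, d)[0]
        w = np.eye(d)
        state = AdapterState(w_img=w, alpha=0.4)
        lc = LossConfig(tau=0.3, beta=0.4)
        _, _, (d_fn, d_fa) = _batch_loss_and_grads(u, u_aug, state, w, f_n, f_a, lc, True)
        eps = 1e-6
        for k in range(3):
            delta = np.zeros(d)
            delta[k] = eps
            hi, _, _ = _batch_loss_and_grads(u, u_aug, state, w, f_n + delta, f_a, lc, False)
            lo, _, _ = _batch_loss_and_grads(u, u_aug, state, w, f_n - delta, f_a, lc, False)
            assert d_fn[k] == pytest.approx((hi["total"] - lo["total"]) / (2 * eps), abs=1e-5)


class TestTrainAdapter:
    def test_seeded_determinism(self, spec, tiny_train_setup):
        samples, img_enc, txt_enc, prompts, _ = tiny_train_setup
        images = [s.image for s in samples]
        s1, log1 = train_adapter(images, prompts, img_enc, txt_enc, spec, _quick_cfg())
        s2, log2 = train_adapter(images, prompts, img_enc, txt_enc, spec, _quick_cfg())
        np.testing.assert_array_equal(s1.w_img, s2.w_img)
        assert log1 == log2

    def test_zero_learning_rate_keeps_initial_state(self, spec, tiny_train_setup):
        samples, img_enc, txt_enc, prompts, _ = tiny_train_setup
        images = [s.image for s in samples]
        cfg = _quick_cfg(learning_rate=0.0)
        state, _ = train_adapter(images, prompts, img_enc, txt_enc, spec, cfg)
        np.testing.assert_array_equal(state.w_img, init_adapter(32, cfg).w_img)
        assert not state.trained

    def test_loss_decreases_on_phantom_data(self, spec, tiny_train_setup):
        samples, img_enc, txt_enc, prompts, _ = tiny_train_setup
        images = [s.image for s in samples]
        cfg = _quick_cfg(epochs=20)
        _, log = train_adapter(images, prompts, img_enc, txt_enc, spec, cfg)
        assert np.isfinite(log[-1]["total"])
        assert log[-1]["total"] < log[0]["total"]

    def test_backbone_outputs_frozen_through_training(self, spec, tiny_train_setup, rng):
        samples, img_enc, txt_enc, prompts, _ = tiny_train_setup
        probe = rng.uniform(size=(32, 32))
        before = img_enc(probe)
        train_adapter([s.image for s in samples], prompts, img_enc, txt_enc, spec,
                      _quick_cfg())
        after = img_enc(probe)
        np.testing.assert_array_equal(before.global_feat, after.global_feat)
        for lv in spec.levels:
            np.testing.assert_array_equal(before.level_feats[lv], after.level_feats[lv])

    def test_empty_training_set_rejected(self, spec, tiny_train_setup):
        _, img_enc, txt_enc, prompts, _ = tiny_train_setup
        with pytest.raises(ValueError):
            train_adapter([], prompts, img_enc, txt_enc, spec, _quick_cfg())

    def test_trust_region_bounds_drift(self, spec, tiny_train_setup):
        samples, img_enc, txt_enc, prompts, _ = tiny_train_setup
        cfg = _quick_cfg(epochs=10, max_drift=0.5, learning_rate=0.05)
        state, _ = train_adapter([s.image for s in samples], prompts, img_enc, txt_enc,
                                 spec, cfg)
        assert np.linalg.norm(state.w_img - np.eye(32)) <= 0.5 + 1e-9

    def test_per_level_maps_created_and_trained(self, spec, tiny_train_setup):
        samples, img_enc, txt_enc, prompts, _ = tiny_train_setup
        cfg = _quick_cfg(per_level=True, epochs=2)
        state, _ = train_adapter([s.image for s in samples], prompts, img_enc, txt_enc,
                                 spec, cfg)
        assert set(state.w_img_levels) == set(spec.levels)

    def test_training_raises_alignment_with_normal_anchor(self, spec):
        """Training pulls adapted normal features toward the normal anchor:
        mean cos(adapted normal global, f_normal) increases over the
        untrained adapter on held-out normal phantoms."""
        ph = PhantomConfig(size=(32, 32), organ_axes=(11.0, 9.0), organ_center_jitter=1.0,
                           lesion_radius=(4.0, 6.0))
        train_set = generate_dataset(ph, 25, 0, seed=7)
        held_out = generate_dataset(ph, 15, 0, seed=8)
        img_enc, txt_enc = toy_encoder_pair(4, spec)
        prompts = PromptSet(
            normal_prompts=["a healthy organ", "a normal organ", "intact tissue"],
            abnormal_prompts=["an organ with lesions", "a diseased organ"])
        cfg = TrainConfig(epochs=25, batch_size=8, seed=3, patches_per_level=4)
        state, _ = train_adapter([s.image for s in train_set], prompts, img_enc,
                                 txt_enc, spec, cfg)
        state0 = init_adapter(spec.feature_dim, cfg)
        bank0 = build_text_bank(prompts, txt_enc)

        def mean_alignment(st):
            bank = adapt_text_bank(bank0, st)
            vals = []
            for s in held_out:
                feats = apply_adapter(encode_image_hierarchical(s.image, img_enc, spec), st)
                vals.append(float(feats.global_feat @ bank.f_normal))
            return np.mean(vals)

        assert mean_alignment(state) > mean_alignment(state0)


class TestSerialization:
    def test_round_trip(self, tmp_path, rng):
        state = AdapterState(w_img=np.eye(8) + 0.01 * rng.standard_normal((8, 8)),
                             alpha=0.5,
                             w_txt=np.eye(8) * 0.99,
                             w_img_levels={12: np.eye(8)},
                             rng_seed=42, trained=True)
        path = tmp_path / "adapter.json"
        save_adapter(state, path)
        loaded = load_adapter(path)
        np.testing.assert_array_equal(loaded.w_img, state.w_img)
        np.testing.assert_array_equal(loaded.w_txt, state.w_txt)
        np.testing.assert_array_equal(loaded.w_img_levels[12], state.w_img_levels[12])
        assert loaded.alpha == 0.5 and loaded.trained and loaded.rng_seed == 42

    def test_version_gate(self, tmp_path):
        path = tmp_path / "adapter.json"
        path.write_text('{"format_version": 99}')
        with pytest.raises(ValueError):
            load_adapter(path)


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(epochs=0)
    with pytest.raises(ValueError):
        TrainConfig(optimizer="lbfgs")
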