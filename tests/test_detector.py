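"""Detection skeleton: shape contracts, selection, refinement, gradients."""

import numpy as np
import pytest

from wavedet.autograd import Tensor, no_grad
from wavedet.detector import (DeformableAttention, ImageTensor, ModelConfig,
                              TinyBackbone, WaveletDetector, extract_features,
                              inverse_sigmoid, perturb_parameters,
                              sinusoidal_position_encoding)
from wavedet.matching import GroundTruthSet, DuplicationSchedule
from wavedet.matching import hhm_loss_batched
from wavedet.nn import Module, Parameter


class TestBackboneContract:
    def test_stride_arithmetic_640(self):
        bb = TinyBackbone((8, 16, 32, 64))
        pyr = extract_features(np.zeros((3, 640, 640), dtype=np.float32), bb)
        dims = [m.shape[-2:] for m in pyr.maps]
        assert dims == [(160, 160), (80, 80), (40, 40), (20, 20)]

    def test_ceil_division_on_odd_sizes(self):
        bb = TinyBackbone((8, 16, 32, 64))
        pyr = extract_features(np.zeros((3, 100, 68), dtype=np.float32), bb)
        dims = [m.shape[-2:] for m in pyr.maps]
        assert dims == [(25, 17), (13, 9), (7, 5), (4, 3)]

    def test_too_small_image_raises(self):
        bb = TinyBackbone((8, 16, 32, 64))
        with pytest.raises(ValueError, match="stride"):
            extract_features(np.zeros((3, 16, 64), dtype=np.float32), bb)

    def test_channel_contract_enforced(self):
        from wavedet.detector import FeaturePyramid
        with pytest.raises(ValueError, match="channel contract"):
            FeaturePyramid([Tensor(np.zeros((1, 7, 8, 8)))] * 4,
                           channels=(8, 16, 32, 64))

    def test_deterministic_under_fixed_seed(self):
        out = []
        for _ in range(2):
            bb = TinyBackbone((8, 16, 32, 64), np.random.default_rng(3))
            pyr = extract_features(np.full((3, 64, 64), 0.5,
                                           dtype=np.float32), bb)
            out.append(pyr.maps[3].data.copy())
        np.testing.assert_array_equal(out[0], out[1])


class TestProjection:
    def test_token_count_and_levels(self, tiny_model):
        pyr = extract_features(np.zeros((2, 3, 64, 64), dtype=np.float32),
                               tiny_model.backbone)
        content = tiny_model.project(pyr)
        expected = 16 ** 2 + 8 ** 2 + 4 ** 2 + 2 ** 2
        assert content.tokens.shape == (2, expected, 64)
        assert content.pos.shape == (expected, 64)
        counts = np.bincount(content.level_index)
        assert list(counts) == [256, 64, 16, 4]

    def test_reference_token_count_arithmetic(self):
        # 640x640 at strides 4/8/16/32: 160^2 + 80^2 + 40^2 + 20^2 = 34000
        assert sum((640 // s) ** 2 for s in (4, 8, 16, 32)) == 34000

    def test_flatten_round_trip(self, tiny_model):
        pyr = extract_features(np.random.default_rng(0)
                               .uniform(0, 1, (1, 3, 64, 64))
                               .astype(np.float32), tiny_model.backbone)
        content = tiny_model.project(pyr)
        start = 0
        for l, (h, w) in enumerate(content.shapes):
            block = content.tokens.data[0, start:start + h * w]
            restored = block.T.reshape(64, h, w)
            # unflatten then re-flatten reproduces the token block exactly
            np.testing.assert_array_equal(
                restored.reshape(64, h * w).T, block)
            start += h * w
        assert start == content.tokens.shape[1]

    def test_wtp_ablation_keeps_interface(self, tiny_config):
        import dataclasses
        cfg = dataclasses.replace(tiny_config, use_wtp=False)
        model = WaveletDetector(cfg, seed=0)
        layers = model.forward(Tensor(np.zeros((1, 3, 64, 64),
                                               dtype=np.float32)))
        assert len(layers) == cfg.decoder_layers + 1
        assert layers[-1].boxes.shape == (1, cfg.num_queries, 4)


class TestPositionalEncoding:
    def test_zero_maps_to_sin0_cos1(self):
        enc = sinusoidal_position_encoding(np.zeros((1, 2)), dim=64)
        half = 16
        assert np.allclose(enc[0, :half], 0.0)          # sin block, coord 0
        assert np.allclose(enc[0, half:2 * half], 1.0)  # cos block, coord 0

    def test_equal_boxes_identical_encodings(self, rng):
        b = rng.uniform(0, 1, (1, 4)).astype(np.float32)
        e1 = sinusoidal_position_encoding(b, dim=256)
        e2 = sinusoidal_position_encoding(b.copy(), dim=256)
        np.testing.assert_array_equal(e1, e2)

    def test_injective_on_fine_grid(self):
        grid = np.linspace(0, 1, 1001).reshape(-1, 1)
        enc = sinusoidal_position_encoding(grid, dim=256)
        # no two grid points share an encoding
        uniq = np.unique(np.round(enc, 6), axis=0)
        assert len(uniq) == len(grid)


class TestDeformableAttention:
    def test_attention_weights_sum_to_one(self, rng):
        att = DeformableAttention(32, 4, 2, 3, rng)
        q = Tensor(rng.normal(size=(2, 5, 32)).astype(np.float32))
        w = att.attn_proj(q).reshape(2, 5, 4, 6).softmax(axis=-1)
        np.testing.assert_allclose(w.data.sum(-1), 1.0, rtol=1e-5)

    def test_zero_offsets_uniform_weights_average_reference_samples(self, rng):
        """With offsets forced to 0 and uniform weights, the output equals
        out_proj of the mean of bilinear samples at the reference across
        levels."""
        dim, heads, levels, points = 8, 2, 2, 2
        att = DeformableAttention(dim, heads, levels, points, rng)
        att.offset_proj.weight.data[:] = 0
        att.offset_proj.bias.data[:] = 0
        att.attn_proj.weight.data[:] = 0
        att.attn_proj.bias.data[:] = 0        # softmax -> uniform
        shapes = [(4, 4), (2, 2)]
        L = 16 + 4
        memory = Tensor(rng.normal(size=(1, L, dim)).astype(np.float32))
        ref = np.array([[[0.5, 0.5]]], dtype=np.float32)   # grid-symmetric
        out = att(Tensor(rng.normal(size=(1, 1, dim)).astype(np.float32)),
                  ref, memory, shapes)
        values = att.value_proj(memory).data.reshape(1, L, heads, dim // heads)
        manual = np.zeros((1, 1, heads, dim // heads), dtype=np.float32)
        start = 0
        for h, w in shapes:
            vmap = values[0, start:start + h * w].reshape(h, w, heads, -1)
            px, py = 0.5 * w - 0.5, 0.5 * h - 0.5
            x0, y0 = int(np.floor(px)), int(np.floor(py))
            fx, fy = px - x0, py - y0
            s = ((1 - fx) * (1 - fy) * vmap[y0, x0]
                 + fx * (1 - fy) * vmap[y0, min(x0 + 1, w - 1)]
                 + (1 - fx) * fy * vmap[min(y0 + 1, h - 1), x0]
                 + fx * fy * vmap[min(y0 + 1, h - 1), min(x0 + 1, w - 1)])
            manual[0, 0] += s / len(shapes)
            start += h * w
        expected = att.out_proj(Tensor(manual.reshape(1, 1, dim))).data
        np.testing.assert_allclose(out.data, expected, atol=1e-5)

    def test_reference_on_pixel_center_reproduces_pixel(self, rng):
        """Single level, zero offsets, weights concentrated on one point:
        sampling at a pixel center returns that pixel's value vector."""
        dim, heads = 4, 1
        att = DeformableAttention(dim, heads, 1, 1, rng)
        att.offset_proj.weight.data[:] = 0
        att.offset_proj.bias.data[:] = 0
        # identity value/out projections isolate the sampling itself
        att.value_proj.weight.data = np.eye(dim, dtype=np.float32)
        att.value_proj.bias.data[:] = 0
        att.out_proj.weight.data = np.eye(dim, dtype=np.float32)
        att.out_proj.bias.data[:] = 0
        h = w = 4
        memory = Tensor(rng.normal(size=(1, h * w, dim)).astype(np.float32))
        # pixel (row 2, col 1): center at ((1+0.5)/4, (2+0.5)/4)
        ref = np.array([[[1.5 / 4, 2.5 / 4]]], dtype=np.float32)
        out = att(Tensor(np.zeros((1, 1, dim), dtype=np.float32)), ref,
                  memory, [(h, w)])
        np.testing.assert_allclose(out.data[0, 0], memory.data[0, 2 * w + 1],
                                   atol=1e-5)


class TestEncoderDecoder:
    def test_encode_preserves_shape(self, tiny_model):
        pyr = extract_features(np.zeros((1, 3, 64, 64), dtype=np.float32),
                               tiny_model.backbone)
        content = tiny_model.project(pyr)
        refined = tiny_model.encode(content)
        assert refined.shape == content.tokens.shape

    def test_zero_encoder_layers_is_identity(self, tiny_config):
        import dataclasses
        cfg = dataclasses.replace(tiny_config, encoder_layers=0)
        model = WaveletDetector(cfg, seed=0)
        pyr = extract_features(np.random.default_rng(0)
                               .uniform(size=(1, 3, 64, 64))
                               .astype(np.float32), model.backbone)
        content = model.project(pyr)
        refined = model.encode(content)
        np.testing.assert_array_equal(refined.data, content.tokens.data)

    def test_select_topk_count_and_sort_oracle(self, tiny_model):
        pyr = extract_features(np.random.default_rng(5)
                               .uniform(size=(1, 3, 64, 64))
                               .astype(np.float32), tiny_model.backbone)
        content = tiny_model.project(pyr)
        refined = tiny_model.encode(content)
        delta, logits = tiny_model.head(0)(refined)
        queries, box_logits, enc_pred = tiny_model.select_topk(refined, content)
        k = tiny_model.config.num_queries
        assert queries.shape == (1, k, 64)
        assert enc_pred.boxes.shape == (1, k, 4)
        scores = logits.data[0].max(axis=-1)
        expected = set(np.argsort(-scores)[:k].tolist())
        sel_scores = np.sort(enc_pred.class_logits.data[0].max(-1))[::-1]
        np.testing.assert_allclose(sel_scores,
                                   np.sort(scores[list(expected)])[::-1],
                                   rtol=1e-6)

    def test_infinite_logit_always_selected(self, tiny_model):
        pyr = extract_features(np.random.default_rng(6)
                               .uniform(size=(1, 3, 64, 64))
                               .astype(np.float32), tiny_model.backbone)
        content = tiny_model.project(pyr)
        refined = tiny_model.encode(content)
        _, logits = tiny_model.head(0)(refined)
        logits.data[0, 123, 0] = np.inf
        scores = logits.data[0].max(-1)
        order = np.argsort(-scores)[:tiny_model.config.num_queries]
        assert 123 in order

    def test_token_count_below_k_raises(self, tiny_config):
        import dataclasses
        cfg = dataclasses.replace(tiny_config, num_queries=1000)
        model = WaveletDetector(cfg, seed=0)
        with pytest.raises(ValueError, match="smaller K|larger image|K="):
            model.forward(Tensor(np.zeros((1, 3, 64, 64), dtype=np.float32)))

    def test_zero_offsets_keep_initial_boxes_across_layers(self, tiny_model):
        # box MLPs end in a zeroed layer at init: delta b = 0 everywhere
        layers = tiny_model.forward(Tensor(
            np.random.default_rng(0).uniform(size=(1, 3, 64, 64))
            .astype(np.float32)))
        for later in layers[2:]:
            np.testing.assert_allclose(later.boxes.data, layers[1].boxes.data,
                                       atol=1e-6)

    def test_layer_cardinality(self, tiny_model):
        layers = tiny_model.forward(Tensor(np.zeros((1, 3, 64, 64),
                                                    dtype=np.float32)))
        assert len(layers) == tiny_model.config.decoder_layers + 1
        assert [l.layer_index for l in layers] == [0, 1, 2]

    def test_boxes_in_unit_interval_every_layer(self, tiny_model, rng):
        layers = tiny_model.forward(Tensor(
            rng.uniform(size=(2, 3, 64, 64)).astype(np.float32)))
        for l in layers:
            assert (l.boxes.data > 0).all() and (l.boxes.data < 1).all()

    def test_head_count_is_m_plus_one(self):
        cfg = ModelConfig(num_classes=2, hidden_dim=32, heads=4,
                          encoder_layers=1, decoder_layers=6, num_queries=10,
                          ffn_hidden_dim=32, backbone_channels=(8, 16, 32, 64))
        model = WaveletDetector(cfg, seed=0)
        heads = [k for k in model._modules if k.startswith("head")]
        assert len(heads) == 7

    def test_ffn_head_output_dims_and_zero_offsets(self, rng):
        from wavedet.detector import FFNHead
        cfg = ModelConfig(num_classes=5, hidden_dim=32, heads=4,
                          backbone_channels=(8, 16, 32, 64))
        head = FFNHead(cfg, rng)
        x = Tensor(rng.normal(size=(7, 32)).astype(np.float32))
        delta, logits = head(x)
        assert delta.shape == (7, 4)
        assert logits.shape == (7, 5)
        np.testing.assert_array_equal(delta.data, 0.0)  # zero-init last layer


class TestLookForwardTwice:
    def test_gradient_reaches_own_and_previous_refinement_only(self):
        """A box loss on decoder layer i updates the refinement heads of
        layers i and i-1 but not i-2."""
        cfg = ModelConfig(num_classes=2, hidden_dim=32, heads=4,
                          encoder_layers=1, decoder_layers=3, num_queries=10,
                          ffn_hidden_dim=32, backbone_channels=(8, 16, 32, 64),
                          deformable_points=2)
        model = WaveletDetector(cfg, seed=0)
        # make offsets nonzero so refinement parameters matter
        for i in range(1, 4):
            last = model.head(i).box_mlp._modules["lin2"]
            last.weight.data[:] = np.random.default_rng(i).normal(
                0, 0.01, last.weight.data.shape)
        layers = model.forward(Tensor(
            np.random.default_rng(0).uniform(size=(1, 3, 64, 64))
            .astype(np.float32)))
        # loss on the final decoder layer's boxes (i = 3)
        loss = layers[3].boxes.sum()
        model.zero_grad()
        loss.backward()
        def box_grad(i):
            head = model.head(i)
            return any(p.grad is not None and np.abs(p.grad).max() > 0
                       for p in head.box_mlp.parameters())
        assert box_grad(3)          # own refinement
        assert box_grad(2)          # previous layer (look forward twice)
        assert not box_grad(1)      # two layers back: blocked by detach


class TestPredict:
    def test_threshold_one_empty(self, tiny_model):
        recs = tiny_model.predict(np.zeros((3, 64, 64), dtype=np.float32),
                                  threshold=1.0)
        assert recs == []

    def test_threshold_zero_all_queries(self, tiny_model):
        recs = tiny_model.predict(np.zeros((3, 64, 64), dtype=np.float32),
                                  threshold=0.0)
        assert len(recs) == tiny_model.config.num_queries

    def test_box_rescaling_round_trip(self, tiny_model):
        from wavedet.data import box_xywh_to_normalized
        img = ImageTensor(np.zeros((3, 64, 64), dtype=np.float32), (64, 64))
        recs = tiny_model.predict(img, threshold=0.0)
        with no_grad():
            layers = tiny_model.forward(Tensor(img.data[None]))
        raw = layers[-1].boxes.data[0]
        by_score = sorted(
            range(len(raw)),
            key=lambda q: -layers[-1].class_logits.data[0, q].max())
        # records are score-sorted; invert rescaling and compare
        probs = 1 / (1 + np.exp(-layers[-1].class_logits.data[0]))
        order = np.argsort(-probs.max(-1), kind="stable")
        for rec, q in zip(recs, order):
            back = box_xywh_to_normalized(rec.bbox, 64, 64)
            np.testing.assert_allclose(back, raw[q], atol=1e-5)

    def test_forward_is_deterministic_and_fast(self, tiny_model):
        import time
        x = Tensor(np.full((1, 3, 64, 64), 0.25, dtype=np.float32))
        with no_grad():
            t0 = time.time()
            a = tiny_model.forward(x)
            dt = time.time() - t0
            b = tiny_model.forward(x)
        np.testing.assert_array_equal(a[-1].boxes.data, b[-1].boxes.data)
        assert dt < 5.0


class TestPerturbParameters:
    def test_fraction_zero_is_identity(self, tiny_config):
        model = WaveletDetector(tiny_config, seed=0)
        before = model.state_dict()
        perturb_parameters(model, 0.0, seed=1)
        after = model.state_dict()
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_same_seed_same_perturbation(self, tiny_config):
        models = []
        for _ in range(2):
            m = WaveletDetector(tiny_config, seed=0)
            perturb_parameters(m, 0.05, seed=42)
            models.append(m.state_dict())
        assert all(np.array_equal(models[0][k], models[1][k])
                   for k in models[0])

    def test_frozen_analysis_filters_exempt(self, tiny_config):
        model = WaveletDetector(tiny_config, seed=0)
        init = model._modules["wtp0"].bank(0).analysis.data.copy()
        perturb_parameters(model, 0.05, seed=3)
        np.testing.assert_array_equal(
            model._modules["wtp0"].bank(0).analysis.data, init)

    def test_relative_noise_sd_monte_carlo(self):
        """Over 1e6 elements, the sd of epsilon/|p| is 0.05 within 1%."""
        class Big(Module):
            def __init__(self):
                super().__init__()
                rng = np.random.default_rng(0)
                self.p = Parameter(rng.uniform(0.5, 2.0, (1000, 1000)))
        m = Big()
        before = m.p.data.copy()
        perturb_parameters(m, 0.05, seed=9)
        rel = (m.p.data - before) / np.abs(before)
        assert abs(rel.std() - 0.05) < 0.05 * 0.01


def test_inverse_sigmoid_round_trip(rng):
    x = rng.uniform(0.01, 0.99, 100).astype(np.float32)
    back = 1 / (1 + np.exp(-inverse_sigmoid(x)))
    np.testing.assert_allclose(back, x, atol=1e-5)
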