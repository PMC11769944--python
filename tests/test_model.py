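import numpy as np
import pytest
import autograd.numpy as anp
from autograd import grad

from specindexnet import model as mdl
from specindexnet import nn
from specindexnet.model import (BRANCH_NAMES, ModelConfig, adacos_scale,
                                band_attention_forward, fusion_head_forward,
                                gated_conv_forward, index_branch_forward,
                                init_model, mask_forward, model_forward,
                                multi_head_attention_forward, ucrn_forward,
                                uniform_gumbel_softmax)


@pytest.fixture(scope="module")
def ref_config():
    return ModelConfig()


@pytest.fixture(scope="module")
def ref_params(ref_config):
    return init_model(ref_config, seed=0)


@pytest.fixture(scope="module")
def small_config():
    return ModelConfig(gconv_channels=32, ucrn_channels=16, recurrent_hidden=16,
                       attn_channels=16, head_hidden=32)


@pytest.fixture(scope="module")
def small_params(small_config):
    return init_model(small_config, seed=1)


def direct_conv1d(w, b, x, kernel, dilation=1, padding=0):
    """Naive convolution oracle: explicit loops over output positions.
    Weight layout is (c_out, tap*c_in + cin)."""
    batch, c_in, length = x.shape
    c_out = w.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding)))
    l_out = xp.shape[2] - dilation * (kernel - 1)
    out = np.zeros((batch, c_out, l_out))
    for bidx in range(batch):
        for o in range(c_out):
            for pos in range(l_out):
                acc = b[o]
                for t in range(kernel):
                    for ci in range(c_in):
                        acc += w[o, t * c_in + ci] * xp[bidx, ci, pos + t * dilation]
                out[bidx, o, pos] = acc
    return out


class TestGatedConv:
    def test_output_shape_64x204(self, ref_params, ref_config):
        x = np.random.default_rng(0).uniform(0, 1, (1, 1, 204)).astype(np.float32)
        out = gated_conv_forward(ref_params["gconv"], x)
        assert np.asarray(out).shape == (1, 64, 204)

    def test_zero_input_zero_output(self, ref_config):
        params = init_model(ref_config, seed=3)
        x = np.zeros((2, 1, 204), dtype=np.float32)
        out = np.asarray(gated_conv_forward(params["gconv"], x))
        # biases are zero-initialised, so ReLU(0 * sigmoid(0)) = 0
        assert np.allclose(out, 0.0)

    def test_matches_direct_evaluation(self, small_params):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 1, (2, 1, 40)).astype(np.float32)
        p = small_params["gconv"]
        feat = direct_conv1d(np.asarray(p["feature"]["w"], float),
                             np.asarray(p["feature"]["b"], float), x, 5, 1, 2)
        gate = direct_conv1d(np.asarray(p["gate"]["w"], float),
                             np.asarray(p["gate"]["b"], float), x, 5, 1, 2)
        expected = np.maximum(feat * (1 / (1 + np.exp(-gate))), 0)
        got = np.asarray(gated_conv_forward(p, x))
        assert np.max(np.abs(got - expected)) < 1e-5


class TestUcrn:
    def test_output_shape_1x204(self, ref_params, ref_config):
        x = np.random.default_rng(1).uniform(0, 1, (1, 64, 204)).astype(np.float32)
        out = ucrn_forward(ref_params["ucrn"], x, ref_config)
        assert np.asarray(out).shape == (1, 1, 204)

    def test_encoder_pooled_lengths(self):
        lengths = []
        length = 204
        for _ in range(4):
            length //= 2
            lengths.append(length)
        assert lengths == [102, 51, 25, 12]
        # and maxpool1d actually produces them
        x = np.random.default_rng(0).normal(size=(1, 3, 204))
        for expect in (102, 51, 25, 12):
            x = np.asarray(nn.maxpool1d(x, 2))
            assert x.shape[2] == expect

    def test_finite_on_unit_inputs(self, ref_params, ref_config):
        x = np.random.default_rng(2).uniform(0, 1, (4, 64, 204)).astype(np.float32)
        out = np.asarray(ucrn_forward(ref_params["ucrn"], x, ref_config))
        assert np.all(np.isfinite(out))


class TestMask:
    def test_zero_input_zero_output(self, ref_params, ref_config):
        x = np.zeros((1, 1, 204), dtype=np.float32)
        out, mask = mask_forward(ref_params, x, ref_config)
        assert np.allclose(np.asarray(out), 0.0)

    def test_shape_preserved(self, ref_params, ref_config):
        x = np.random.default_rng(3).uniform(0, 1, (2, 1, 204)).astype(np.float32)
        out, mask = mask_forward(ref_params, x, ref_config)
        assert np.asarray(out).shape == (2, 1, 204)
        assert np.asarray(mask).shape == (2, 1, 204)


class TestAdacos:
    def test_s_closed_form(self):
        assert 2 * np.log(204) == pytest.approx(10.636, abs=1e-3)
        x = np.zeros(204)
        # constant x: B_i = 1, ln(B_avg) = 0, alpha = S*c
        c = 0.37
        alpha = adacos_scale(np.full(204, c), 204)
        assert float(alpha) == pytest.approx(2 * np.log(204) * c, abs=1e-6)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=204)
        s = 2 * np.log(204)
        b = np.exp(s * x - np.max(s * x))
        expected = np.max(s * x) + np.log(b.mean()) / np.cos(np.pi / 4)
        assert float(adacos_scale(x, 204)) == pytest.approx(expected, abs=1e-10)

    def test_errors(self):
        with pytest.raises(ValueError):
            adacos_scale(np.ones(5), 1)
        with pytest.raises(ValueError):
            adacos_scale(np.array([]), 10)


class TestUniformGumbelSoftmax:
    def test_soft_sums_to_one(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(7, 31))
        out = np.asarray(uniform_gumbel_softmax(logits, 1.0, 10.0, hard=False,
                                                rng=rng))
        assert np.allclose(out.sum(axis=-1), 1.0, atol=1e-9)
        assert np.all(out >= 0)

    def test_dominant_logit(self):
        logits = np.array([10.0, 0.0, 0.0])
        out = np.asarray(uniform_gumbel_softmax(logits, 0.01, 10.0, hard=False,
                                                rng=np.random.default_rng(0)))
        assert out[0] > 0.999

    def test_hard_exact_one_hot(self):
        rng = np.random.default_rng(1)
        logits = rng.normal(size=(13, 50))
        out = np.asarray(uniform_gumbel_softmax(logits, 1.0, 10.0, hard=True,
                                                rng=rng))
        assert np.all(out.sum(axis=-1) == 1.0)
        assert np.all((out == 0) | (out == 1))
        assert np.all((out == 1).sum(axis=-1) == 1)

    def test_parameter_errors(self):
        with pytest.raises(ValueError):
            uniform_gumbel_softmax(np.ones(3), 0.0, 10.0)
        with pytest.raises(ValueError):
            uniform_gumbel_softmax(np.ones(3), 1.0, -1.0)

    def test_hard_frequencies_match_independent_sampler(self):
        """Empirical selection frequencies vs a from-scratch Monte-Carlo
        re-implementation of argmax(logits + U[0,1)/shrink)."""
        logits = np.array([0.02, 0.05, 0.0, 0.04])
        n = 100_000
        rng = np.random.default_rng(2)
        out = np.asarray(uniform_gumbel_softmax(
            np.tile(logits, (n, 1)), 1.0, 10.0, hard=True, rng=rng))
        freq = out.mean(axis=0)

        oracle_rng = np.random.default_rng(123)
        draws = logits[None, :] + oracle_rng.random((n, 4)) / 10.0
        oracle = np.bincount(np.argmax(draws, axis=1), minlength=4) / n
        # both frequency estimates carry binomial error -> sd scales by sqrt(2)
        se = np.sqrt(oracle * (1 - oracle) / n)
        assert np.all(np.abs(freq - oracle) <= 3 * np.sqrt(2) * se + 1e-4)

    def test_straight_through_gradient_uses_soft(self):
        logits = np.array([0.3, 0.1, -0.2])

        def f(lg):
            out = uniform_gumbel_softmax(lg, 1.0, 10.0, hard=True, rng=None)
            return anp.sum(out * anp.array([1.0, 2.0, 3.0]))

        def f_soft(lg):
            out = uniform_gumbel_softmax(lg, 1.0, 10.0, hard=False, rng=None)
            return anp.sum(out * anp.array([1.0, 2.0, 3.0]))

        assert np.allclose(grad(f)(logits), grad(f_soft)(logits), atol=1e-10)


class TestBandAttention:
    def test_output_length_matches_channels(self, ref_params, ref_config):
        x = np.random.default_rng(0).uniform(0, 1, (1, 1, 204)).astype(np.float32)
        feats, _ = mask_forward(ref_params, x, ref_config)
        act, align, idx = band_attention_forward(ref_params["heads"][0],
                                                 np.asarray(feats), x, ref_config,
                                                 hard=True, rng=None)
        assert np.asarray(act).shape == (1, 64)

    def test_hard_rows_one_hot(self, small_params, small_config):
        x = np.random.default_rng(1).uniform(0, 1, (3, 1, 204)).astype(np.float32)
        feats, _ = mask_forward(small_params, x, small_config)
        _, align, _ = band_attention_forward(small_params["heads"][1],
                                             np.asarray(feats), x, small_config,
                                             hard=True, rng=None)
        align = np.asarray(align)
        assert np.all((align == 0) | (align == 1))
        assert np.all(align.sum(axis=-1) == 1)

    def test_hard_output_is_sigmoid_gather(self, small_params):
        # plain-gather contract: the adaptive-scale multiplier is turned off
        cfg = ModelConfig(gconv_channels=32, ucrn_channels=16,
                          recurrent_hidden=16, attn_channels=16,
                          head_hidden=32, scale_selected=False)
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, (2, 1, 204)).astype(np.float32)
        feats, _ = mask_forward(small_params, x, cfg)
        act, align, idx = band_attention_forward(small_params["heads"][2],
                                                 np.asarray(feats), x,
                                                 cfg, hard=True, rng=None)
        act = np.asarray(act)
        gathered = np.take_along_axis(np.broadcast_to(x[:, 0, :][:, None, :],
                                                      (2, idx.shape[1], 204)),
                                      idx[..., None], -1)[..., 0]
        expected = 1 / (1 + np.exp(-gathered))
        assert np.max(np.abs(act - expected)) < 1e-6

    def test_activations_in_open_unit_interval(self, small_params, small_config):
        x = np.random.default_rng(3).uniform(0, 1, (5, 1, 204)).astype(np.float32)
        feats, _ = mask_forward(small_params, x, small_config)
        act, _, _ = band_attention_forward(small_params["heads"][0],
                                           np.asarray(feats), x, small_config,
                                           hard=True, rng=None)
        act = np.asarray(act)
        assert np.all(act > 0) and np.all(act < 1)

    def test_fused_path_equals_per_head(self, small_params, small_config):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 1, (3, 1, 204)).astype(np.float32)
        feats, _ = mask_forward(small_params, x, small_config)
        feats = np.asarray(feats)
        acts, idx = multi_head_attention_forward(small_params["heads"], feats, x,
                                                 small_config, hard=True, rng=None)
        acts = np.asarray(acts)
        for i in range(mdl.N_HEADS):
            a, _, ih = band_attention_forward(small_params["heads"][i], feats, x,
                                              small_config, hard=True, rng=None)
            assert np.allclose(np.asarray(a), acts[:, i, :], atol=2e-6)
            assert np.array_equal(ih, idx[:, i, :])

    def test_channel_permutation_preserves_selected_band_set(self, small_params,
                                                             small_config):
        import copy
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 1, (1, 1, 204)).astype(np.float32)
        feats, _ = mask_forward(small_params, x, small_config)
        feats = np.asarray(feats)
        head = small_params["heads"][0]
        _, _, idx = band_attention_forward(head, feats, x, small_config,
                                           hard=True, rng=None)
        perm = rng.permutation(small_config.attn_channels)
        head2 = copy.deepcopy(head)
        head2["wl"] = head2["wl"][perm]
        _, _, idx2 = band_attention_forward(head2, feats, x, small_config,
                                            hard=True, rng=None)
        assert np.array_equal(idx2[0], idx[0][perm])


class TestIndexBranches:
    def test_add_mul_arithmetic(self):
        sel = {"R1": np.array([[0.5]]), "R2": np.array([[0.25]]),
               "R3": np.array([[0.8]]), "R4": np.array([[0.4]])}
        out = index_branch_forward(sel, "add_mul", eps=0.0)
        assert float(out[0, 0]) == pytest.approx(2.34375)

    def test_ratio_identity(self):
        sel = {"R1": np.array([[0.6]]), "R2": np.array([[0.6]])}
        assert float(index_branch_forward(sel, "ratio")[0, 0]) == pytest.approx(1.0, rel=1e-5)

    def test_double_diff_degenerate_finite(self):
        sel = {k: np.array([[0.5]]) for k in ("R1", "R2", "R3", "R4")}
        out = index_branch_forward(sel, "double_diff")
        assert np.isfinite(float(out[0, 0]))

    def test_missing_role_raises(self):
        with pytest.raises(ValueError):
            index_branch_forward({"R1": np.ones((1, 1))}, "ratio")
        with pytest.raises(ValueError):
            index_branch_forward({}, "nonsense")


class TestFusionHead:
    def test_scores_sum_to_one(self, small_params, small_config):
        rng = np.random.default_rng(0)
        feats = rng.normal(size=(4, 3, small_config.attn_channels)).astype(np.float32)
        _, scores = fusion_head_forward(small_params["fusion"], feats, small_config)
        assert np.allclose(np.asarray(scores).sum(axis=1), 1.0, atol=1e-6)

    def test_scalar_output(self, small_params, small_config):
        feats = np.zeros((2, 3, small_config.attn_channels), dtype=np.float32)
        pred, _ = fusion_head_forward(small_params["fusion"], feats, small_config)
        assert np.asarray(pred).shape == (2,)

    def test_wrong_branch_count_raises(self, small_params, small_config):
        with pytest.raises(ValueError):
            fusion_head_forward(small_params["fusion"],
                                np.zeros((1, 2, small_config.attn_channels)),
                                small_config)

    def test_saturated_gate_selects_single_branch(self, small_config):
        """Force the score conv to put all weight on one form; the output must
        equal the head applied to that branch alone."""
        params = init_model(small_config, seed=9)
        fusion = params["fusion"]
        fusion["score"]["w"] = np.array([[100.0, 0, 0]] * 3, dtype=np.float32).T * 0
        fusion["score"]["w"][:, 0] = 100.0     # every output row amplifies form 0
        fusion["score"]["b"] = np.array([100.0, -100.0, -100.0], dtype=np.float32)
        rng = np.random.default_rng(1)
        feats = rng.normal(size=(3, 3, small_config.attn_channels)).astype(np.float32)
        pred, scores = fusion_head_forward(fusion, feats, small_config)
        only_first = feats.copy()
        only_first[:, 1:, :] = feats[:, :1, :]
        pred2, _ = fusion_head_forward(fusion, only_first, small_config)
        assert np.allclose(np.asarray(scores)[:, 0, :], 1.0, atol=1e-6)
        assert np.allclose(np.asarray(pred), np.asarray(pred2), atol=1e-6)


class TestModelForward:
    def test_finite_prediction(self, small_params, small_config):
        x = np.random.default_rng(0).uniform(0, 1, (4, 204)).astype(np.float32)
        out = model_forward(small_params, small_config, x, hard=True, rng=None)
        assert np.all(np.isfinite(np.asarray(out["pred"])))

    def test_eval_mode_deterministic(self, small_params, small_config):
        x = np.random.default_rng(1).uniform(0, 1, (2, 204)).astype(np.float32)
        o1 = model_forward(small_params, small_config, x, hard=True, rng=None)
        o2 = model_forward(small_params, small_config, x, hard=True, rng=None)
        assert np.array_equal(np.asarray(o1["pred"]), np.asarray(o2["pred"]))

    def test_composition_matches_stagewise(self, small_params, small_config):
        """Full forward equals manual composition of the stage operations."""
        cfg = small_config
        x = np.random.default_rng(2).uniform(0, 1, (2, 204)).astype(np.float32)
        out = model_forward(small_params, cfg, x, hard=True, rng=None)

        xb = x.reshape(2, 1, 204)
        masked, _ = mask_forward(small_params, xb, cfg)
        masked = np.asarray(masked)
        role = {b: {} for b in BRANCH_NAMES}
        for i, branch, rname in mdl.iter_head_roles():
            act, _, _ = band_attention_forward(small_params["heads"][i], masked,
                                               xb, cfg, hard=True, rng=None)
            role[branch][rname] = np.asarray(act)
        feats = np.stack([np.clip(np.asarray(index_branch_forward(role[b], b,
                                                                  cfg.index_eps)),
                                  -cfg.branch_clip, cfg.branch_clip)
                          for b in BRANCH_NAMES], axis=1)
        pred, _ = fusion_head_forward(small_params["fusion"],
                                      feats.astype(np.float32), cfg)
        assert np.max(np.abs(np.asarray(out["pred"]) - np.asarray(pred))) < 1e-5

    def test_no_nan_over_many_random_spectra(self, small_params, small_config):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, (1000, 204)).astype(np.float32)
        out = model_forward(small_params, small_config, x, hard=True, rng=None)
        assert np.all(np.isfinite(np.asarray(out["pred"])))
        assert np.all(np.isfinite(np.asarray(out["form_scores"])))


class TestParameterCount:
    def test_single_linear_layer(self):
        p = nn.linear_init(np.random.default_rng(0), 64, 128)
        assert nn.count_parameters(p) == 64 * 128 + 128 == 8320

    def test_reference_config_under_one_million(self, ref_params):
        assert mdl.count_parameters(ref_params) <= 1_000_000

    def test_matches_shape_walk(self, ref_params):
        def walk(tree):
            if isinstance(tree, dict):
                return sum(walk(v) for v in tree.values())
            if isinstance(tree, (list, tuple)):
                return sum(walk(v) for v in tree)
            return int(np.prod(np.shape(tree)))
        assert mdl.count_parameters(ref_params) == walk(ref_params)


class TestConfigValidation:
    def test_bad_configs(self):
        with pytest.raises(ValueError):
            ModelConfig(gconv_channels=33)
        with pytest.raises(ValueError):
            ModelConfig(n_bands=8)
        with pytest.raises(ValueError):
            ModelConfig(gumbel_temperature=0)

    def test_checkpoint_roundtrip(self, small_params, small_config, tmp_path):
        wl = np.linspace(400, 1000, 204)
        mdl.save_model(small_params, small_config, wl, tmp_path / "ckpt")
        params, config, wl2 = mdl.load_model(tmp_path / "ckpt")
        assert config == small_config
        assert np.allclose(wl2, wl)
        x = np.random.default_rng(5).uniform(0, 1, (2, 204)).astype(np.float32)
        o1 = model_forward(small_params, small_config, x, hard=True, rng=None)
        o2 = model_forward(params, config, x, hard=True, rng=None)
        assert np.allclose(np.asarray(o1["pred"]), np.asarray(o2["pred"]))
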