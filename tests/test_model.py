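"""Architecture contracts: token arithmetic, shapes, attention properties,
the literal equation-by-equation encoder transcription oracle, exact GELU,
and the closed-form trainable-parameter accounting."""

import numpy as np
import pytest
from scipy.special import erf

from ctnet.autograd import Tensor
from ctnet.model import (ConfigError, CTNet, ModelConfig, build_model,
                         count_parameters, gelu, parameter_breakdown,
                         token_length, load_checkpoint, save_checkpoint)

from conftest import tiny_model_cfg


class TestTokenLength:
    @pytest.mark.parametrize("p2,expected",
                             [(8, 15), (6, 20), (1, 125), (10, 12)])
    def test_printed_token_sizes(self, p2, expected):
        assert token_length(1000, 8, p2) == expected

    def test_nonpositive_arguments_rejected(self):
        with pytest.raises(ConfigError):
            token_length(1000, 0, 8)

    @pytest.mark.parametrize("t,p1,p2", [(256, 8, 4), (1000, 8, 8),
                                         (333, 5, 7), (1000, 8, 6)])
    def test_matches_actual_forward_token_count(self, t, p1, p2):
        cfg = tiny_model_cfg(T=t, P1=p1, P2=p2, Kc1=8, Kc2=4, L=0)
        model = build_model(cfg).eval()
        s = model.conv_forward(np.zeros((1, 3, t)))
        assert s.shape == (1, token_length(t, p1, p2), cfg.d)


class TestBuild:
    def test_benchmark_geometries_build_and_emit_logits(self):
        m4 = build_model(ModelConfig.iv2a()).eval()
        assert m4(np.zeros((5, 22, 1000))).shape == (5, 4)
        m2 = build_model(ModelConfig.iv2b()).eval()
        assert m2(np.zeros((3, 3, 1000))).shape == (3, 2)

    def test_heads_must_divide_embedding(self):
        with pytest.raises(ConfigError, match="divisible"):
            build_model(ModelConfig.iv2a(h=3))    # d=16, 3 does not divide

    def test_zero_tokens_rejected(self):
        with pytest.raises(ConfigError, match="token"):
            build_model(tiny_model_cfg(T=16, P1=8, P2=4))


class TestConvModule:
    def test_iv2a_token_geometry(self):
        model = build_model(ModelConfig.iv2a()).eval()
        assert model.conv_forward(np.zeros((2, 22, 1000))).shape == (2, 15, 16)

    def test_p2_six_gives_twenty_tokens(self):
        model = build_model(ModelConfig.iv2a(P2=6)).eval()
        assert model.conv_forward(np.zeros((1, 22, 1000))).shape == (1, 20, 16)

    def test_zero_input_finite_in_eval_mode(self):
        model = build_model(ModelConfig.iv2b()).eval()
        out = model(np.zeros((2, 3, 1000)))
        assert np.isfinite(out.data).all()


class TestEncoder:
    def test_attention_rows_are_stochastic(self):
        cfg = tiny_model_cfg()
        model = build_model(cfg, seed=3).eval()
        x = np.random.default_rng(0).standard_normal((2, 3, cfg.T))
        model(x)
        for layer in model.layers:
            a = layer.last_attention
            assert (a >= 0).all()
            np.testing.assert_allclose(a.sum(axis=-1), 1.0, atol=1e-6)

    def test_identical_tokens_give_uniform_attention(self):
        cfg = tiny_model_cfg(L=1)
        model = build_model(cfg, seed=0).eval()
        t_c = cfg.token_count
        s = Tensor(np.tile(np.random.default_rng(1).standard_normal(cfg.d),
                           (1, t_c, 1)))
        model.encoder_forward(s)
        np.testing.assert_allclose(model.layers[0].last_attention,
                                   1.0 / t_c, atol=1e-6)

    def test_encoder_matches_equation_transcription(self):
        """Independent oracle: the attention / residual / feed-forward chain
        written out step by step in plain numpy from the defining equations."""
        cfg = ModelConfig(C=2, T=48, N=2, F1=1, D=2, Kc1=4, Kc2=2, P1=4,
                          P2=4, h=1, L=1, p1=0.0, p2=0.0, p_ffn=0.0)
        model = build_model(cfg, seed=7).eval()
        layer = model.layers[0]
        t_c, d = 3, cfg.d
        s = np.random.default_rng(5).standard_normal((1, t_c, d))

        def ln(x, gamma, beta, eps=1e-5):
            mu = x.mean(-1, keepdims=True)
            var = x.var(-1, keepdims=True)
            return (x - mu) / np.sqrt(var + eps) * gamma + beta

        wq, bq = layer.wq.weight.data, layer.wq.bias.data
        wk, bk = layer.wk.weight.data, layer.wk.bias.data
        wv, bv = layer.wv.weight.data, layer.wv.bias.data
        q, k, v = s @ wq + bq, s @ wk + bk, s @ wv + bv
        scores = q @ k.transpose(0, 2, 1) / np.sqrt(d / cfg.h)
        e_s = np.exp(scores - scores.max(-1, keepdims=True))
        a = e_s / e_s.sum(-1, keepdims=True)
        mha = (a @ v) @ layer.wo.weight.data + layer.wo.bias.data
        o = ln(mha + s, layer.ln1.gamma.data, layer.ln1.beta.data)
        hidden = o @ layer.ff1.weight.data + layer.ff1.bias.data
        hidden = hidden * 0.5 * (1 + erf(hidden / np.sqrt(2)))
        pf = hidden @ layer.ff2.weight.data + layer.ff2.bias.data
        expected = ln(pf + o, layer.ln2.gamma.data, layer.ln2.beta.data)

        actual = model.encoder_forward(Tensor(s.astype(np.float32))).data
        np.testing.assert_allclose(actual, expected, atol=1e-5)


class TestGelu:
    def test_zero_fixed_point(self):
        assert gelu(0.0) == 0.0

    def test_approaches_identity_for_large_input(self):
        assert gelu(10.0) == pytest.approx(10.0, abs=1e-6)

    def test_value_at_one_is_normal_cdf(self):
        assert gelu(1.0) == pytest.approx(0.841345, abs=1e-6)


class TestClassifier:
    def test_zero_encoder_output_is_conv_only_path(self):
        model = build_model(ModelConfig.iv2a()).eval()
        x = np.random.default_rng(0).standard_normal((2, 22, 1000))
        s = model.conv_forward(x)
        zero_e = Tensor(np.zeros_like(s.data))
        ablated = model.classify(s, zero_e).data
        b = s.shape[0]
        direct = (s.reshape(b, -1).data @ model.fc.weight.data
                  + model.fc.bias.data)
        np.testing.assert_allclose(ablated, direct, atol=1e-6)

    def test_flatten_geometry_and_softmax_normalization(self):
        model = build_model(ModelConfig.iv2a()).eval()
        assert model.fc.weight.shape == (240, 4)    # 15 tokens x 16 channels
        logits = model(np.random.default_rng(1).standard_normal((3, 22, 1000)))
        p = np.exp(logits.data) / np.exp(logits.data).sum(1, keepdims=True)
        np.testing.assert_allclose(p.sum(1), 1.0, atol=1e-6)

    def test_shape_mismatch_rejected(self):
        model = build_model(tiny_model_cfg()).eval()
        s = model.conv_forward(np.zeros((1, 3, 256)))
        with pytest.raises(ValueError, match="shape"):
            model.classify(s, Tensor(np.zeros((1, 2, 2))))


def expected_parameter_count(cfg: ModelConfig) -> int:
    """Closed-form accounting: bias-free convolutions + affine batch norms,
    biased attention/feed-forward linears + affine layer norms, one final
    fully-connected layer."""
    d = cfg.d
    conv = (cfg.F1 * cfg.Kc1 + 2 * cfg.F1            # temporal conv + BN
            + cfg.F1 * cfg.D * cfg.C + 2 * d         # depthwise conv + BN
            + d * d * cfg.Kc2 + 2 * d)               # spatial conv + BN
    per_layer = (4 * (d * d + d)                     # W^Q,W^K,W^V,W^O + biases
                 + 2 * 2 * d                         # two layer norms
                 + d * cfg.ffn_mult * d + cfg.ffn_mult * d
                 + cfg.ffn_mult * d * d + d)         # feed-forward
    classifier = cfg.token_count * d * cfg.N + cfg.N
    return conv + cfg.L * per_layer + classifier


class TestParameterAccounting:
    @pytest.mark.parametrize("cfg,expected", [
        (ModelConfig.iv2a(), 25_684),
        (ModelConfig.iv2b(), 24_898),
        (ModelConfig.iv2a(L=0), 6_004),
    ])
    def test_benchmark_counts(self, cfg, expected):
        assert count_parameters(build_model(cfg)) == expected

    def test_breakdown_blocks(self):
        bd = parameter_breakdown(build_model(ModelConfig.iv2a()))
        assert bd == {"conv_module": 5040, "encoder": 6 * 3280,
                      "classifier": 964, "total": 25_684}

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_closed_form_over_random_configs(self, seed):
        rng = np.random.default_rng(seed)
        f1 = int(rng.choice([2, 4, 8]))
        dmul = int(rng.choice([1, 2]))
        d = f1 * dmul
        heads = int(rng.choice([h for h in (1, 2, 4) if d % h == 0]))
        cfg = ModelConfig(C=int(rng.integers(2, 8)), T=512,
                          N=int(rng.integers(2, 5)), F1=f1, D=dmul,
                          Kc1=int(rng.integers(4, 33)),
                          Kc2=int(rng.integers(2, 9)),
                          P1=int(rng.choice([4, 8])),
                          P2=int(rng.choice([2, 4, 8])), h=heads,
                          L=int(rng.integers(0, 4)),
                          ffn_mult=int(rng.choice([2, 4])))
        assert count_parameters(build_model(cfg)) == expected_parameter_count(cfg)


class TestDeterminismAndCheckpoint:
    def test_inference_deterministic_in_eval_mode(self):
        model = build_model(tiny_model_cfg(), seed=2).eval()
        x = np.random.default_rng(3).standard_normal((4, 3, 256))
        a = model(x).data
        b = model(x).data
        np.testing.assert_array_equal(a, b)

    def test_checkpoint_round_trip(self, tmp_path):
        model = build_model(tiny_model_cfg(), seed=4).eval()
        x = np.random.default_rng(5).standard_normal((2, 3, 256))
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        back = load_checkpoint(path).eval()
        np.testing.assert_array_equal(model(x).data, back(x).data)
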