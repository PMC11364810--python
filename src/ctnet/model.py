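"""The convolutional-Transformer decoder (CTNet architecture).

Per trial, a three-layer convolutional module (temporal convolution,
channel depth-wise convolution, spatial convolution — EEGNet-style, but with
a plain 1-D spatial convolution instead of a separable one) compresses a
``C x T`` standardized EEG trial into a token sequence ``S`` of shape
``T_C x d``, where ``T_C = floor(floor(T / P1) / P2)`` after the two average
pooling stages and ``d = F2`` feature channels.  A post-norm Transformer
encoder of depth ``L`` (multi-head scaled dot-product attention, position-wise
feed-forward with exact-erf GELU; no positional encoding) refines the tokens
into ``E``.  The classifier adds ``S + E`` elementwise (a residual fusion of
convolutional and encoded features), flattens, applies dropout and a single
fully-connected layer to ``N`` logits.

Convolution layers carry no biases (each is followed by batch normalization);
attention and feed-forward linear layers do carry biases.  With the default
hyperparameters this yields 25,684 trainable parameters at (C=22, T=1000,
N=4) and 24,898 at (C=3, T=1000, N=2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf as _erf

from . import nn
from .autograd import Tensor, gelu_exact, matmul, softmax_lastdim
from .nn import count_parameters  # re-exported

__all__ = ["ModelConfig", "CTNet", "token_length", "build_model",
           "count_parameters", "gelu", "parameter_breakdown"]


class ConfigError(ValueError):
    """Inconsistent architecture hyperparameters."""


def token_length(t: int, p1: int, p2: int) -> int:
    """Token count after two successive average-pooling stages (integer floor
    at each stage)."""
    if t <= 0 or p1 <= 0 or p2 <= 0:
        raise ConfigError(f"non-positive pooling arguments ({t}, {p1}, {p2})")
    return (t // p1) // p2


def gelu(x):
    """GELU(x) = x * Phi(x), with Phi the exact standard-normal CDF."""
    arr = np.asarray(x, dtype=np.float64)
    out = arr * 0.5 * (1.0 + _erf(arr / np.sqrt(2.0)))
    return out if out.ndim else float(out)


@dataclass
class ModelConfig:
    """Architecture hyperparameters; defaults are the global settings shared
    by both benchmark geometries."""

    C: int = 22                # EEG channels
    T: int = 1000              # samples per trial
    N: int = 4                 # classes
    F1: int = 8                # temporal filters
    Kc1: int = 64              # temporal kernel length (1/4 of 250 Hz)
    D: int = 2                 # depth multiplier of the depth-wise conv
    Kc2: int = 16              # spatial conv kernel length
    P1: int = 8                # first average-pooling length
    P2: int = 8                # second average-pooling length
    h: int = 2                 # attention heads
    L: int = 6                 # encoder depth (0 = conv + classifier only)
    ffn_mult: int = 4          # feed-forward expansion (d -> ffn_mult*d)
    p1: float = 0.5            # conv-module dropout (0.25 for cross-subject)
    p2: float = 0.5            # classifier dropout
    p_ffn: float = 0.5         # dropout between the feed-forward linears
    bn_eps: float = 1e-5       # batch-norm epsilon (framework default)
    bn_momentum: float = 0.1   # batch-norm running-stat momentum

    @property
    def F2(self) -> int:       # spatial filters = embedding size d
        return self.F1 * self.D

    @property
    def d(self) -> int:
        return self.F2

    @property
    def d_k(self) -> int:
        return self.d // self.h

    def validate(self) -> None:
        if self.d % self.h != 0:
            raise ConfigError(f"d={self.d} not divisible by h={self.h}")
        if token_length(self.T, self.P1, self.P2) < 1:
            raise ConfigError(
                f"pooling ({self.P1}, {self.P2}) leaves zero tokens for T={self.T}")
        for name in ("p1", "p2", "p_ffn"):
            p = getattr(self, name)
            if not 0.0 <= p < 1.0:
                raise ConfigError(f"dropout {name}={p} outside [0, 1)")
        if self.L < 0:
            raise ConfigError("encoder depth L must be >= 0")

    @property
    def token_count(self) -> int:
        return token_length(self.T, self.P1, self.P2)

    @classmethod
    def iv2a(cls, **kw) -> "ModelConfig":
        return cls(C=22, T=1000, N=4, **kw)

    @classmethod
    def iv2b(cls, **kw) -> "ModelConfig":
        return cls(C=3, T=1000, N=2, **kw)


class EncoderLayer(nn.Module):
    """One post-norm encoder layer: multi-head attention + feed-forward,
    each wrapped as LN(sublayer(x) + x)."""

    def __init__(self, cfg: ModelConfig, rng, drop_rng):
        super().__init__()
        d = cfg.d
        self.h = cfg.h
        self.d_k = cfg.d_k
        self.wq = nn.Linear(d, d, rng)
        self.wk = nn.Linear(d, d, rng)
        self.wv = nn.Linear(d, d, rng)
        self.wo = nn.Linear(d, d, rng)
        self.ln1 = nn.LayerNorm(d)
        self.ff1 = nn.Linear(d, cfg.ffn_mult * d, rng)
        self.ff2 = nn.Linear(cfg.ffn_mult * d, d, rng)
        self.drop_ffn = nn.Dropout(cfg.p_ffn, drop_rng)
        self.ln2 = nn.LayerNorm(d)
        self.last_attention: np.ndarray | None = None  # (B, h, T_C, T_C)

    def _split_heads(self, x: Tensor, b: int, t: int) -> Tensor:
        return x.reshape(b, t, self.h, self.d_k).transpose(0, 2, 1, 3)

    def attention(self, x: Tensor) -> Tensor:
        b, t, _ = x.shape
        q = self._split_heads(self.wq(x), b, t)
        k = self._split_heads(self.wk(x), b, t)
        v = self._split_heads(self.wv(x), b, t)
        scores = matmul(q, k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.d_k))
        weights = softmax_lastdim(scores)          # rows sum to 1 over keys
        self.last_attention = weights.data
        z = matmul(weights, v)                     # (B, h, T_C, d_k)
        z = z.transpose(0, 2, 1, 3).reshape(b, t, self.h * self.d_k)
        return self.wo(z)

    def __call__(self, x: Tensor) -> Tensor:
        o = self.ln1(self.attention(x) + x)
        ff = self.ff2(self.drop_ffn(gelu_exact(self.ff1(o))))
        return self.ln2(ff + o)


class CTNet(nn.Module):
    """Full pipeline: conv module -> L encoder layers -> residual classifier."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
        self.drop_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
        f1, f2 = cfg.F1, cfg.F2
        self.conv_t = nn.Conv2d(1, f1, (1, cfg.Kc1), "same-w", rng=rng)
        self.bn1 = nn.BatchNorm2d(f1, cfg.bn_eps, cfg.bn_momentum)
        self.conv_dw = nn.Conv2d(f1, f1 * cfg.D, (cfg.C, 1), groups=f1, rng=rng)
        self.bn2 = nn.BatchNorm2d(f2, cfg.bn_eps, cfg.bn_momentum)
        self.pool1 = nn.AvgPoolW(cfg.P1)
        self.drop1 = nn.Dropout(cfg.p1, self.drop_rng)
        self.conv_s = nn.Conv2d(f2, f2, (1, cfg.Kc2), "same-w", rng=rng)
        self.bn3 = nn.BatchNorm2d(f2, cfg.bn_eps, cfg.bn_momentum)
        self.pool2 = nn.AvgPoolW(cfg.P2)
        self.drop2 = nn.Dropout(cfg.p1, self.drop_rng)
        self.layers = [EncoderLayer(cfg, rng, self.drop_rng)
                       for _ in range(cfg.L)]
        self.drop_cls = nn.Dropout(cfg.p2, self.drop_rng)
        self.fc = nn.Linear(cfg.token_count * cfg.d, cfg.N, rng)

    # -- stages ------------------------------------------------------------
    def conv_forward(self, x) -> Tensor:
        """(B, C, T) trials -> token sequence S of shape (B, T_C, d)."""
        x = self._as_input(x)
        b = x.shape[0]
        if x.shape[2] != self.cfg.C or x.shape[3] != self.cfg.T:
            raise ValueError(
                f"expected trials shaped ({self.cfg.C}, {self.cfg.T}),"
                f" got {x.shape[2:]}")
        y = self.bn1(self.conv_t(x))
        y = self.drop1(self.pool1(self.bn2(self.conv_dw(y)).elu()))
        y = self.drop2(self.pool2(self.bn3(self.conv_s(y)).elu()))
        # (B, d, 1, T_C) -> (B, T_C, d): one token per retained time point
        return y.reshape(b, self.cfg.d, -1).transpose(0, 2, 1)

    def encoder_forward(self, s: Tensor) -> Tensor:
        e = s
        for layer in self.layers:
            e = layer(e)
        return e

    def classify(self, s: Tensor, e: Tensor) -> Tensor:
        if s.shape != e.shape:
            raise ValueError(f"S {s.shape} and E {e.shape} differ in shape")
        b = s.shape[0]
        fused = (s + e).reshape(b, -1)
        return self.fc(self.drop_cls(fused))

    def __call__(self, x) -> Tensor:
        s = self.conv_forward(x)
        e = self.encoder_forward(s)
        return self.classify(s, e)

    # -- helpers -----------------------------------------------------------
    @staticmethod
    def _as_input(x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=nn.DTYPE))
        if x.ndim == 2:
            x = x.reshape(1, 1, *x.shape)
        elif x.ndim == 3:
            x = x.reshape(x.shape[0], 1, x.shape[1], x.shape[2])
        return x

    def predict_logits(self, data: np.ndarray, batch: int = 256) -> np.ndarray:
        """Deterministic evaluation-mode logits for an array of trials."""
        was_training = self.training
        self.eval()
        out = []
        for lo in range(0, len(data), batch):
            out.append(self(data[lo:lo + batch]).data.copy())
        self.train(was_training)
        return np.concatenate(out) if out else np.empty((0, self.cfg.N))

    def predict(self, data: np.ndarray, batch: int = 256) -> np.ndarray:
        return self.predict_logits(data, batch).argmax(axis=1)


def build_model(cfg: ModelConfig, seed: int = 0) -> CTNet:
    """Construct the model, validating the configuration."""
    return CTNet(cfg, seed=seed)


def parameter_breakdown(model: CTNet) -> dict[str, int]:
    """Closed-form-checkable accounting of trainable parameters by block."""
    cfg = model.cfg

    def block(mods) -> int:
        return sum(count_parameters(m) for m in mods)

    conv = block([model.conv_t, model.bn1, model.conv_dw, model.bn2,
                  model.conv_s, model.bn3])
    encoder = block(model.layers)
    classifier = count_parameters(model.fc)
    return {"conv_module": conv, "encoder": encoder, "classifier": classifier,
            "total": conv + encoder + classifier}


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: CTNet, path) -> None:
    """Architecture config + weights in a single .npz file."""
    import json
    cfg_json = json.dumps({k: v for k, v in model.cfg.__dict__.items()})
    np.savez(path, __config__=np.frombuffer(cfg_json.encode(), dtype=np.uint8),
             **model.state_dict())


def load_checkpoint(path) -> CTNet:
    import json
    with np.load(path) as z:
        cfg = ModelConfig(**json.loads(bytes(z["__config__"]).decode()))
        model = CTNet(cfg)
        state = {k: z[k] for k in z.files if k != "__config__"}
    model.load_state_dict(state)
    return model
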