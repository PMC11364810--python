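"""Shared fixtures.

The expensive end-to-end fixture (training the full decoder on synthetic
motor-imagery trials at three modulation depths) is session-scoped so the
smoke tests and the monotonicity check share one set of training runs.
"""

from __future__ import annotations

import numpy as np
import pytest

from ctnet.model import ModelConfig
from ctnet.preprocess import AugmentConfig
from ctnet.synthetic import SynthConfig, generate_mi_trials
from ctnet.training import TrainConfig, run_subject_specific


def tiny_model_cfg(**kw) -> ModelConfig:
    """A fast geometry (T=256) preserving every architectural stage."""
    base = dict(C=3, T=256, N=2, F1=4, D=2, Kc1=16, Kc2=8, P1=8, P2=4,
                h=2, L=2, p1=0.25, p2=0.25, p_ffn=0.25)
    base.update(kw)
    return ModelConfig(**base)


@pytest.fixture(scope="session")
def small_trialset():
    return generate_mi_trials(SynthConfig(n_per_class=10, C=3, T=256,
                                          effect=1.0, seed=42))


@pytest.fixture(scope="session")
def e2e_results():
    """Held-out accuracy of the full pipeline at effect 0, 1 and 3.

    Strong-effect condition: 100 trials/class for training, an independent
    100/class test session, 30 training epochs — the decoder must separate
    an (1+3)-fold band-power contrast essentially perfectly, while the
    zero-effect condition must stay at chance.
    """
    out = {}
    for eff in (0.0, 1.0, 3.0):
        train = generate_mi_trials(SynthConfig(n_per_class=100, effect=eff,
                                               seed=11))
        test = generate_mi_trials(SynthConfig(n_per_class=100, effect=eff,
                                              seed=12))
        train.subject_id = test.subject_id = "S01"
        test.session_tag = "test"
        cfg = TrainConfig(epochs=30, batch_size=64, seed=0,
                          augment=AugmentConfig(K=8, multiplier=1, seed=0))
        res = run_subject_specific([(train, test)], ModelConfig.iv2b(), cfg)
        out[eff] = res[0]
    return out
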