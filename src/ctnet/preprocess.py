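"""Per-trial standardization and segmentation-and-recombination augmentation.

Standardization is a scalar Z-score over all C x T entries of a trial (mean 0,
population standard deviation 1).  It is applied before augmentation, so
artificial trials are recombinations of standardized segments.

S&R augmentation splits every training trial into K equal contiguous temporal
segments and builds artificial trials by concatenating, in original temporal
order, segment k of a uniformly chosen same-class trial for each position k.
Classes are never mixed and validation/test data are never augmented.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np

from .trialset import TrialSet


class DegenerateTrialError(ValueError):
    """A trial with zero variance cannot be standardized."""


@dataclass
class AugmentConfig:
    K: int = 8            # segments per trial; T must be divisible by K
    multiplier: int = 1   # artificial trials per original trial (0 = off)
    seed: int = 0

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.multiplier < 0:
            raise ValueError("multiplier must be >= 0")


def zscore_trial(trial: np.ndarray) -> np.ndarray:
    """(trial - mean) / std with scalar statistics over all C*T entries.

    Uses the population standard deviation (denominator C*T).  Idempotent up
    to numerical tolerance; rejects constant trials.
    """
    trial = np.asarray(trial, dtype=np.float64)
    mu = trial.mean()
    sd = trial.std()
    if sd == 0:
        raise DegenerateTrialError("constant trial: standard deviation is zero")
    return (trial - mu) / sd


def zscore_trialset(ts: TrialSet) -> TrialSet:
    """Apply :func:`zscore_trial` independently to every trial."""
    out = np.empty(ts.data.shape, dtype=np.float64)
    for i in range(ts.n_trials):
        out[i] = zscore_trial(ts.data[i])
    return _dc_replace(ts, data=out)


def segment_recombine(ts: TrialSet, cfg: AugmentConfig) -> TrialSet:
    """Generate artificial same-class trials by segment recombination.

    Returns only the artificial trials — ``multiplier * n_trials`` of them,
    class counts proportional to the input's.  Each artificial trial of class
    c concatenates K verbatim segments, segment k drawn from segment position
    k of a uniformly chosen class-c original.  Deterministic given
    ``cfg.seed``.
    """
    t = ts.n_samples
    if t % cfg.K != 0:
        raise ValueError(f"T={t} not divisible by K={cfg.K}")
    for c in range(ts.n_classes):
        if not ts.prediction_only and len(ts.class_indices(c)) == 0:
            raise ValueError(f"class {c} has no trials to recombine")
    rng = np.random.default_rng(cfg.seed)
    seg_len = t // cfg.K
    n_art = cfg.multiplier * ts.n_trials
    data = np.empty((n_art, ts.n_channels, t), dtype=ts.data.dtype)
    labels = np.empty(n_art, dtype=np.int64)
    i = 0
    for c in np.unique(ts.labels):
        pool = ts.class_indices(int(c))
        per_class = cfg.multiplier * len(pool)
        # (per_class, K) uniform choices of source trial per segment position
        src = rng.integers(0, len(pool), size=(per_class, cfg.K))
        for row in src:
            for k, j in enumerate(row):
                sl = slice(k * seg_len, (k + 1) * seg_len)
                data[i, :, sl] = ts.data[pool[j], :, sl]
            labels[i] = c
            i += 1
    return _dc_replace(ts, data=data[:i], labels=labels[:i],
                       prediction_only=True)


def concat_trialsets(a: TrialSet, b: TrialSet) -> TrialSet:
    """Stack two compatible trial sets (e.g. originals + artificial trials)."""
    if a.data.shape[1:] != b.data.shape[1:] or a.n_classes != b.n_classes:
        raise ValueError("trial sets are not compatible")
    return _dc_replace(a, data=np.concatenate([a.data, b.data]),
                       labels=np.concatenate([a.labels, b.labels]),
                       prediction_only=a.prediction_only or b.prediction_only)
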