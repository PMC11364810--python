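"""Subject-specific and leave-one-subject-out training protocols.

Both protocols share the same inner loop: standardize per trial, hold out a
stratified random validation fraction, optionally expand the *training
portion only* with S&R augmentation, optimize the categorical cross-entropy
with Adam (lr 0.001, betas (0.5, 0.999)), and keep the weight snapshot with
the minimum validation loss.  No early stopping: all epochs run.  When the
configured batch size exceeds the training-set size a single full batch is
used per epoch.  Everything is reproducible given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np

from .autograd import Tensor
from .metrics import SubjectResult, confusion_matrix, subject_result
from .model import CTNet, ModelConfig, build_model
from .nn import Adam, DTYPE
from .preprocess import (AugmentConfig, concat_trialsets, segment_recombine,
                         zscore_trialset)
from .trialset import TrialSet


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    beta1: float = 0.5
    beta2: float = 0.999
    batch_size: int = 288           # 512 for LOSO in the benchmark protocol
    epochs: int = 1000              # 600 for LOSO in the benchmark protocol
    val_fraction: float = 0.30
    seed: int = 0
    augment: AugmentConfig | None = field(default_factory=AugmentConfig)
    dropout_profile: str = "subject_specific"   # or "cross_subject" (p1=0.25)

    def __post_init__(self):
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must lie strictly in (0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.dropout_profile not in ("subject_specific", "cross_subject"):
            raise ValueError(f"unknown dropout profile {self.dropout_profile!r}")

    def conv_dropout(self) -> float:
        return 0.5 if self.dropout_profile == "subject_specific" else 0.25


@dataclass
class FitHistory:
    train_loss: list[float]
    val_loss: list[float]
    val_accuracy: list[float]
    selected_epoch: int


class SplitError(ValueError):
    pass


def split_train_val(ts: TrialSet, val_fraction: float,
                    seed: int) -> tuple[TrialSet, TrialSet]:
    """Stratified random split; per-class validation count within one trial
    of ``val_fraction``; deterministic given ``seed``."""
    if not 0 < val_fraction < 1:
        raise SplitError(f"val_fraction must lie in (0, 1), got {val_fraction}")
    rng = np.random.default_rng(seed)
    sizes = []
    for c in range(ts.n_classes):
        n_c = len(ts.class_indices(c))
        if n_c < 2:
            raise SplitError(f"class {c} has {n_c} trial(s); need >= 2")
        sizes.append(n_c)
    # largest-remainder apportionment of the total validation count, so the
    # overall fraction is exact and each class is within one trial of it
    targets = [val_fraction * n_c for n_c in sizes]
    n_val = [int(t) for t in targets]
    remainder = int(round(sum(targets))) - sum(n_val)
    order = sorted(range(len(sizes)), key=lambda c: targets[c] - n_val[c],
                   reverse=True)
    for c in order[:max(remainder, 0)]:
        n_val[c] += 1
    train_idx, val_idx = [], []
    for c in range(ts.n_classes):
        idx = ts.class_indices(c)
        perm = rng.permutation(idx)
        k = min(max(n_val[c], 1), len(idx) - 1)
        val_idx.extend(perm[:k])
        train_idx.extend(perm[k:])
    return ts.subset(np.sort(train_idx)), ts.subset(np.sort(val_idx))


def cross_entropy(probs: np.ndarray, onehot: np.ndarray,
                  eps: float = 1e-12) -> float:
    """Mean categorical cross-entropy -(1/M) sum_ij y_ij log p_ij.

    ``probs`` rows must sum to 1; logs are clamped at ``eps`` so a zero
    probability at a true label yields a large finite loss.
    """
    probs = np.asarray(probs, dtype=np.float64)
    onehot = np.asarray(onehot, dtype=np.float64)
    if probs.shape != onehot.shape:
        raise ValueError("probs and labels differ in shape")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    return float(-(onehot * np.log(np.clip(probs, eps, None))).sum()
                 / probs.shape[0])


def _loss_from_logits(logits, labels: np.ndarray):
    """Stable autograd cross-entropy from logits (log-sum-exp form)."""
    n, k = logits.shape
    shift = Tensor(logits.data.max(axis=1, keepdims=True))
    z = logits - shift
    logp = z - z.exp().sum(axis=1, keepdims=True).log()
    onehot = np.eye(k, dtype=np.float64)[labels]
    return -(logp * Tensor(onehot)).sum() * (1.0 / n)


def fit(model: CTNet, train: TrialSet, val: TrialSet,
        cfg: TrainConfig) -> tuple[CTNet, FitHistory]:
    """Adam optimization with best-validation-loss model selection."""
    if train.n_trials == 0 or val.n_trials == 0:
        raise ValueError("training and validation sets must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    xtr = train.data.astype(DTYPE)
    ytr = train.labels
    opt = Adam(model.parameters(), lr=cfg.learning_rate,
               betas=(cfg.beta1, cfg.beta2))
    batch = min(cfg.batch_size, train.n_trials)
    hist = FitHistory([], [], [], 0)
    best_loss, best_state = np.inf, None
    for _epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(train.n_trials)
        losses = []
        for lo in range(0, train.n_trials, batch):
            sel = order[lo:lo + batch]
            logits = model(xtr[sel])
            loss = _loss_from_logits(logits, ytr[sel])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data) * len(sel))
        hist.train_loss.append(sum(losses) / train.n_trials)
        vlogits = model.predict_logits(val.data.astype(DTYPE))
        vloss = float(_loss_from_logits(Tensor(vlogits), val.labels).data)
        vacc = float((vlogits.argmax(axis=1) == val.labels).mean())
        hist.val_loss.append(vloss)
        hist.val_accuracy.append(vacc)
        if vloss < best_loss:
            best_loss = vloss
            best_state = model.state_dict()
            hist.selected_epoch = _epoch
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, hist


def prepare_training_data(ts: TrialSet, cfg: TrainConfig) -> tuple[TrialSet, TrialSet]:
    """Standardize, split off validation, then augment the training part only."""
    ts = zscore_trialset(ts)
    tr, va = split_train_val(ts, cfg.val_fraction, cfg.seed)
    if cfg.augment is not None and cfg.augment.multiplier > 0:
        aug = segment_recombine(tr, _dc_replace(cfg.augment,
                                                seed=cfg.augment.seed + cfg.seed))
        tr = concat_trialsets(tr, aug)
    return tr, va


def _evaluate(model: CTNet, test: TrialSet) -> SubjectResult:
    if test.n_trials == 0:
        raise ValueError(f"subject {test.subject_id!r} has an empty test set")
    test = zscore_trialset(test)
    pred = model.predict(test.data.astype(DTYPE))
    cm = confusion_matrix(test.labels, pred, test.n_classes)
    return subject_result(test.subject_id, cm)


def run_subject_specific(pairs: list[tuple[TrialSet, TrialSet]],
                         model_cfg: ModelConfig,
                         train_cfg: TrainConfig,
                         histories: list | None = None) -> list[SubjectResult]:
    """Train and evaluate each subject independently on their own sessions."""
    results = []
    for train_ts, test_ts in pairs:
        if train_ts.subject_id != test_ts.subject_id:
            raise ValueError(
                f"mismatched subject pair: {train_ts.subject_id!r} vs"
                f" {test_ts.subject_id!r}")
        mc = _dc_replace(model_cfg, p1=train_cfg.conv_dropout())
        model = build_model(mc, seed=train_cfg.seed)
        tr, va = prepare_training_data(train_ts, train_cfg)
        model, hist = fit(model, tr, va, train_cfg)
        if histories is not None:
            histories.append(hist)
        results.append(_evaluate(model, test_ts))
    return results


def run_loso(subjects: list[TrialSet], model_cfg: ModelConfig,
             train_cfg: TrainConfig,
             histories: list | None = None) -> list[SubjectResult]:
    """Leave-one-subject-out: pool all other subjects as training data."""
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    if train_cfg.dropout_profile != "cross_subject":
        train_cfg = _dc_replace(train_cfg, dropout_profile="cross_subject")
    results = []
    for held in range(len(subjects)):
        pool = [s for i, s in enumerate(subjects) if i != held]
        if any(s.n_trials == 0 for s in pool) or subjects[held].n_trials == 0:
            raise ValueError("empty subject in LOSO pool")
        merged = pool[0]
        for s in pool[1:]:
            merged = concat_trialsets(merged, s)
        mc = _dc_replace(model_cfg, p1=train_cfg.conv_dropout())
        model = build_model(mc, seed=train_cfg.seed)
        tr, va = prepare_training_data(merged, train_cfg)
        model, hist = fit(model, tr, va, train_cfg)
        if histories is not None:
            histories.append(hist)
        results.append(_evaluate(model, subjects[held]))
    return results
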