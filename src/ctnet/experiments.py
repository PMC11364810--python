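"""Experiment orchestration: ablations and hyperparameter sweeps.

The ablation grid crosses S&R augmentation {WA, NA} with the Transformer
encoder {WT, NT}; NT keeps every other setting fixed and sets the encoder
depth L to 0, so the classifier receives the convolutional tokens alone
(S + 0).  Effect sizes (Hedges' g) are reported for the five standard
pairwise comparisons.  Sweeps vary one architecture axis (second pooling
length P2, attention heads, encoder depth) with everything else fixed.

Every run writes a manifest of the fully resolved configuration and seeds,
sufficient to re-execute it bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace as _dc_replace
from pathlib import Path

from .metrics import EffectSizeResult, SubjectResult, aggregate, hedges_g
from .model import ModelConfig, token_length
from .preprocess import AugmentConfig
from .synthetic import SynthConfig
from .training import TrainConfig, run_subject_specific
from .trialset import TrialSet

ABLATION_CONDITIONS = ("WA+WT", "WA+NT", "NA+WT", "NA+NT")
# the five standard comparisons: (name, group1, group2)
ABLATION_COMPARISONS = (
    ("WA+WT vs WA+NT", "WA+WT", "WA+NT"),
    ("NA+WT vs NA+NT", "NA+WT", "NA+NT"),
    ("WT+WA vs WT+NA", "WA+WT", "NA+WT"),
    ("NT+WA vs NT+NA", "WA+NT", "NA+NT"),
    ("WA+WT vs NA+NT", "WA+WT", "NA+NT"),
)


@dataclass
class ExperimentConfig:
    """Resolved description of one campaign (ablation or sweep)."""

    synth: SynthConfig | None = None          # synthetic data source...
    container_pairs: list[tuple] | None = None  # ...or pre-built trial sets
    protocol: str = "subject_specific"
    model: ModelConfig = field(default_factory=ModelConfig.iv2b)
    train: TrainConfig = field(default_factory=TrainConfig)
    n_subjects: int = 2
    sweep_axis: str = "P2"                    # P2 | heads | depth
    sweep_values: list[int] = field(default_factory=lambda: [1, 6, 8, 10])
    seed: int = 0

    def validate(self) -> None:
        if (self.synth is None) == (self.container_pairs is None):
            raise ValueError("exactly one dataset source must be given")
        if self.sweep_axis not in ("P2", "heads", "depth"):
            raise ValueError(f"unknown sweep axis {self.sweep_axis!r}")


def _subject_pairs(cfg: ExperimentConfig) -> list[tuple[TrialSet, TrialSet]]:
    if cfg.container_pairs is not None:
        return list(cfg.container_pairs)
    from .synthetic import generate_mi_trials
    pairs = []
    for s in range(cfg.n_subjects):
        base = cfg.seed + 7919 * (s + 1)
        tr = generate_mi_trials(_dc_replace(cfg.synth, seed=base))
        te = generate_mi_trials(_dc_replace(cfg.synth, seed=base + 1))
        tr.subject_id = te.subject_id = f"S{s + 1:02d}"
        te.session_tag = "test"
        pairs.append((tr, te))
    return pairs


@dataclass
class AblationReport:
    per_condition: dict[str, list[SubjectResult]]
    effect_sizes: dict[str, EffectSizeResult]


def run_ablation(cfg: ExperimentConfig) -> AblationReport:
    """Run the four {WA,NA} x {WT,NT} conditions and the five effect sizes."""
    cfg.validate()
    pairs = _subject_pairs(cfg)
    per_condition: dict[str, list[SubjectResult]] = {}
    for cond in ABLATION_CONDITIONS:
        with_aug = cond.startswith("WA")
        with_tf = cond.endswith("WT")
        mc = cfg.model if with_tf else _dc_replace(cfg.model, L=0)
        tc = cfg.train if with_aug else _dc_replace(cfg.train, augment=None)
        per_condition[cond] = run_subject_specific(pairs, mc, tc)
    effect_sizes = {}
    for name, g1, g2 in ABLATION_COMPARISONS:
        a1 = [r.accuracy * 100 for r in per_condition[g1]]
        a2 = [r.accuracy * 100 for r in per_condition[g2]]
        try:
            effect_sizes[name] = hedges_g(a1, a2)
        except ValueError:            # identical groups: g = 0 by convention
            effect_sizes[name] = EffectSizeResult(
                g=0.0, d=0.0, mean1=float(sum(a1) / len(a1)),
                mean2=float(sum(a2) / len(a2)), std1=0.0, std2=0.0,
                n1=len(a1), n2=len(a2))
    return AblationReport(per_condition=per_condition,
                          effect_sizes=effect_sizes)


def run_sweep(cfg: ExperimentConfig) -> list[dict]:
    """Train/evaluate once per sweep value; returns one summary row each."""
    cfg.validate()
    pairs = _subject_pairs(cfg)
    rows = []
    for value in cfg.sweep_values:
        if cfg.sweep_axis == "P2":
            mc = _dc_replace(cfg.model, P2=value)
        elif cfg.sweep_axis == "heads":
            mc = _dc_replace(cfg.model, h=value)
        else:
            mc = _dc_replace(cfg.model, L=value)
        mc.validate()                      # raises ConfigError on bad values
        results = run_subject_specific(pairs, mc, cfg.train)
        agg = aggregate(results) if len(results) > 1 else None
        row = {
            "axis": cfg.sweep_axis,
            "value": value,
            "token_size": token_length(mc.T, mc.P1, mc.P2),
            "mean_accuracy_pct": (agg.mean_pct if agg
                                  else results[0].accuracy * 100),
            "std_accuracy_pct": agg.std_pct if agg else 0.0,
            "mean_kappa": (agg.mean_kappa if agg else results[0].kappa),
        }
        rows.append(row)
    return rows


def write_manifest(cfg: ExperimentConfig, out_dir, extra: dict | None = None):
    """Persist the resolved configuration + seeds for exact re-execution."""
    from . import __version__

    def enc(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(type(o).__name__)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_dict = dataclasses.asdict(_dc_replace(cfg, container_pairs=None))
    if cfg.container_pairs is not None:
        cfg_dict["container_pairs"] = [
            {"subject_id": tr.subject_id, "n_train": tr.n_trials,
             "n_test": te.n_trials} for tr, te in cfg.container_pairs]
    manifest = {"package_version": __version__,
                "config": cfg_dict, **(extra or {})}
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=enc))
    return path
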