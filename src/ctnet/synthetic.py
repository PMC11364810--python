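"""Class-conditional synthetic motor-imagery EEG.

The generator emulates the signature that makes motor imagery decodable:
band-limited sensorimotor-rhythm power (mu 8-13 Hz by default, beta 13-30 Hz
as an alternative) that differs between classes on designated channels, on
top of per-channel 1/f background noise.  Every channel mapped by *any*
class carries a baseline oscillation in the band; trials of class ``c``
carry ``(1 + effect)`` times that baseline band power on the channels mapped
to ``c``.  With ``effect = 0`` the classes are therefore exchangeable in
distribution.

The oscillation is narrow-band *filtered Gaussian noise*, not a sinusoid, so
the fixture is not trivially linearly separable and exercises the temporal
convolution filters realistically.  No physiological forward modeling is
attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trialset import TrialSet


@dataclass
class SynthConfig:
    n_per_class: int = 50
    C: int = 3                    # channels; default mirrors BCI IV-2b geometry
    T: int = 1000                 # samples per trial
    fs: float = 250.0
    n_classes: int = 2
    class_channel_map: dict[int, list[int]] | None = None  # class -> channels
    band: tuple[float, float] = (8.0, 13.0)   # mu rhythm by default
    effect: float = 1.0           # fractional band-power modulation depth
    noise_exponent: float = 1.0   # spectral slope of 1/f^a background
    seed: int = 0

    def resolved_map(self) -> dict[int, list[int]]:
        if self.class_channel_map is not None:
            return {int(k): list(v) for k, v in self.class_channel_map.items()}
        # default: spread classes over channels round-robin (C3 vs C4 style)
        return {c: [c % self.C] for c in range(self.n_classes)}

    def validate(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")
        if not 0 < self.band[0] < self.band[1] <= self.fs / 2:
            raise ValueError(f"band {self.band} invalid for fs={self.fs}")
        for c, chans in self.resolved_map().items():
            if not 0 <= c < self.n_classes:
                raise ValueError(f"mapped class {c} out of range")
            for ch in chans:
                if not 0 <= ch < self.C:
                    raise ValueError(
                        f"mapped channel {ch} out of range for C={self.C}")


def _one_over_f_noise(rng: np.random.Generator, n_ch: int, t: int,
                      exponent: float) -> np.ndarray:
    """Per-channel independent noise with power spectrum 1/f^exponent,
    scaled to unit variance."""
    white = rng.standard_normal((n_ch, t))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(t)
    scale = np.ones_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=t, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


def _narrowband_noise(rng: np.random.Generator, n_ch: int, t: int, fs: float,
                      band: tuple[float, float]) -> np.ndarray:
    """Gaussian noise band-limited to ``band`` (hard FFT mask), unit variance."""
    white = rng.standard_normal((n_ch, t))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(t, d=1.0 / fs)
    mask = (f >= band[0]) & (f <= band[1])
    x = np.fft.irfft(spec * mask, n=t, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


def generate_mi_trials(cfg: SynthConfig) -> TrialSet:
    """Generate ``n_per_class * n_classes`` labeled trials, deterministic in
    ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    cmap = cfg.resolved_map()
    rhythmic = sorted({ch for chans in cmap.values() for ch in chans})
    n = cfg.n_per_class * cfg.n_classes
    data = np.empty((n, cfg.C, cfg.T))
    labels = np.empty(n, dtype=np.int64)
    i = 0
    for c in range(cfg.n_classes):
        boost = np.ones(cfg.C)
        boost[cmap[c]] = np.sqrt(1.0 + cfg.effect)   # power scale -> amplitude
        for _ in range(cfg.n_per_class):
            bg = _one_over_f_noise(rng, cfg.C, cfg.T, cfg.noise_exponent)
            osc = np.zeros((cfg.C, cfg.T))
            osc[rhythmic] = _narrowband_noise(rng, len(rhythmic), cfg.T,
                                              cfg.fs, cfg.band)
            data[i] = bg + boost[:, None] * osc
            labels[i] = c
            i += 1
    names = [f"SYN{k}" for k in range(cfg.C)]
    return TrialSet(data=data, labels=labels, fs=cfg.fs, channel_names=names,
                    n_classes=cfg.n_classes, subject_id=f"synthetic-{cfg.seed}",
                    session_tag="train")


def generate_subjects(cfg: SynthConfig, n_subjects: int,
                      seed: int | None = None) -> list[TrialSet]:
    """Independent same-distribution synthetic subjects (for LOSO fixtures)."""
    base = cfg.seed if seed is None else seed
    out = []
    for s in range(n_subjects):
        c = SynthConfig(**{**cfg.__dict__, "seed": base + 1000 * (s + 1)})
        ts = generate_mi_trials(c)
        ts.subject_id = f"S{s + 1:02d}"
        out.append(ts)
    return out
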