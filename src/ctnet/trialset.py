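"""The labeled trial container used throughout the package.

A :class:`TrialSet` holds a stack of motor-imagery EEG trials — a numeric
array of shape ``(n_trials, C, T)`` — together with integer class labels,
the sampling rate, channel names and provenance tags.  It is the single
in-memory currency passed between the loader, the synthetic generator, the
preprocessing stage and the training protocols.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, replace

import numpy as np

CONTAINER_VERSION = 1


class TrialSetFormatError(ValueError):
    """Raised when a persisted trial-set container is malformed."""


@dataclass
class TrialSet:
    data: np.ndarray                  # (n_trials, C, T)
    labels: np.ndarray                # (n_trials,) ints in [0, n_classes)
    fs: float                         # sampling rate, Hz
    channel_names: list[str]
    n_classes: int
    subject_id: str = ""
    session_tag: str = "train"        # "train" | "test"
    prediction_only: bool = False     # True: not every class need be present

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 3:
            raise ValueError(f"data must be (trials, C, T), got {self.data.shape}")
        n, c, t = self.data.shape
        if len(self.labels) != n:
            raise ValueError(f"{n} trials but {len(self.labels)} labels")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if n and (c < 1 or t < 1):
            raise ValueError("each trial needs at least 1 channel and 1 sample")
        if len(self.channel_names) != c:
            raise ValueError(
                f"{c} channels but {len(self.channel_names)} channel names")
        if n:
            if self.labels.min() < 0 or self.labels.max() >= self.n_classes:
                raise ValueError("labels must lie in [0, n_classes)")
            if not self.prediction_only:
                present = set(np.unique(self.labels).tolist())
                missing = set(range(self.n_classes)) - present
                if missing:
                    raise ValueError(
                        f"classes {sorted(missing)} absent; set prediction_only"
                        " to allow incomplete class coverage")

    # -- conveniences ------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def subset(self, idx) -> "TrialSet":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        idx = idx.astype(np.int64, copy=False)
        return replace(self, data=self.data[idx], labels=self.labels[idx],
                       prediction_only=True)

    def class_indices(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.labels == c)


@dataclass
class WindowSpec:
    """Half-open trial window [start_sec, end_sec) relative to the trial
    start marker, 0-based in samples."""

    start_sec: float
    end_sec: float

    def __post_init__(self):
        if self.end_sec <= self.start_sec:
            raise ValueError("end_sec must exceed start_sec")

    def n_samples(self, fs: float) -> int:
        n = (self.end_sec - self.start_sec) * fs
        if abs(n - round(n)) > 1e-9 or n <= 0:
            raise ValueError(
                f"window of {self.end_sec - self.start_sec} s at {fs} Hz does"
                " not give a positive integer sample count")
        return int(round(n))


# ---------------------------------------------------------------------------
# single-file container: a zip holding header.json + data.npy + labels.npy
# ---------------------------------------------------------------------------

def save_trialset(ts: TrialSet, path) -> None:
    """Persist a trial set as a single-file archive (zip of npy + JSON header)."""
    header = {
        "version": CONTAINER_VERSION,
        "fs": float(ts.fs),
        "channel_names": list(ts.channel_names),
        "n_classes": int(ts.n_classes),
        "subject_id": ts.subject_id,
        "session_tag": ts.session_tag,
        "prediction_only": bool(ts.prediction_only),
    }
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("header.json", json.dumps(header, indent=1))
        for name, arr in (("data.npy", ts.data), ("labels.npy", ts.labels)):
            buf = io.BytesIO()
            np.save(buf, arr)
            zf.writestr(name, buf.getvalue())


def load_trialset(path) -> TrialSet:
    """Inverse of :func:`save_trialset`; bit-identical round trip."""
    try:
        with zipfile.ZipFile(path) as zf:
            names = set(zf.namelist())
            for required in ("header.json", "data.npy", "labels.npy"):
                if required not in names:
                    raise TrialSetFormatError(
                        f"container missing member '{required}'")
            header = json.loads(zf.read("header.json"))
            data = np.load(io.BytesIO(zf.read("data.npy")))
            labels = np.load(io.BytesIO(zf.read("labels.npy")))
    except zipfile.BadZipFile as exc:
        raise TrialSetFormatError(f"not a trial-set container: {exc}") from exc
    except json.JSONDecodeError as exc:
        raise TrialSetFormatError(f"corrupt field 'header.json': {exc}") from exc
    if header.get("version") != CONTAINER_VERSION:
        raise TrialSetFormatError(
            f"corrupt field 'version': {header.get('version')!r}")
    try:
        return TrialSet(
            data=data, labels=labels, fs=header["fs"],
            channel_names=header["channel_names"],
            n_classes=header["n_classes"], subject_id=header["subject_id"],
            session_tag=header["session_tag"],
            prediction_only=header["prediction_only"])
    except KeyError as exc:
        raise TrialSetFormatError(f"corrupt field {exc}") from exc
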