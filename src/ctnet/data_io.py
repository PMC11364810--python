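"""Readers for the BCI Competition IV-2a / IV-2b GDF recordings.

Trials are cut as half-open windows ``[start, end)`` in samples, 0-based,
relative to each trial-start marker (GDF event 768/0x300); the motor-imagery
class is taken from the cue annotation inside the trial.  Only EEG channels
are returned — EOG channels are dropped, and no filtering or artifact removal
is applied (standardization happens downstream).  Trials flagged by the
recording's rejection marker (event 1023) are excluded by default.

GDF parsing itself is delegated to :mod:`mne` (an optional dependency);
everything on top — window arithmetic, label mapping, trial assembly — is
pure and unit-tested without real recordings.
"""

from __future__ import annotations

import os

import numpy as np

from .trialset import TrialSet, WindowSpec

# contiguous 0-based class maps, per benchmark convention
IV2A_CLASSES = {"769": 0, "770": 1, "771": 2, "772": 3}   # left/right/feet/tongue
IV2B_CLASSES = {"769": 0, "770": 1}                        # left/right
TRIAL_START = "768"
REJECT = "1023"

DATASET_CONTRACT = {
    "iv2a": {"classes": IV2A_CLASSES, "n_eeg": 22, "n_classes": 4},
    "iv2b": {"classes": IV2B_CLASSES, "n_eeg": 3, "n_classes": 2},
}


class GdfFormatError(ValueError):
    """Raised when a GDF file lacks the expected motor-imagery annotations."""


def assemble_trials(signal: np.ndarray, fs: float, events: list[tuple[int, str]],
                    window: WindowSpec, class_map: dict[str, int],
                    keep_rejected: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Cut cue-labeled trial windows out of a continuous multichannel record.

    Parameters
    ----------
    signal
        ``(C, n_total_samples)`` continuous recording.
    events
        ``(onset_sample, code)`` pairs, onset ascending.  Trial starts carry
        code ``'768'``; the class cue (and any rejection marker) follow within
        the trial.
    window
        Seconds relative to the trial-start marker, half-open in samples.

    Returns ``(data, labels)`` with ``data`` shaped (n_trials, C, n_win).
    """
    n_win = window.n_samples(fs)
    start_off = int(round(window.start_sec * fs))
    starts = [i for i, (_, code) in enumerate(events) if code == TRIAL_START]
    if not starts:
        # some recordings annotate only the cues; fall back to cue onsets
        starts = [i for i, (_, code) in enumerate(events) if code in class_map]
        cue_is_start = True
        if not starts:
            raise GdfFormatError("no motor-imagery cue events found")
    else:
        cue_is_start = False
    data, labels = [], []
    for pos, ev_ix in enumerate(starts):
        onset, _ = events[ev_ix]
        next_onset = (events[starts[pos + 1]][0]
                      if pos + 1 < len(starts) else np.inf)
        label, rejected = None, False
        if cue_is_start:
            label = class_map[events[ev_ix][1]]
            scan = events[ev_ix + 1:]
        else:
            scan = events[ev_ix + 1:]
        for t, code in scan:
            if t >= next_onset:
                break
            if code == REJECT:
                rejected = True
            elif label is None and code in class_map:
                label = class_map[code]
        if not cue_is_start and label is None:
            continue                       # trial without a cue (e.g. eye runs)
        if rejected and not keep_rejected:
            continue
        lo = onset + start_off
        hi = lo + n_win
        if lo < 0 or hi > signal.shape[1]:
            raise IndexError(
                f"window [{lo}, {hi}) extends past the recording"
                f" of {signal.shape[1]} samples")
        data.append(signal[:, lo:hi])
        labels.append(label)
    if not labels:
        raise GdfFormatError("no motor-imagery cue events found")
    return np.stack(data), np.asarray(labels, dtype=np.int64)


def load_gdf_trials(path, dataset_id: str, window: WindowSpec,
                    keep_rejected: bool = False,
                    subject_id: str = "", session_tag: str = "train") -> TrialSet:
    """Load one BCI IV-2a/2b session file into a :class:`TrialSet`."""
    if dataset_id not in DATASET_CONTRACT:
        raise ValueError(f"unknown dataset_id {dataset_id!r}; use 'iv2a'/'iv2b'")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    import mne  # deferred: heavy optional dependency

    contract = DATASET_CONTRACT[dataset_id]
    raw = mne.io.read_raw_gdf(path, preload=True, verbose="error")
    eeg_names = [ch for ch in raw.ch_names if "EOG" not in ch.upper()]
    if len(eeg_names) != contract["n_eeg"]:
        raise GdfFormatError(
            f"expected {contract['n_eeg']} EEG channels, found {len(eeg_names)}")
    raw.pick(eeg_names)
    fs = float(raw.info["sfreq"])
    signal = raw.get_data() * 1e6          # volts -> microvolts
    events = [(int(round(onset * fs)), desc)
              for onset, desc in zip(raw.annotations.onset,
                                     raw.annotations.description)]
    events.sort(key=lambda e: e[0])
    data, labels = assemble_trials(signal, fs, events, window,
                                   contract["classes"], keep_rejected)
    return TrialSet(data=data, labels=labels, fs=fs, channel_names=eeg_names,
                    n_classes=contract["n_classes"], subject_id=subject_id,
                    session_tag=session_tag, prediction_only=True)
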