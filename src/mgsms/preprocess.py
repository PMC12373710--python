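"""EEG preprocessing: band-pass filter, common average reference, z-scoring,
and epoching around stimulus onset.

The pipeline order is fixed and canonical: filter -> average reference ->
z-score -> epoch.  Filtering and referencing operate on the whole session;
z-scoring is per channel over the full session so that global field power
remains comparable across trials.  Epochs span 500 ms before stimulus onset
to 1.5 s after stimulus offset (2.3 s total) and are tiled by three half-open
analysis intervals: fixation [t0-0.5, t0), visual [t0, t0+0.3), memory
[t0+0.3, t0+1.8), with t0 the stimulus onset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

logger = logging.getLogger(__name__)

#: Epoch geometry in seconds, relative to stimulus onset.
EPOCH_PRE = 0.5
EPOCH_POST = 1.8  # stim_dur + analysed memory window
EPOCH_LEN = EPOCH_PRE + EPOCH_POST  # 2.3 s
INTERVALS = ("fixation", "visual", "memory")


@dataclass(frozen=True)
class EEGRecording:
    """A channels-by-samples recording with its montage and reference state."""

    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    reference: str = "raw"

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 2:
            raise ValueError("data must be (channels, samples)")
        if data.shape[0] != len(self.channel_names):
            raise ValueError("channel count does not match channel_names")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class Epoch:
    """One trial's analysis window, with interval bounds in samples."""

    data: np.ndarray
    fs: float
    subject: int
    trial: int
    t0: float = EPOCH_PRE  # stimulus onset within the epoch, seconds

    @property
    def interval_bounds(self) -> dict[str, tuple[int, int]]:
        """Half-open sample ranges that tile the epoch exactly."""
        b0 = int(round(EPOCH_PRE * self.fs))
        b1 = int(round((EPOCH_PRE + 0.3) * self.fs))
        b2 = int(round(EPOCH_LEN * self.fs))
        return {"fixation": (0, b0), "visual": (b0, b1), "memory": (b1, b2)}

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def epoch_n_samples(fs: float) -> int:
    return int(round(EPOCH_LEN * fs))


def bandpass(
    rec: EEGRecording, lo: float = 1.0, hi: float = 30.0, order: int = 6
) -> EEGRecording:
    """Zero-phase Butterworth band-pass, applied per channel.

    ``order`` is the final filter order (a band-pass of order 6 corresponds
    to a 3rd-order low/high-pass prototype); forward-backward application
    makes the phase response zero and squares the magnitude response.
    """
    if not 0 < lo < hi:
        raise ValueError("need 0 < lo < hi")
    if hi >= rec.fs / 2:
        raise ValueError(f"hi={hi} Hz requires fs > {2 * hi} Hz, got {rec.fs}")
    if order < 2 or order % 2:
        raise ValueError("band-pass order must be an even integer >= 2")
    sos = sps.butter(order // 2, [lo, hi], btype="bandpass", output="sos", fs=rec.fs)
    out = sps.sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=out)


def rereference_average(rec: EEGRecording) -> EEGRecording:
    """Common average reference: subtract the cross-channel mean per sample."""
    if rec.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    out = rec.data - rec.data.mean(axis=0, keepdims=True)
    return replace(rec, data=out, reference="common_average")


def zscore(rec: EEGRecording) -> EEGRecording:
    """Per-channel session-wide standardisation (population SD)."""
    mean = rec.data.mean(axis=1, keepdims=True)
    sd = rec.data.std(axis=1, ddof=0, keepdims=True)
    zero = np.flatnonzero(sd.ravel() == 0.0)
    if zero.size:
        raise ValueError(
            f"zero-variance channel(s): {[rec.channel_names[i] for i in zero]}"
        )
    return replace(rec, data=(rec.data - mean) / sd)


def preprocess(
    rec: EEGRecording, lo: float = 1.0, hi: float = 30.0, order: int = 6
) -> EEGRecording:
    """The canonical chain: band-pass, common average reference, z-score."""
    return zscore(rereference_average(bandpass(rec, lo, hi, order)))


def epoch_trials(
    rec: EEGRecording,
    events: pd.DataFrame,
    valid: np.ndarray | pd.Series | None = None,
) -> list[Epoch]:
    """Cut one epoch per valid trial: [stim_on - 0.5 s, stim_off + 1.5 s).

    Stimulus onset maps to the first sample at or after the event time
    (0-based, half-open windows).  Trials whose window falls outside the
    recording are skipped with a warning; invalid trials are not epoched.
    """
    n_epoch = epoch_n_samples(rec.fs)
    pre = int(round(EPOCH_PRE * rec.fs))
    epochs: list[Epoch] = []
    for idx, ev in events.reset_index(drop=True).iterrows():
        if valid is not None and not bool(np.asarray(valid)[idx]):
            continue
        onset = int(np.ceil(float(ev["t_stim_on_s"]) * rec.fs - 1e-9))
        start = onset - pre
        stop = start + n_epoch
        if start < 0 or stop > rec.n_samples:
            logger.warning(
                "trial %s window [%d, %d) outside recording; skipped",
                ev.get("trial", idx), start, stop,
            )
            continue
        epochs.append(
            Epoch(
                data=rec.data[:, start:stop],
                fs=rec.fs,
                subject=int(ev.get("subject", 0)),
                trial=int(ev.get("trial", idx)),
            )
        )
    return epochs
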