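"""On-disk formats: EEG CSV, events TSV, gaze CSV, prototypes, ground truth.

The canonical EEG format is a plain CSV with one row per sample and one
column per channel, header row holding the montage channel names in order.
EDF recordings can be read when mne is installed.  Ground truth and run
manifests are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .segmentation import LabelSequence, PrototypeSet
from .synth import GroundTruth, Session


# ---------------------------------------------------------------------------
# EEG


def write_eeg_csv(path, data: np.ndarray, channel_names, fs: float) -> None:
    """Samples-by-channels CSV; the sampling rate rides in a header comment."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs_hz={fs}\n")
        pd.DataFrame(np.asarray(data).T, columns=list(channel_names)).to_csv(
            fh, index=False, float_format="%.6g"
        )


def read_eeg_csv(path) -> tuple[np.ndarray, tuple[str, ...], float]:
    path = Path(path)
    fs = None
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("# fs_hz="):
            fs = float(first.strip().split("=", 1)[1])
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    if fs is None:
        raise ValueError(f"{path} has no '# fs_hz=' header line")
    return df.to_numpy().T, tuple(df.columns), fs


def read_eeg_edf(path) -> tuple[np.ndarray, tuple[str, ...], float]:
    """Read an EDF recording via mne (optional dependency)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return raw.get_data(), tuple(raw.ch_names), float(raw.info["sfreq"])


def read_eeg(path) -> tuple[np.ndarray, tuple[str, ...], float]:
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_eeg_edf(path)
    return read_eeg_csv(path)


# ---------------------------------------------------------------------------
# events / gaze / tidy tables


def write_events_tsv(path, events: pd.DataFrame) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gaze_csv(path, gaze: pd.DataFrame) -> None:
    gaze.to_csv(path, index=False, float_format="%.3f")


def read_gaze_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# prototypes


def write_prototypes(csv_path, json_path, protos: PrototypeSet, meta: dict | None = None) -> None:
    """Prototypes as channels-by-states CSV plus JSON metadata."""
    df = pd.DataFrame(
        protos.maps.T, columns=list(protos.labels), index=list(protos.channel_names)
    )
    df.index.name = "channel"
    df.to_csv(csv_path)
    payload = {
        "labels": list(protos.labels),
        "pairing": {k: list(v) for k, v in (protos.pairing or {}).items()},
        "channel_names": list(protos.channel_names),
    }
    payload.update(meta or {})
    Path(json_path).write_text(json.dumps(payload, indent=2))


def read_prototypes(csv_path, json_path) -> PrototypeSet:
    df = pd.read_csv(csv_path, index_col="channel")
    meta = json.loads(Path(json_path).read_text())
    return PrototypeSet(
        maps=df.to_numpy().T,
        channel_names=tuple(meta["channel_names"]),
        labels=tuple(meta["labels"]),
        pairing={k: tuple(v) for k, v in meta["pairing"].items()} or None,
    )


# ---------------------------------------------------------------------------
# label sequences


def write_labels_tsv(path, seq: LabelSequence) -> None:
    df = pd.DataFrame(
        {
            "sample": np.arange(seq.n_samples),
            "time_s": np.arange(seq.n_samples) / seq.fs,
            "state": [seq.states[i] for i in seq.labels],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_labels_tsv(path, fs: float, mode: str, states) -> LabelSequence:
    df = pd.read_csv(path, sep="\t")
    index = {s: i for i, s in enumerate(states)}
    labels = np.array([index[s] for s in df["state"]], dtype=np.int64)
    return LabelSequence(labels=labels, fs=fs, mode=mode, states=tuple(states))


# ---------------------------------------------------------------------------
# ground truth


def ground_truth_to_json(truth: GroundTruth, session: Session | None = None) -> dict:
    payload = {
        "chain": truth.chain.tolist(),
        "dwell_mean": truth.dwell_mean,
        "snr": truth.snr,
        "coupling_beta": truth.coupling_beta,
        "error_sigma": list(truth.error_sigma),
        "blink_prob": truth.blink_prob,
        "far_tp_boost": truth.far_tp_boost,
        "prototypes": {
            "labels": list(truth.prototypes.labels),
            "channel_names": list(truth.prototypes.channel_names),
            "maps": truth.prototypes.maps.tolist(),
        },
    }
    if session is not None:
        planted = {}
        for sub in session.subjects:
            planted[str(sub.subject)] = [
                [[int(v), int(ln)] for v, _, ln in seq.segments]
                for seq in sub.planted_labels
            ]
        payload["planted_segments"] = planted
    return payload


def write_ground_truth(path, truth: GroundTruth, session: Session | None = None) -> None:
    Path(path).write_text(json.dumps(ground_truth_to_json(truth, session)))


def write_session(outdir, session: Session) -> None:
    """Write a full synthetic study: per-subject EEG/events/gaze + truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = []
    for sub in session.subjects:
        d = outdir / f"sub-{sub.subject:02d}"
        d.mkdir(exist_ok=True)
        write_eeg_csv(
            d / "eeg.csv",
            sub.eeg,
            session.truth.prototypes.channel_names,
            session.cfg.fs_eeg,
        )
        write_gaze_csv(d / "gaze.csv", sub.gaze)
        frames.append(sub.events)
    write_events_tsv(outdir / "events.tsv", pd.concat(frames, ignore_index=True))
    write_ground_truth(outdir / "ground_truth.json", session.truth, session)
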