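"""EEG segment container, fixture/EDF I/O, and deterministic preprocessing.

Preprocessing follows the fixed order resample -> average reference ->
high-pass, matching standard practice for montage-referenced resting EEG:
recordings sampled at 256 Hz are brought to 128 Hz, re-referenced to the
common average of the loaded channel set, and high-pass filtered at 0.1 Hz
with a zero-phase 4th-order Butterworth to remove drift without phase
distortion inside 20 s epochs.

The plain-text fixture format is a delimited matrix (samples x channels,
header row of 10-20 labels) plus a JSON sidecar carrying ``fs``,
``subject_id`` and ``condition`` — diffable and language neutral.  EDF files
are read through :mod:`mne` and scaled to microvolts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

CONDITIONS = ("EO", "2D", "3D")

__all__ = ["EEGSegment", "CONDITIONS", "load_segment", "save_segment", "preprocess", "extract_epoch"]


@dataclass(frozen=True)
class EEGSegment:
    """One labelled multichannel EEG epoch.

    data
        channels x samples array (microvolts or arbitrary units).
    fs
        Sampling rate in Hz.
    channel_labels
        Ordered 10-20 site names, one per data row.
    reference
        ``"as-recorded"`` or ``"average"`` (after common-average re-referencing).
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    subject_id: str = ""
    condition: str = ""
    reference: str = "as-recorded"

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))
        if data.ndim != 2:
            raise ValueError(f"data must be 2-D (channels x samples), got shape {data.shape}")
        if data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{data.shape[0]} data rows but {len(self.channel_labels)} channel labels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("duplicate channel labels")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        bad = np.argwhere(~np.isfinite(data))
        if bad.size:
            ch, idx = bad[0]
            raise ValueError(
                f"non-finite sample in channel {self.channel_labels[ch]!r} at index {idx}"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def save_segment(seg: EEGSegment, path: str | Path) -> Path:
    """Write a segment as ``<path>.csv`` + ``<path>.json`` sidecar.

    Returns the CSV path.  The matrix is samples x channels with a header
    row of labels; the sidecar holds fs, subject_id, condition, reference.
    """
    path = Path(path)
    csv_path = path.with_suffix(".csv")
    pd.DataFrame(seg.data.T, columns=list(seg.channel_labels)).to_csv(
        csv_path, index=False, float_format="%.10g"
    )
    sidecar = {
        "fs": seg.fs,
        "subject_id": seg.subject_id,
        "condition": seg.condition,
        "reference": seg.reference,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return csv_path


def _load_fixture(path: Path) -> EEGSegment:
    csv_path = path.with_suffix(".csv")
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("fs", "subject_id", "condition"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar_path} missing field {key!r}")
    frame = pd.read_csv(csv_path)
    return EEGSegment(
        data=frame.to_numpy().T,
        fs=float(meta["fs"]),
        channel_labels=tuple(frame.columns),
        subject_id=str(meta["subject_id"]),
        condition=str(meta["condition"]),
        reference=str(meta.get("reference", "as-recorded")),
    )


def _load_edf(path: Path) -> EEGSegment:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return EEGSegment(
        data=raw.get_data() * 1e6,  # mne loads volts; analyses use microvolts
        fs=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
        subject_id=path.stem,
    )


def load_segment(path: str | Path, format: str = "fixture") -> EEGSegment:
    """Load one EEG segment from disk.

    ``format="fixture"`` expects the CSV+JSON pair written by
    :func:`save_segment` (pass either file or the common stem);
    ``format="edf"`` reads a European Data Format file via mne, converting
    to microvolts using the header scaling.
    """
    path = Path(path)
    if format == "fixture":
        return _load_fixture(path)
    if format == "edf":
        return _load_edf(path)
    raise ValueError(f"unknown format {format!r}")


def preprocess(seg: EEGSegment, target_fs: float = 128.0, highpass_hz: float = 0.1) -> EEGSegment:
    """Resample to ``target_fs``, common-average reference, then high-pass.

    Resampling uses a polyphase rational resampler; the high-pass is a
    zero-phase (forward-backward) 4th-order Butterworth, so the effective
    magnitude response is 8th order with no group delay.  Upsampling is
    refused, and average referencing requires at least 2 channels.
    """
    if target_fs > seg.fs:
        raise ValueError(f"refusing to upsample from {seg.fs} Hz to {target_fs} Hz")
    if seg.data.shape[0] < 2:
        raise ValueError("average referencing needs at least 2 channels")
    data = seg.data
    if target_fs != seg.fs:
        from fractions import Fraction

        frac = Fraction(target_fs / seg.fs).limit_denominator(1000)
        data = signal.resample_poly(data, frac.numerator, frac.denominator, axis=1)
    data = data - data.mean(axis=0, keepdims=True)
    if highpass_hz > 0:
        sos = signal.butter(4, highpass_hz, btype="highpass", fs=target_fs, output="sos")
        data = signal.sosfiltfilt(sos, data, axis=1)
    return replace(seg, data=data, fs=float(target_fs), reference="average")


def extract_epoch(seg: EEGSegment, start_s: float, dur_s: float = 20.0) -> EEGSegment:
    """Cut a ``dur_s``-second epoch starting at ``start_s`` seconds.

    Returns exactly ``round(dur_s * fs)`` samples per channel with metadata
    inherited; refuses windows that fall outside the recording.
    """
    if dur_s <= 0:
        raise ValueError(f"duration must be positive, got {dur_s}")
    if start_s < 0:
        raise ValueError(f"start must be >= 0, got {start_s}")
    i0 = int(round(start_s * seg.fs))
    n = int(round(dur_s * seg.fs))
    if i0 + n > seg.n_samples:
        raise ValueError(
            f"window [{start_s}, {start_s + dur_s}] s exceeds recording of "
            f"{seg.duration_s:.3f} s"
        )
    return replace(seg, data=seg.data[:, i0 : i0 + n])
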