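"""Shared fixtures: a session-wide synthetic study and a minimal EDF writer."""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pytest

from vreeg import (
    SyntheticStudyConfig,
    build_fd_table,
    build_power_table,
    gen_study,
    preprocess,
)

STUDY_SEED = 1


@pytest.fixture(scope="session")
def study_segments():
    """Default 15-subject, three-condition study, preprocessed (seed 1)."""
    cfg = SyntheticStudyConfig(seed=STUDY_SEED)
    return [preprocess(s) for s in gen_study(cfg)]


@pytest.fixture(scope="session")
def power_table(study_segments):
    return build_power_table(study_segments)


@pytest.fixture(scope="session")
def fd_table(study_segments):
    return build_fd_table(study_segments)


def write_minimal_edf(
    path: Path,
    data: np.ndarray,
    fs: float,
    labels: list[str],
    physical_range: tuple[float, float] = (-1000.0, 1000.0),
) -> Path:
    """Write a one-record EDF file (synthetic test fixture, int16 samples).

    Covers just enough of the format for reader round-trips: one data
    record of ``n_samples`` per channel, physical units microvolts.
    """
    n_ch, n_samples = data.shape
    record_dur = n_samples / fs
    pmin, pmax = physical_range
    dmin, dmax = -32768, 32767

    def pad(text: str, width: int) -> bytes:
        return text.encode("ascii")[:width].ljust(width)

    header = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),  # patient id
            pad("Startdate X X X X", 80),  # recording id
            pad("01.01.20", 8),
            pad("00.00.00", 8),
            pad(str(256 + 256 * n_ch), 8),
            pad("", 44),
            pad("1", 8),  # number of records
            pad(f"{record_dur:g}", 8),
            pad(str(n_ch), 4),
        ]
    )
    fields = [
        [pad(lbl, 16) for lbl in labels],
        [pad("AgAgCl electrode", 80)] * n_ch,
        [pad("uV", 8)] * n_ch,
        [pad(f"{pmin:g}", 8)] * n_ch,
        [pad(f"{pmax:g}", 8)] * n_ch,
        [pad(str(dmin), 8)] * n_ch,
        [pad(str(dmax), 8)] * n_ch,
        [pad("", 80)] * n_ch,
        [pad(str(n_samples), 8)] * n_ch,
        [pad("", 32)] * n_ch,
    ]
    header += b"".join(b"".join(f) for f in fields)
    digital = np.clip(
        np.round((data - pmin) / (pmax - pmin) * (dmax - dmin) + dmin), dmin, dmax
    ).astype("<i2")
    path.write_bytes(header + digital.tobytes())
    return path
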