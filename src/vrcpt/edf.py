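"""Minimal European Data Format (EDF) writer and an MNE-backed reader.

Only the subset of EDF needed for continuous multi-channel EEG is written:
uniform sampling rate, 1-second data records, 16-bit samples with a
symmetric physical range in microvolts.  Reading goes through
:func:`mne.io.read_raw_edf`, so anything written here round-trips through a
standard reader (to within the 16-bit quantization step of the chosen
physical range).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field too long: {text!r} (> {width})")
    return b.ljust(width)


def write_edf(path: Path | str, data_uv: np.ndarray, sfreq: float,
              ch_names: tuple[str, ...] | list[str],
              phys_max_uv: float | None = None) -> None:
    """Write ``data_uv`` (n_channels x n_samples, microvolts) as EDF.

    ``sfreq`` must be a whole number of samples per second; the signal is
    zero-padded to a whole number of 1-second records.  The header carries a
    fixed start date so identical data produce byte-identical files.
    """
    data = np.asarray(data_uv, dtype=np.float64)
    if data.ndim != 2 or data.shape[0] != len(ch_names):
        raise ValueError("data must be (n_channels, n_samples) matching ch_names")
    if abs(sfreq - round(sfreq)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(sfreq))              # samples per 1 s record
    n_ch, n_samp = data.shape
    n_rec = int(np.ceil(n_samp / spr))
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_samp] = data

    if phys_max_uv is None:
        phys_max_uv = float(np.ceil(max(np.abs(padded).max(), 1.0)))
    dig_max = 32767
    scale = dig_max / phys_max_uv
    digital = np.clip(np.round(padded * scale), -dig_max, dig_max).astype("<i2")

    header = b"".join([
        _field("0", 8),
        _field("X X X X", 80),                      # patient id
        _field("Startdate 01-JAN-2000 X X X", 80),  # recording id
        _field("01.01.00", 8),
        _field("00.00.00", 8),
        _field(str(256 * (1 + n_ch)), 8),
        _field("", 44),
        _field(str(n_rec), 8),
        _field("1", 8),                             # record duration, s
        _field(str(n_ch), 4),
    ])
    sig = b"".join([
        b"".join(_field(name, 16) for name in ch_names),
        b"".join(_field("AgAgCl electrode", 80) for _ in ch_names),
        b"".join(_field("uV", 8) for _ in ch_names),
        b"".join(_field(f"{-phys_max_uv:g}", 8) for _ in ch_names),
        b"".join(_field(f"{phys_max_uv:g}", 8) for _ in ch_names),
        b"".join(_field(str(-dig_max), 8) for _ in ch_names),
        b"".join(_field(str(dig_max), 8) for _ in ch_names),
        b"".join(_field("BP 0.01-100 Hz", 80) for _ in ch_names),
        b"".join(_field(str(spr), 8) for _ in ch_names),
        b"".join(_field("", 32) for _ in ch_names),
    ])
    # data records: per record, all samples of signal 1, then signal 2, ...
    records = digital.reshape(n_ch, n_rec, spr).transpose(1, 0, 2)
    Path(path).write_bytes(header + sig + records.tobytes())


def read_edf(path: Path | str) -> tuple[np.ndarray, float, tuple[str, ...]]:
    """Read an EDF file; returns (data_uv, sfreq, ch_names)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6   # MNE loads EEG in volts
    return data_uv, float(raw.info["sfreq"]), tuple(raw.ch_names)
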