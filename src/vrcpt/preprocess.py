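"""Continuous-EEG preprocessing: band-pass filtering, epoching, baseline
correction and threshold-based artifact rejection.

The processing chain mirrors standard event-related-potential practice:

1. zero-phase band-pass 0.5-30 Hz (4th-order Butterworth, forward-backward),
2. segmentation into stimulus-locked epochs of -200..+800 ms,
3. baseline correction against the pre-stimulus interval [-200, 0) ms,
4. peak-to-peak amplitude rejection (default 150 uV) as an automated,
   reproducible stand-in for manual independent-component screening.

Epoch windows follow the half-open convention [-pre, +post): with sampling
rate ``fs`` an epoch holds ``(pre_ms + post_ms) * fs / 1000`` samples and
sample index ``pre_ms * fs / 1000`` falls exactly on the stimulus onset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

log = logging.getLogger(__name__)

REFERENCE_LABELS = ("A1", "A2")


@dataclass
class Recording:
    """Continuous multi-channel EEG in microvolts.

    ``t0_ms`` is the time of the first sample on the event clock, so an
    event at ``onset_ms`` sits at sample ``(onset_ms - t0_ms) * fs / 1000``.
    """

    data: np.ndarray              # (n_channels, n_samples), uV
    sfreq: float                  # Hz
    ch_names: tuple[str, ...]
    t0_ms: float = 0.0
    participant: int | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.ch_names):
            raise ValueError("data must be (n_channels, n_samples) matching ch_names")
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")
        if np.isnan(self.data).any():
            raise ValueError("recording contains NaNs")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel_index(self, label: str) -> int:
        return self.ch_names.index(label)


@dataclass
class EpochSet:
    """Stimulus-locked epochs: ``data`` is (n_epochs, n_channels, n_samples).

    ``rejected`` flags epochs excluded from every downstream average;
    ``reject_reason`` records why.  ``dropped`` lists events that could not
    be epoched at all (out of recording bounds), so that
    ``usable events == n_epochs + len(dropped)``.
    """

    data: np.ndarray
    times_ms: np.ndarray          # sample times relative to stimulus onset
    sfreq: float
    ch_names: tuple[str, ...]
    meta: pd.DataFrame            # per-epoch: onset_ms, kind, condition, participant
    rejected: np.ndarray = field(default=None)  # type: ignore[assignment]
    reject_reason: list[str] = field(default_factory=list)
    dropped: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rejected is None:
            self.rejected = np.zeros(len(self.data), dtype=bool)
            self.reject_reason = [""] * len(self.data)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def pre_samples(self) -> int:
        return int(np.sum(self.times_ms < 0))

    def channel_index(self, label: str) -> int:
        return self.ch_names.index(label)

    def good_mask(self, kind: str | None = None) -> np.ndarray:
        mask = ~self.rejected
        if kind is not None:
            mask = mask & (self.meta["kind"].to_numpy() == kind)
        return mask

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(), times_ms=self.times_ms.copy(), sfreq=self.sfreq,
            ch_names=self.ch_names, meta=self.meta.copy(),
            rejected=self.rejected.copy(), reject_reason=list(self.reject_reason),
            dropped=list(self.dropped),
        )


def save_epochs(ep: EpochSet, path) -> None:
    """Write an epoch container: compressed array archive plus a JSON
    sidecar (``<path>.meta.json``) holding the epoch metadata."""
    import json
    from pathlib import Path

    path = Path(path)
    np.savez_compressed(path, data=ep.data, times_ms=ep.times_ms,
                        rejected=ep.rejected)
    sidecar = {
        "sfreq": ep.sfreq,
        "ch_names": list(ep.ch_names),
        "meta": ep.meta.to_dict(orient="list"),
        "reject_reason": list(ep.reject_reason),
        "dropped": [[onset, reason] for onset, reason in ep.dropped],
    }
    path.with_suffix(".meta.json").write_text(json.dumps(sidecar) + "\n")


def load_epochs(path) -> EpochSet:
    """Read an epoch container written by :func:`save_epochs`."""
    import json
    from pathlib import Path

    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    arrays = np.load(path)
    sidecar = json.loads(path.with_suffix(".meta.json").read_text())
    return EpochSet(
        data=arrays["data"], times_ms=arrays["times_ms"],
        sfreq=float(sidecar["sfreq"]), ch_names=tuple(sidecar["ch_names"]),
        meta=pd.DataFrame(sidecar["meta"]),
        rejected=arrays["rejected"].astype(bool),
        reject_reason=list(sidecar["reject_reason"]),
        dropped=[(float(o), r) for o, r in sidecar["dropped"]],
    )


def _butter_sos(low: float, high: float, sfreq: float, order: int = 4) -> np.ndarray:
    nyq = sfreq / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist ({nyq} Hz)"
        )
    return signal.butter(order, [low, high], btype="bandpass", fs=sfreq, output="sos")


def bandpass_response_db(low: float, high: float, sfreq: float, freq: float,
                         order: int = 4) -> float:
    """Two-pass (zero-phase) power gain of the band-pass at ``freq``, in dB."""
    sos = _butter_sos(low, high, sfreq, order)
    _, h = signal.sosfreqz(sos, worN=[freq], fs=sfreq)
    # forward-backward filtering squares the magnitude response
    return float(20.0 * np.log10(np.abs(h[0]) ** 2 + 1e-300))


def bandpass(rec: Recording, low: float = 0.5, high: float = 30.0,
             order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass of a continuous recording.

    A 4th-order design applied forward and backward (``sosfiltfilt``) keeps
    the phase response flat, which protects component latencies.
    """
    sos = _butter_sos(low, high, rec.sfreq, order)
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=filtered)


def epoch(rec: Recording, events, pre_ms: float = 200.0, post_ms: float = 800.0,
          kinds: Sequence[str] | None = None) -> EpochSet:
    """Cut stimulus-locked epochs of ``[-pre_ms, +post_ms)`` around each event.

    Events whose window falls outside the recording are dropped and logged
    rather than raising.  ``kinds`` restricts which event kinds are epoched
    (default: all).
    """
    onsets = np.asarray(events.onsets, dtype=float)
    kind_arr = np.asarray(events.kinds)
    if len(onsets) == 0:
        raise ValueError("event list is empty")
    if kinds is not None:
        sel = np.isin(kind_arr, list(kinds))
        onsets, kind_arr = onsets[sel], kind_arr[sel]

    fs = rec.sfreq
    pre_samp = int(round(pre_ms * fs / 1000.0))
    post_samp = int(round(post_ms * fs / 1000.0))
    n_samp = pre_samp + post_samp
    times_ms = (np.arange(n_samp) - pre_samp) * 1000.0 / fs

    data_list, rows, dropped = [], [], []
    for onset, kind in zip(onsets, kind_arr):
        center = int(round((onset - rec.t0_ms) * fs / 1000.0))
        start, stop = center - pre_samp, center + post_samp
        if start < 0 or stop > rec.n_samples:
            dropped.append((float(onset), "window outside recording bounds"))
            continue
        data_list.append(rec.data[:, start:stop])
        rows.append({"onset_ms": float(onset), "kind": str(kind),
                     "condition": rec.condition, "participant": rec.participant})
    if dropped:
        log.info("dropped %d/%d events at recording bounds", len(dropped), len(onsets))
    data = (np.stack(data_list) if data_list
            else np.empty((0, len(rec.ch_names), n_samp)))
    meta = pd.DataFrame(rows, columns=["onset_ms", "kind", "condition", "participant"])
    return EpochSet(data=data, times_ms=times_ms, sfreq=fs,
                    ch_names=rec.ch_names, meta=meta, dropped=dropped)


def baseline_correct(ep: EpochSet) -> EpochSet:
    """Subtract each epoch's mean over the pre-stimulus interval [-pre, 0).

    Idempotent; raises if the window contains no pre-stimulus samples.
    """
    pre = ep.times_ms < 0
    if not pre.any():
        raise ValueError("epoch window has no pre-stimulus samples to baseline on")
    out = ep.copy()
    base = out.data[:, :, pre].mean(axis=2, keepdims=True)
    out.data = out.data - base
    return out


def reject_artifacts(ep: EpochSet, abs_threshold: float = 150.0,
                     channels: Sequence[str] | None = None) -> EpochSet:
    """Flag epochs whose peak-to-peak range exceeds ``abs_threshold`` uV.

    The check runs on analysis channels only (mastoid references are
    skipped).  Rejection accumulates: an already-rejected epoch stays
    rejected.  This threshold rule replaces manual component screening with
    a deterministic, reproducible criterion.
    """
    if abs_threshold <= 0:
        raise ValueError("threshold must be positive")
    if channels is None:
        channels = [c for c in ep.ch_names if c not in REFERENCE_LABELS]
    idx = [ep.channel_index(c) for c in channels]
    out = ep.copy()
    if out.n_epochs == 0:
        return out
    ptp = out.data[:, idx, :].max(axis=2) - out.data[:, idx, :].min(axis=2)
    bad = (ptp > abs_threshold).any(axis=1)
    n_new = int((bad & ~out.rejected).sum())
    for i in np.flatnonzero(bad & ~out.rejected):
        out.reject_reason[i] = f"peak-to-peak > {abs_threshold:g} uV"
    out.rejected = out.rejected | bad
    if n_new:
        log.info("rejected %d/%d epochs exceeding %.1f uV peak-to-peak",
                 n_new, out.n_epochs, abs_threshold)
    return out
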