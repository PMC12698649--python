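"""Event-related potential averaging and P300 feature extraction.

The P300 is the positive deflection peaking roughly 300 ms after a task-
relevant stimulus.  Features are measured on each participant's average
waveform (not the grand average), because the downstream contrasts are
paired across participants: for every participant x condition x electrode
the peak amplitude (uV) and its latency (ms post-stimulus) are taken as the
maximum of the average waveform within a configurable search window,
250-500 ms by default.  Ties resolve to the earliest sample, making the
detector deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import EpochSet

DEFAULT_P300_WINDOW = (250.0, 500.0)


@dataclass(frozen=True)
class ERPWaveform:
    electrode: str
    condition: str | None
    times_ms: np.ndarray
    mean_uv: np.ndarray
    n_epochs: int


@dataclass(frozen=True)
class P300Feature:
    participant: int | None
    condition: str | None
    electrode: str
    latency_ms: float
    amplitude_uv: float
    search_window: tuple[float, float]
    n_epochs: int


def average_erp(ep: EpochSet, electrode: str, kind: str = "target") -> ERPWaveform:
    """Pointwise mean over non-rejected epochs of the given kind."""
    mask = ep.good_mask(kind=kind)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"no usable {kind!r} epochs for {electrode}")
    ci = ep.channel_index(electrode)
    mean = ep.data[mask, ci, :].mean(axis=0)
    cond = ep.meta["condition"].iloc[0] if len(ep.meta) else None
    return ERPWaveform(electrode=electrode, condition=cond,
                       times_ms=ep.times_ms, mean_uv=mean, n_epochs=n)


def detect_p300(w: ERPWaveform,
                window: tuple[float, float] = DEFAULT_P300_WINDOW,
                participant: int | None = None) -> P300Feature:
    """Peak amplitude and latency of the waveform maximum inside ``window``.

    The peak is the global maximum on the closed window [low, high] ms;
    exact ties resolve to the earliest sample.
    """
    low, high = window
    if not (0.0 < low < high <= 800.0):
        raise ValueError("search window must lie within (0, 800] ms")
    sel = (w.times_ms >= low) & (w.times_ms <= high)
    if not sel.any():
        raise ValueError("search window contains no samples")
    seg = w.mean_uv[sel]
    if np.isnan(seg).all():
        raise ValueError("waveform is all-NaN in the search window")
    k = int(np.nanargmax(seg))
    times = w.times_ms[sel]
    return P300Feature(participant=participant, condition=w.condition,
                       electrode=w.electrode, latency_ms=float(times[k]),
                       amplitude_uv=float(seg[k]), search_window=(low, high),
                       n_epochs=w.n_epochs)


def p300_features(ep: EpochSet, electrodes, participant: int | None = None,
                  window: tuple[float, float] = DEFAULT_P300_WINDOW) -> pd.DataFrame:
    """Tidy P300 feature table for one participant-condition epoch set."""
    rows = []
    for el in electrodes:
        feat = detect_p300(average_erp(ep, el), window=window, participant=participant)
        rows.append({
            "participant": participant, "condition": feat.condition,
            "electrode": el, "latency_ms": feat.latency_ms,
            "amplitude_uv": feat.amplitude_uv, "n_epochs": feat.n_epochs,
        })
    return pd.DataFrame(rows)
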