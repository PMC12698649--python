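"""Sample entropy and fuzzy entropy for EEG epochs.

Both statistics quantify the irregularity of a time series as the negative
log of the conditional probability that subsequences similar for ``m``
consecutive points remain similar at ``m + 1`` points; larger values mean a
more complex, less self-similar signal.

**Sample entropy** (SampEn) uses a hard similarity criterion: embedding
vectors ``X(i) = [x(i) .. x(i+m-1)]`` match when their Chebyshev
(max-coordinate) distance is strictly below the tolerance ``r``.  With
``N - m`` template vectors at both lengths, self-matches excluded and each
per-template fraction divided by ``N - m - 1``,

    SampEn(m, r, N) = -ln( A(r) / B(r) )

where ``B`` and ``A`` are the average match fractions at lengths ``m`` and
``m + 1``.  When no ``m + 1`` matches exist (``A = 0``) the estimator is
undefined; this implementation returns ``inf`` as a sentinel and epoch
averaging excludes (and counts) such epochs.

**Fuzzy entropy** (FuzzyEn) replaces the hard threshold with a graded
exponential membership ``exp(-d^n / r)`` and removes the local mean of each
embedding window before computing distances, which makes it insensitive to
slow baseline shifts:

    FuzzyEn(m, n, r, N) = ln Phi^m(n, r) - ln Phi^{m+1}(n, r).

Defaults follow the study protocol: SampEn with m=2, r=0.25*SD; FuzzyEn
with m=2, r=0.2*SD, fuzziness exponent n=2; entropy is computed on the
post-stimulus 0-800 ms segment of each epoch with ``r`` scaled by that
segment's own SD, then averaged per participant x condition x electrode.
All logarithms are natural (units: nats); no cross-channel normalization is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .montage import Montage
from .preprocess import EpochSet


@dataclass(frozen=True)
class EntropyParams:
    """Parameters of one entropy metric."""

    metric: str = "sampen"            # "sampen" | "fuzzyen"
    m: int = 2
    r_factor: float = 0.25            # tolerance as a multiple of segment SD
    n: int = 2                        # fuzziness exponent (fuzzyen only)

    def __post_init__(self) -> None:
        if self.metric not in ("sampen", "fuzzyen"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.m < 1 or self.r_factor <= 0 or self.n < 1:
            raise ValueError("require m >= 1, r_factor > 0, n >= 1")


SAMPEN_DEFAULT = EntropyParams(metric="sampen", m=2, r_factor=0.25)
FUZZYEN_DEFAULT = EntropyParams(metric="fuzzyen", m=2, r_factor=0.2, n=2)


def _check_series(x: np.ndarray, m: int, r: float) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64).ravel()
    if len(x) < m + 2:
        raise ValueError(f"series of length {len(x)} too short for m={m}")
    if r <= 0:
        raise ValueError("tolerance r must be positive")
    return x


def _chebyshev_pairs(absdiff: np.ndarray, m: int, n_templates: int) -> np.ndarray:
    """Pairwise Chebyshev distances of the first ``n_templates`` m-length
    embeddings, from the precomputed |x_i - x_j| matrix."""
    d = absdiff[:n_templates, :n_templates].copy()
    for k in range(1, m):
        np.maximum(d, absdiff[k:k + n_templates, k:k + n_templates], out=d)
    return d


def sample_entropy(x, m: int = 2, r: float = 1.0) -> float:
    """SampEn(m, r) of a series with *absolute* tolerance ``r``.

    Returns ``inf`` when no m+1-length matches exist.  A constant series
    returns 0 for any r > 0 (every pair matches at both lengths).
    """
    x = _check_series(x, m, r)
    n_t = len(x) - m                  # templates used at both lengths
    if n_t < 2:
        raise ValueError("series too short: fewer than two templates")
    absdiff = np.abs(x[:, None] - x[None, :])
    d_m = _chebyshev_pairs(absdiff, m, n_t)
    d_m1 = _chebyshev_pairs(absdiff, m + 1, n_t)
    off = ~np.eye(n_t, dtype=bool)    # exclude self-matches
    b = (d_m < r)[off].mean()
    a = (d_m1 < r)[off].mean()
    if a == 0.0:
        return float("inf")
    return float(np.log(b) - np.log(a))


def _fuzzy_phi(x: np.ndarray, m: int, r: float, n: int, n_templates: int) -> float:
    # local-mean-removed embeddings
    windows = np.lib.stride_tricks.sliding_window_view(x, m)[:n_templates]
    u = windows - windows.mean(axis=1, keepdims=True)
    d = np.abs(u[:, None, :] - u[None, :, :]).max(axis=2)
    sim = np.exp(-(d ** n) / r)
    off = ~np.eye(n_templates, dtype=bool)
    return float(sim[off].mean())


def fuzzy_entropy(x, m: int = 2, r: float = 1.0, n: int = 2) -> float:
    """FuzzyEn(m, n, r) with *absolute* tolerance ``r``.

    Membership is strictly positive for finite data, so no sentinel is
    needed; a constant series returns exactly 0.
    """
    x = _check_series(x, m, r)
    if n < 1:
        raise ValueError("fuzziness exponent n must be >= 1")
    n_t = len(x) - m
    if n_t < 2:
        raise ValueError("series too short: fewer than two templates")
    phi_m = _fuzzy_phi(x, m, r, n, n_t)
    phi_m1 = _fuzzy_phi(x, m + 1, r, n, n_t)
    return float(np.log(phi_m) - np.log(phi_m1))


def _batched_sampen(segs: np.ndarray, m: int, r: np.ndarray) -> np.ndarray:
    """SampEn of each row of ``segs`` (B, N) with per-row tolerance ``r``.

    Vectorized equivalent of :func:`sample_entropy`; rows without m+1
    matches get ``inf``.
    """
    b_count, n = segs.shape
    n_t = n - m
    absdiff = np.abs(segs[:, :, None] - segs[:, None, :])
    d_m = absdiff[:, :n_t, :n_t].copy()
    for k in range(1, m):
        np.maximum(d_m, absdiff[:, k:k + n_t, k:k + n_t], out=d_m)
    d_m1 = np.maximum(d_m, absdiff[:, m:m + n_t, m:m + n_t])
    off = ~np.eye(n_t, dtype=bool)
    rr = r[:, None]
    bsum = (d_m[:, off] < rr).mean(axis=1)
    asum = (d_m1[:, off] < rr).mean(axis=1)
    with np.errstate(divide="ignore"):
        out = np.log(bsum) - np.log(asum)
    out[asum == 0.0] = np.inf
    return out


def _batched_fuzzyen(segs: np.ndarray, m: int, r: np.ndarray, n_exp: int) -> np.ndarray:
    """FuzzyEn of each row of ``segs`` (B, N) with per-row tolerance ``r``."""
    def phi(mm: int) -> np.ndarray:
        w = np.lib.stride_tricks.sliding_window_view(segs, mm, axis=1)[:, :n_t]
        u = w - w.mean(axis=2, keepdims=True)
        d = np.abs(u[:, :, None, :] - u[:, None, :, :]).max(axis=3)
        sim = np.exp(-(d ** n_exp) / r[:, None, None])
        off = ~np.eye(n_t, dtype=bool)
        return sim[:, off].mean(axis=1)

    n_t = segs.shape[1] - m
    return np.log(phi(m)) - np.log(phi(m + 1))


try:  # optional JIT acceleration; the numpy path is the reference
    import numba as _numba

    @_numba.njit(cache=False)
    def _nb_sampen_many(segs, m, rs, out):  # pragma: no cover - jitted
        b_count, n = segs.shape
        n_t = n - m
        for b in range(b_count):
            x = segs[b]
            r = rs[b]
            nb = 0
            na = 0
            for i in range(n_t):
                for j in range(i + 1, n_t):
                    dm = 0.0
                    for k in range(m):
                        v = abs(x[i + k] - x[j + k])
                        if v > dm:
                            dm = v
                    if dm < r:
                        nb += 1
                        v = abs(x[i + m] - x[j + m])
                        if (v if v > dm else dm) < r:
                            na += 1
            if na == 0:
                out[b] = np.inf
            else:
                out[b] = np.log(nb / na)

    @_numba.njit(cache=False)
    def _nb_fuzzyen_many(segs, m, rs, n_exp, out):  # pragma: no cover - jitted
        b_count, n = segs.shape
        n_t = n - m
        for b in range(b_count):
            x = segs[b]
            r = rs[b]
            u_m = np.empty((n_t, m))
            u_m1 = np.empty((n_t, m + 1))
            for i in range(n_t):
                mean_m = 0.0
                for k in range(m):
                    mean_m += x[i + k]
                mean_m /= m
                for k in range(m):
                    u_m[i, k] = x[i + k] - mean_m
                mean_m1 = 0.0
                for k in range(m + 1):
                    mean_m1 += x[i + k]
                mean_m1 /= m + 1
                for k in range(m + 1):
                    u_m1[i, k] = x[i + k] - mean_m1
            s_m = 0.0
            s_m1 = 0.0
            square = n_exp == 2.0      # avoid per-pair pow for the default
            for i in range(n_t):
                for j in range(i + 1, n_t):
                    dm = 0.0
                    for k in range(m):
                        v = abs(u_m[i, k] - u_m[j, k])
                        if v > dm:
                            dm = v
                    e = dm * dm if square else dm ** n_exp
                    s_m += np.exp(-e / r)
                    dm1 = 0.0
                    for k in range(m + 1):
                        v = abs(u_m1[i, k] - u_m1[j, k])
                        if v > dm1:
                            dm1 = v
                    e1 = dm1 * dm1 if square else dm1 ** n_exp
                    s_m1 += np.exp(-e1 / r)
            out[b] = np.log(s_m) - np.log(s_m1)

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional speedup
    _HAVE_NUMBA = False


_CHUNK_ELEMENTS = 40_000_000   # cap scratch arrays at ~320 MB


def batch_entropy(segs: np.ndarray, params: EntropyParams) -> np.ndarray:
    """Entropy of every row of ``segs`` with SD-relative tolerance.

    Degenerate rows (zero SD) get ``nan``; undefined SampEn rows get
    ``inf``.  Matches the scalar functions exactly; exists because per-epoch
    x per-electrode loops over the scalar API dominate cohort runtimes.
    """
    segs = np.asarray(segs, dtype=np.float64)
    b_count, n = segs.shape
    sd = segs.std(axis=1)
    ok = sd > 0
    out = np.full(b_count, np.nan)
    if not ok.any():
        return out
    rows = np.flatnonzero(ok)
    r = params.r_factor * sd[rows]
    vals = np.empty(len(rows))
    if _HAVE_NUMBA:
        sub = np.ascontiguousarray(segs[rows])
        if params.metric == "sampen":
            _nb_sampen_many(sub, params.m, r, vals)
        else:
            _nb_fuzzyen_many(sub, params.m, r, float(params.n), vals)
    else:
        chunk = max(int(_CHUNK_ELEMENTS // (n * n)), 1)
        for i in range(0, len(rows), chunk):
            sl = rows[i:i + chunk]
            if params.metric == "sampen":
                vals[i:i + chunk] = _batched_sampen(segs[sl], params.m, r[i:i + chunk])
            else:
                vals[i:i + chunk] = _batched_fuzzyen(segs[sl], params.m,
                                                     r[i:i + chunk], params.n)
    out[rows] = vals
    return out


def entropy_of_segment(x, params: EntropyParams) -> float:
    """Entropy of one segment with the tolerance scaled by the segment SD.

    Raises on a degenerate (zero-SD) segment, where an SD-relative
    tolerance is undefined.
    """
    x = np.asarray(x, dtype=np.float64)
    sd = float(x.std())
    if sd == 0.0:
        raise ValueError("constant segment: SD-relative tolerance is zero")
    r = params.r_factor * sd
    if params.metric == "sampen":
        return sample_entropy(x, m=params.m, r=r)
    return fuzzy_entropy(x, m=params.m, r=r, n=params.n)


def epoch_entropy(ep: EpochSet, params: EntropyParams,
                  participant: int | None = None,
                  kind: str = "target") -> pd.DataFrame:
    """Per-electrode mean entropy over the usable epochs of one
    participant-condition set.

    For each epoch x electrode the post-stimulus 0-800 ms segment is
    extracted, the tolerance set to ``r_factor`` times that segment's SD,
    and the entropy computed; the arithmetic mean over epochs is reported.
    Epochs yielding the undefined-SampEn sentinel (or a degenerate segment)
    are excluded from the mean and counted in ``n_excluded``.
    """
    mask = ep.good_mask(kind=kind)
    if not mask.any():
        raise ValueError("no usable epochs")
    post = ep.times_ms >= 0
    cond = ep.meta["condition"].iloc[0] if len(ep.meta) else None
    n_ch = len(ep.ch_names)
    n_ep = int(mask.sum())
    segs = ep.data[mask][:, :, post]                 # (n_ep, n_ch, N)
    flat = segs.transpose(1, 0, 2).reshape(n_ch * n_ep, -1)
    values = batch_entropy(flat, params).reshape(n_ch, n_ep)
    rows = []
    for ci, el in enumerate(ep.ch_names):
        v = values[ci]
        good = np.isfinite(v)
        if not good.any():
            raise ValueError(f"all epochs degenerate for electrode {el}")
        rows.append({"participant": participant, "condition": cond,
                     "electrode": el, "metric": params.metric,
                     "value": float(v[good].mean()),
                     "n_epochs_averaged": int(good.sum()),
                     "n_excluded": int((~good).sum())})
    return pd.DataFrame(rows)


def region_entropy(table: pd.DataFrame, montage: Montage) -> pd.DataFrame:
    """Region-level entropy: unweighted electrode mean within region per
    participant, keeping participants separate for paired statistics."""
    df = table.copy()
    df["region"] = df["electrode"].map(montage.region_of)
    if df["region"].isna().any():
        bad = sorted(df.loc[df["region"].isna(), "electrode"].unique())
        raise ValueError(f"electrodes without region: {bad}")
    df = df[df["region"] != "reference"]
    return (df.groupby(["participant", "condition", "region", "metric"],
                       as_index=False)["value"].mean())
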