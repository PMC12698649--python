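"""Synthetic VR-CPT cohort generator.

Emulates a Go/No-go continuous performance test run in a virtual classroom
under two conditions - without (``N-D``) and with (``Y-D``) visual
distractors - at the statistical level the downstream analyses assume:

* **Task structure.** Blocks of 100 target + 50 non-target stimuli in random
  order, 500 ms stimulus duration and 1000 ms inter-stimulus interval, i.e.
  a fixed 1500 ms onset-to-onset spacing.
* **Evoked activity.** Each target elicits a positive, Gaussian-shaped P300
  component (default full width at half maximum 120 ms).  A participant's
  component latency and amplitude at each electrode are drawn once per
  condition from normal distributions whose means default to the study's
  published group means; single trials jitter around the participant
  latency.  Because trial-latency jitter smears the participant-average
  waveform, the injected single-trial amplitude is scaled up analytically
  (``sqrt(s^2 + sd_jitter^2)/s`` for a Gaussian bump of width ``s``) so the
  *measured* average-peak amplitude is calibrated to the configured mean.
* **Background activity.** 1/f ("pink") noise plus narrow-band Gaussian
  activity in the delta/theta/alpha/beta bands plus broadband white noise.
  Under the distractor condition an extra white-noise admixture (a fixed
  fraction of the background SD) is added on frontal, central and parietal
  channels only, producing the regional broadband-complexity increase the
  entropy analyses are designed to detect, while leaving occipital and
  temporal channels as a built-in negative control.
* **Behavior.** Commission, omission and multipress counts are Poisson with
  the published condition means; reaction time is truncated normal.

Everything is reproducible: a cohort is a pure function of its
:class:`CohortConfig` (including its ``seed``).
"""

from __future__ import annotations

import functools
import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .edf import write_edf
from .montage import make_montage
from .preprocess import Recording

CONDITIONS = ("N-D", "Y-D")

#: Default synthesized channel set: the six midline P300 electrodes plus two
#: lateral electrodes per region, 16 channels total.
DEFAULT_CHANNELS: tuple[str, ...] = (
    "Fz", "FCz", "F3", "F4",          # frontal
    "Cz", "CPz", "C3", "C4",          # central
    "Pz", "P3", "P4",                 # parietal
    "Oz", "O1", "O2",                 # occipital
    "T3", "T4",                       # temporal
)


@dataclass(frozen=True)
class EventSequence:
    """Ordered stimulus onsets with kind labels for one block."""

    onsets: tuple[float, ...]         # ms, strictly increasing
    kinds: tuple[str, ...]            # "target" / "nontarget"
    condition: str = "N-D"
    block_id: int = 0
    stim_ms: float = 500.0
    isi_ms: float = 1000.0

    @property
    def events(self) -> list[tuple[float, str]]:
        return list(zip(self.onsets, self.kinds))

    @property
    def n_target(self) -> int:
        return sum(k == "target" for k in self.kinds)

    @property
    def n_nontarget(self) -> int:
        return sum(k == "nontarget" for k in self.kinds)


@dataclass(frozen=True)
class ErpParams:
    """Evoked-component parameters for one electrode x condition."""

    latency_ms: float
    amplitude_uv: float
    latency_sd_ms: float = 20.0       # between-participant
    jitter_sd_ms: float = 25.0        # within-participant, trial to trial
    amplitude_sd_uv: float = 0.5      # between-participant
    width_fwhm_ms: float = 120.0


@dataclass(frozen=True)
class ComplexityParams:
    """Background-signal composition for one condition (per channel, uV)."""

    pink_sd_uv: float = 2.0
    pink_exponent: float = 1.0
    band_rms_uv: tuple[tuple[str, float], ...] = (
        ("delta", 0.7), ("theta", 0.6), ("alpha", 0.7), ("beta", 0.4),
    )
    white_sd_uv: float = 0.8
    #: extra white-noise SD under distraction, as a fraction of the total
    #: background SD; applied on ``distraction_regions`` channels only.
    distraction_white_weight: float = 0.0
    distraction_regions: tuple[str, ...] = ("frontal", "central", "parietal")

    def background_sd(self) -> float:
        band_var = sum(a ** 2 for _, a in self.band_rms_uv)
        return float(np.sqrt(self.pink_sd_uv ** 2 + band_var + self.white_sd_uv ** 2))


@dataclass(frozen=True)
class BehaviorParams:
    commission_mean: float
    omission_mean: float
    multipress_mean: float
    rt_mean_s: float
    rt_sd_s: float = 0.03


@dataclass(frozen=True)
class BehavioralRecord:
    participant_id: int
    condition: str
    commission: int
    omission: int
    multipress: int
    mean_rt: float


# Published group means used as generator calibration.
# P300 latency (ms) and peak amplitude (uV) per midline electrode; amplitude
# SDs are the published per-electrode SDs.  Latency SDs are not published;
# defaults of 20 ms (between-participant) and 25 ms (trial jitter) apply.
_P300_TABLE: dict[str, dict[str, tuple[float, float, float]]] = {
    # condition -> electrode -> (latency_ms, amplitude_uv, amplitude_sd_uv)
    "N-D": {
        "CPz": (361.69, 4.468, 0.345),
        "Pz": (356.09, 4.640, 0.597),
        "Cz": (367.74, 4.268, 0.710),
        "FCz": (375.82, 3.993, 0.805),
        "Fz": (377.73, 3.772, 0.161),
        "Oz": (327.94, 2.453, 0.326),
    },
    "Y-D": {
        "CPz": (377.10, 4.573, 0.775),
        "Pz": (376.06, 4.778, 1.012),
        "Cz": (380.38, 4.354, 0.586),
        "FCz": (381.99, 4.221, 0.518),
        "Fz": (380.17, 4.024, 0.518),
        "Oz": (351.42, 3.758, 0.805),
    },
}

# Generic evoked parameters for electrodes without published values.
_P300_GENERIC = {"N-D": (365.0, 3.0, 0.5), "Y-D": (378.0, 3.2, 0.5)}

_BEHAVIOR_TABLE: dict[str, BehaviorParams] = {
    "N-D": BehaviorParams(commission_mean=1.33, omission_mean=0.14,
                          multipress_mean=0.15, rt_mean_s=0.367),
    "Y-D": BehaviorParams(commission_mean=3.15, omission_mean=1.18,
                          multipress_mean=0.56, rt_mean_s=0.368),
}


def default_erp_params(channels: tuple[str, ...] = DEFAULT_CHANNELS,
                       symmetric: bool = False) -> dict[str, dict[str, ErpParams]]:
    """Per-condition, per-electrode evoked parameters.

    With ``symmetric=True`` both conditions use the no-distractor values, so
    that the only condition difference in a cohort is the broadband-noise
    admixture - the right control when validating the complexity analyses.
    """
    out: dict[str, dict[str, ErpParams]] = {}
    for cond in CONDITIONS:
        src = "N-D" if symmetric else cond
        table = _P300_TABLE[src]
        generic = _P300_GENERIC[src]
        out[cond] = {}
        for ch in channels:
            lat, amp, amp_sd = table.get(ch, generic)
            out[cond][ch] = ErpParams(latency_ms=lat, amplitude_uv=amp,
                                      amplitude_sd_uv=amp_sd)
    return out


def default_complexity_params(distraction_weight: float = 0.25) -> dict[str, ComplexityParams]:
    return {
        "N-D": ComplexityParams(distraction_white_weight=0.0),
        "Y-D": ComplexityParams(distraction_white_weight=distraction_weight),
    }


def default_behavior_params() -> dict[str, BehaviorParams]:
    return dict(_BEHAVIOR_TABLE)


@dataclass(frozen=True)
class CohortConfig:
    """Full description of a synthetic cohort; hashable to a manifest digest."""

    n_participants: int = 66
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    sampling_rate: float = 1000.0
    seed: int = 0
    n_target: int = 100
    n_nontarget: int = 50
    stim_ms: float = 500.0
    isi_ms: float = 1000.0
    pad_ms: float = 4000.0            # pre/post roll outside the event train
    erp_params: dict[str, dict[str, ErpParams]] = field(default_factory=default_erp_params)
    complexity_params: dict[str, ComplexityParams] = field(default_factory=default_complexity_params)
    behavior_params: dict[str, BehaviorParams] = field(default_factory=default_behavior_params)

    def __post_init__(self) -> None:
        if self.sampling_rate < 250.0:
            raise ValueError("sampling_rate must be >= 250 Hz")
        if self.n_participants < 1:
            raise ValueError("need at least one participant")
        for cond, params in self.erp_params.items():
            for ch, p in params.items():
                if min(p.latency_sd_ms, p.jitter_sd_ms, p.amplitude_sd_uv) < 0:
                    raise ValueError(f"negative SD in erp_params[{cond}][{ch}]")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def default_config(**overrides) -> CohortConfig:
    """The calibrated default cohort; keyword overrides replace fields."""
    channels = overrides.get("channels", DEFAULT_CHANNELS)
    symmetric = overrides.pop("symmetric_erp", False)
    base = dict(
        erp_params=default_erp_params(tuple(channels), symmetric=symmetric),
        complexity_params=default_complexity_params(),
        behavior_params=default_behavior_params(),
    )
    base.update(overrides)
    return CohortConfig(**base)


# ----------------------------------------------------------------- events --

def generate_events(n_target: int, n_nontarget: int, stim_ms: float = 500.0,
                    isi_ms: float = 1000.0, seed: int | None = None,
                    condition: str = "N-D", block_id: int = 0) -> EventSequence:
    """Randomly interleave target/non-target stimuli on a fixed time grid.

    Onset-to-onset spacing is ``stim_ms + isi_ms`` (1500 ms by default);
    kind labels are a uniform shuffle, deterministic given ``seed``.
    """
    if n_target <= 0 or n_nontarget < 0:
        raise ValueError("need n_target >= 1 and n_nontarget >= 0")
    rng = np.random.default_rng(seed)
    kinds = np.array(["target"] * n_target + ["nontarget"] * n_nontarget)
    kinds = rng.permutation(kinds)
    spacing = stim_ms + isi_ms
    onsets = np.arange(len(kinds)) * spacing
    return EventSequence(onsets=tuple(onsets.tolist()), kinds=tuple(kinds.tolist()),
                         condition=condition, block_id=block_id,
                         stim_ms=stim_ms, isi_ms=isi_ms)


# -------------------------------------------------------------- recording --

def _pink_noise(rng: np.random.Generator, n: int, sfreq: float,
                exponent: float) -> np.ndarray:
    """Unit-variance 1/f^exponent (power) noise via spectral shaping."""
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    spec = shape * (rng.standard_normal(len(freqs))
                    + 1j * rng.standard_normal(len(freqs)))
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _narrowband_noise(rng: np.random.Generator, n: int, sfreq: float,
                      low: float, high: float) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to [low, high) Hz."""
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    mask = (freqs >= low) & (freqs < high)
    spec = np.zeros(len(freqs), dtype=complex)
    spec[mask] = rng.standard_normal(mask.sum()) + 1j * rng.standard_normal(mask.sum())
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


_BAND_EDGES = {"delta": (0.5, 4.0), "theta": (4.0, 8.0),
               "alpha": (8.0, 12.0), "beta": (12.0, 30.0)}


def _gauss_bump(t_ms: np.ndarray, center_ms: float, amp: float, s_ms: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t_ms - center_ms) / s_ms) ** 2)


@functools.lru_cache(maxsize=256)
def _measurement_gain(lat_ms: float, s_eff_ms: float, fs: float,
                      band: tuple[float, float] = (0.5, 30.0),
                      spacing_ms: float = 1500.0) -> float:
    """Peak gain of the average evoked template through the standard
    measurement chain (zero-phase Butterworth band-pass, pre-stimulus
    baseline correction, windowed peak pick).

    The zero-phase 0.5 Hz high-pass shaves a little off a 100+ ms-wide
    positive component even after baseline correction (~2%); computing that
    transfer on a deterministic bump train lets the generator define its
    configured amplitudes as *measured* average peaks.
    """
    from scipy import signal as _signal

    onsets = np.arange(21) * spacing_ms
    pad = 4000.0
    dur = onsets[-1] + spacing_ms + 2 * pad
    n = int(np.ceil(dur / 1000.0) * fs)
    t = -pad + np.arange(n) * 1000.0 / fs
    x = np.zeros(n)
    for o in onsets:
        x += _gauss_bump(t, o + lat_ms, 1.0, s_eff_ms)
    sos = _signal.butter(4, list(band), btype="bandpass", fs=fs, output="sos")
    y = _signal.sosfiltfilt(sos, x)
    i = int((onsets[10] + pad) * fs / 1000.0)
    pre = int(200 * fs / 1000.0)
    post = int(800 * fs / 1000.0)
    ep = y[i - pre:i + post]
    ep = ep - ep[:pre].mean()
    w0, w1 = int(450 * fs / 1000.0), int(700 * fs / 1000.0) + 1
    return float(ep[w0:w1].max())


def _participant_rng(cfg: CohortConfig, participant_id: int, condition: str,
                     stream: int) -> np.random.Generator:
    """Counter-based seeding: independent stream per participant x condition."""
    c_idx = CONDITIONS.index(condition)
    ss = np.random.SeedSequence(cfg.seed, spawn_key=(participant_id, c_idx, stream))
    return np.random.default_rng(ss)


def generate_recording(cfg: CohortConfig, events: EventSequence,
                       participant_id: int, condition: str) -> Recording:
    """Synthesize one continuous recording for a participant x condition.

    The recording spans ``pad_ms`` before the first onset to ``pad_ms``
    after the last stimulus offset (rounded up to whole seconds so it maps
    onto 1-second data records on disk), with ``t0_ms`` set accordingly.
    """
    if cfg.sampling_rate < 60.0:  # pragma: no cover - blocked by config check
        raise ValueError("sampling rate too low for 30 Hz content")
    fs = cfg.sampling_rate
    comp = cfg.complexity_params[condition]
    erp = cfg.erp_params[condition]
    montage = make_montage()

    last = max(events.onsets)
    duration_ms = cfg.pad_ms + last + events.stim_ms + cfg.pad_ms
    duration_ms = float(np.ceil(duration_ms / 1000.0) * 1000.0)
    n = int(round(duration_ms * fs / 1000.0))
    t0_ms = -cfg.pad_ms
    t_ms = t0_ms + np.arange(n) * 1000.0 / fs

    trait_rng = _participant_rng(cfg, participant_id, condition, stream=0)
    noise_rng = _participant_rng(cfg, participant_id, condition, stream=1)

    target_onsets = np.array([o for o, k in zip(events.onsets, events.kinds)
                              if k == "target"])
    data = np.empty((len(cfg.channels), n))
    for ci, ch in enumerate(cfg.channels):
        p = erp[ch]
        # participant-level component traits (drawn before any noise so the
        # trait stream is independent of recording length)
        lat_p = trait_rng.normal(p.latency_ms, p.latency_sd_ms)
        amp_p = max(trait_rng.normal(p.amplitude_uv, p.amplitude_sd_uv), 0.1)

        x = comp.pink_sd_uv * _pink_noise(noise_rng, n, fs, comp.pink_exponent)
        for band, rms in comp.band_rms_uv:
            lo, hi = _BAND_EDGES[band]
            x += rms * _narrowband_noise(noise_rng, n, fs, lo, hi)
        if comp.white_sd_uv > 0:
            x += comp.white_sd_uv * noise_rng.standard_normal(n)
        if (comp.distraction_white_weight > 0
                and montage.region_of.get(ch) in comp.distraction_regions):
            extra = comp.distraction_white_weight * comp.background_sd()
            x += extra * noise_rng.standard_normal(n)

        s = p.width_fwhm_ms / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        # trial-jitter smearing attenuates the average peak by s/sqrt(s^2+j^2),
        # and the zero-phase band-pass of the measurement chain by a further
        # ~2%; pre-compensate both so the *measured* per-participant average
        # peak is calibrated to amp_p
        s_eff = np.sqrt(s ** 2 + p.jitter_sd_ms ** 2)
        gain = _measurement_gain(round(p.latency_ms), round(s_eff, 1), fs)
        amp_trial = amp_p * (s_eff / s) / gain
        for onset in target_onsets:
            lat_trial = noise_rng.normal(lat_p, p.jitter_sd_ms)
            center = onset + lat_trial
            i0 = max(int((center - 5 * s - t0_ms) * fs / 1000.0), 0)
            i1 = min(int((center + 5 * s - t0_ms) * fs / 1000.0) + 1, n)
            x[i0:i1] += _gauss_bump(t_ms[i0:i1], center, amp_trial, s)
        data[ci] = x

    return Recording(data=data, sfreq=fs, ch_names=tuple(cfg.channels),
                     t0_ms=t0_ms, participant=participant_id, condition=condition)


# --------------------------------------------------------------- behavior --

def generate_behavior(cfg: CohortConfig, participant_id: int, condition: str,
                      seed: int | None = None) -> BehavioralRecord:
    """Draw one participant's behavioral summary for a condition.

    Counts are Poisson at the configured means; mean reaction time is
    normal, truncated below at 0.05 s.  Omissions are capped at the number
    of targets.
    """
    p = cfg.behavior_params[condition]
    rng = (np.random.default_rng(seed) if seed is not None
           else _participant_rng(cfg, participant_id, condition, stream=2))
    commission = int(rng.poisson(p.commission_mean))
    omission = int(min(rng.poisson(p.omission_mean), cfg.n_target))
    multipress = int(rng.poisson(p.multipress_mean))
    rt = float(rng.normal(p.rt_mean_s, p.rt_sd_s))
    while rt < 0.05:
        rt = float(rng.normal(p.rt_mean_s, p.rt_sd_s))
    return BehavioralRecord(participant_id=participant_id, condition=condition,
                            commission=commission, omission=omission,
                            multipress=multipress, mean_rt=rt)


def behavior_table(cfg: CohortConfig) -> pd.DataFrame:
    """Behavioral records for the whole cohort, both conditions, tidy."""
    rows = []
    for pid in range(cfg.n_participants):
        for cond in CONDITIONS:
            rec = generate_behavior(cfg, pid, cond)
            rows.append(asdict(rec))
    df = pd.DataFrame(rows).rename(columns={"participant_id": "participant"})
    return df


# ----------------------------------------------------------------- cohort --

def cohort_events(cfg: CohortConfig, participant_id: int, condition: str) -> EventSequence:
    """The event sequence for one participant x condition (deterministic)."""
    rng = _participant_rng(cfg, participant_id, condition, stream=3)
    return generate_events(cfg.n_target, cfg.n_nontarget, cfg.stim_ms,
                           cfg.isi_ms, seed=int(rng.integers(2 ** 31)),
                           condition=condition)


def iter_cohort(cfg: CohortConfig):
    """Yield (participant_id, condition, events, recording) for the cohort."""
    for pid in range(cfg.n_participants):
        for cond in CONDITIONS:
            ev = cohort_events(cfg, pid, cond)
            rec = generate_recording(cfg, ev, pid, cond)
            yield pid, cond, ev, rec


def _events_tsv(path: Path, events: EventSequence) -> None:
    lines = ["onset_ms\tkind\tcondition"]
    for onset, kind in zip(events.onsets, events.kinds):
        lines.append(f"{onset:.1f}\t{kind}\t{events.condition}")
    path.write_text("\n".join(lines) + "\n")


def read_events_tsv(path: Path | str) -> EventSequence:
    df = pd.read_csv(path, sep="\t")
    cond = str(df["condition"].iloc[0]) if len(df) else "N-D"
    return EventSequence(onsets=tuple(df["onset_ms"].astype(float)),
                         kinds=tuple(df["kind"].astype(str)), condition=cond)


def generate_cohort(cfg: CohortConfig, out_dir: Path | str) -> dict:
    """Write the cohort to disk: one EDF + events TSV per participant x
    condition, a behavior CSV, and a JSON manifest with the config hash.

    Returns the manifest dict.  Byte-identical on re-run with the same
    config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for pid, cond, ev, rec in iter_cohort(cfg):
        tag = cond.replace("-", "")
        stem = f"sub-{pid:03d}_cond-{tag}"
        write_edf(out / f"{stem}.edf", rec.data, rec.sfreq, rec.ch_names)
        _events_tsv(out / f"{stem}_events.tsv", ev)
        files.append({"participant": pid, "condition": cond,
                      "edf": f"{stem}.edf", "events": f"{stem}_events.tsv",
                      "t0_ms": rec.t0_ms})
    behavior = behavior_table(cfg)
    behavior.to_csv(out / "behavior.csv", index=False)
    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_participants": cfg.n_participants,
        "sampling_rate": cfg.sampling_rate,
        "channels": list(cfg.channels),
        "conditions": list(CONDITIONS),
        "recordings": files,
        "behavior": "behavior.csv",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
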