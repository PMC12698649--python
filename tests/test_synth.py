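"""Generator tests: montage structure, event timing, behavioral draws,
injected-signal identities and cohort reproducibility."""

from dataclasses import replace

import numpy as np
import pytest

from vrcpt import synth
from vrcpt.montage import MIDLINE_6, REGION_ELECTRODES, make_montage


class TestMontage:
    def test_region_assignments(self, montage):
        assert montage.region_of["Fz"] == "frontal"
        assert montage.region_of["CPz"] == "central"
        assert montage.region_of["Oz"] == "occipital"
        assert montage.region_of["A1"] == "reference"
        assert montage.region_of["A2"] == "reference"

    def test_counts(self, montage):
        assert len(montage.channels) == 32
        assert len(set(montage.channels)) == 32
        assert len(montage.analysis_channels) == 30
        sizes = {r: len(e) for r, e in REGION_ELECTRODES.items()}
        assert sizes == {"frontal": 12, "central": 6, "parietal": 3,
                         "occipital": 3, "temporal": 6}

    def test_unknown_electrode_raises(self, montage):
        with pytest.raises(KeyError):
            montage.region("Xz")


class TestEvents:
    def test_default_block_structure(self):
        ev = synth.generate_events(100, 50, seed=0)
        assert len(ev.onsets) == 150
        assert ev.n_target == 100 and ev.n_nontarget == 50
        spacings = np.diff(ev.onsets)
        assert np.all(spacings == 1500.0)
        assert ev.onsets[-1] == 149 * 1500.0

    def test_single_target(self):
        ev = synth.generate_events(1, 0, seed=3)
        assert ev.events == [(0.0, "target")]

    def test_deterministic(self):
        a = synth.generate_events(100, 50, seed=42)
        b = synth.generate_events(100, 50, seed=42)
        assert a.kinds == b.kinds and a.onsets == b.onsets

    def test_shuffle_varies_with_seed(self):
        a = synth.generate_events(100, 50, seed=1)
        b = synth.generate_events(100, 50, seed=2)
        assert a.kinds != b.kinds

    @pytest.mark.parametrize("nt, nn", [(0, 50), (-1, 5)])
    def test_bad_counts(self, nt, nn):
        with pytest.raises(ValueError):
            synth.generate_events(nt, nn)


class TestBehavior:
    def test_zero_means_give_zero_counts(self):
        cfg = synth.default_config(seed=0, n_participants=1)
        bp = {c: synth.BehaviorParams(0.0, 0.0, 0.0, rt_mean_s=0.4)
              for c in synth.CONDITIONS}
        cfg = replace(cfg, behavior_params=bp)
        rec = synth.generate_behavior(cfg, 0, "N-D")
        assert (rec.commission, rec.omission, rec.multipress) == (0, 0, 0)
        assert rec.mean_rt > 0.05

    def test_deterministic(self):
        cfg = synth.default_config(seed=5)
        a = synth.generate_behavior(cfg, 3, "Y-D")
        b = synth.generate_behavior(cfg, 3, "Y-D")
        assert a == b

    def test_condition_calibration_means(self):
        # large cohort: empirical means within 2 SE of the configured
        # Poisson/normal means for both conditions
        cfg = synth.default_config(seed=11, n_participants=10000)
        df = synth.behavior_table(cfg)
        for cond in synth.CONDITIONS:
            p = cfg.behavior_params[cond]
            sub = df[df.condition == cond]
            for col, mean in [("commission", p.commission_mean),
                              ("omission", p.omission_mean),
                              ("multipress", p.multipress_mean)]:
                se = np.sqrt(max(mean, 1e-9) / len(sub))
                assert abs(sub[col].mean() - mean) < 2 * se + 1e-9
            se_rt = p.rt_sd_s / np.sqrt(len(sub))
            assert abs(sub["mean_rt"].mean() - p.rt_mean_s) < 2 * se_rt


def _quiet_config(**kw):
    """Config with no noise and no parameter variability."""
    cfg = synth.default_config(**kw)
    cp = {c: synth.ComplexityParams(pink_sd_uv=0.0, band_rms_uv=(),
                                    white_sd_uv=0.0)
          for c in synth.CONDITIONS}
    erp = {c: {ch: replace(p, latency_sd_ms=0.0, jitter_sd_ms=0.0,
                           amplitude_sd_uv=0.0)
               for ch, p in cfg.erp_params[c].items()}
           for c in synth.CONDITIONS}
    return replace(cfg, complexity_params=cp, erp_params=erp)


class TestRecording:
    def test_injected_bump_identity(self):
        # no noise, no jitter: the raw recording peaks at the configured
        # amplitude and latency after each target (calibration gain only
        # matters through the measurement chain, which is bypassed here)
        cfg = _quiet_config(seed=0, n_participants=1, channels=("CPz",))
        p = cfg.erp_params["N-D"]["CPz"]
        erp = {c: {"CPz": replace(p, latency_ms=360.0, amplitude_uv=4.0)}
               for c in synth.CONDITIONS}
        cfg = replace(cfg, erp_params=erp)
        ev = synth.generate_events(1, 0, seed=0)
        rec = synth.generate_recording(cfg, ev, 0, "N-D")
        t = rec.t0_ms + np.arange(rec.n_samples) * 1000.0 / rec.sfreq
        post = (t >= 0) & (t < 800)
        x = rec.data[0, post]
        # peak sits at 360 ms; amplitude is the configured 4 uV divided by
        # the (known, near-unity) measurement-chain gain
        k = int(np.argmax(x))
        assert abs(t[post][k] - 360.0) <= 1.0
        assert x.max() == pytest.approx(4.0, rel=0.03)

    def test_distraction_raises_broadband_variance(self):
        cfg = synth.default_config(seed=4, n_participants=1, channels=("Fz", "Oz"),
                                   symmetric_erp=True)
        ev = synth.cohort_events(cfg, 0, "N-D")
        rec_nd = synth.generate_recording(cfg, ev, 0, "N-D")
        rec_yd = synth.generate_recording(cfg, ev, 0, "Y-D")
        var = lambda r, ch: r.data[r.channel_index(ch)].var()
        # frontal channel gets the distractor admixture, occipital does not
        assert var(rec_yd, "Fz") > var(rec_nd, "Fz") * 1.02
        assert var(rec_yd, "Oz") == pytest.approx(var(rec_nd, "Oz"), rel=0.05)

    def test_deterministic(self):
        cfg = synth.default_config(seed=9, n_participants=1, channels=MIDLINE_6,
                                   sampling_rate=250.0, n_target=5, n_nontarget=2)
        ev = synth.cohort_events(cfg, 0, "N-D")
        a = synth.generate_recording(cfg, ev, 0, "N-D")
        b = synth.generate_recording(cfg, ev, 0, "N-D")
        np.testing.assert_array_equal(a.data, b.data)


@pytest.fixture(scope="module")
def cohort(tmp_path_factory):
    cfg = synth.default_config(seed=1, n_participants=2, channels=("Fz", "Oz"),
                               sampling_rate=250.0, n_target=4, n_nontarget=2)
    out = tmp_path_factory.mktemp("cohort")
    manifest = synth.generate_cohort(cfg, out)
    return cfg, out, manifest


class TestCohortOutput:
    def test_file_counts(self, cohort):
        _, out, manifest = cohort
        assert len(list(out.glob("*.edf"))) == 4
        assert len(list(out.glob("*_events.tsv"))) == 4
        assert (out / "behavior.csv").exists()
        assert (out / "manifest.json").exists()
        assert len(manifest["recordings"]) == 4

    def test_rerun_byte_identical_events(self, cohort, tmp_path):
        cfg, out, _ = cohort
        synth.generate_cohort(cfg, tmp_path)
        for f in sorted(out.glob("*_events.tsv")):
            assert (tmp_path / f.name).read_bytes() == f.read_bytes()
        for f in sorted(out.glob("*.edf")):
            assert (tmp_path / f.name).read_bytes() == f.read_bytes()

    def test_config_hash_tracks_erp_params(self, cohort):
        cfg, _, manifest = cohort
        erp = {c: dict(cfg.erp_params[c]) for c in cfg.erp_params}
        erp["N-D"]["Fz"] = replace(erp["N-D"]["Fz"], amplitude_uv=9.9)
        changed = replace(cfg, erp_params=erp)
        assert changed.config_hash() != manifest["config_hash"]

    def test_edf_round_trip(self, cohort):
        from vrcpt.edf import read_edf

        cfg, out, manifest = cohort
        entry = manifest["recordings"][0]
        ev = synth.read_events_tsv(out / entry["events"])
        rec = synth.generate_recording(cfg, ev, entry["participant"],
                                       entry["condition"])
        data, sfreq, ch_names = read_edf(out / entry["edf"])
        assert sfreq == cfg.sampling_rate
        assert tuple(ch_names) == ("Fz", "Oz")
        n = rec.n_samples
        quant = np.abs(data[:, :n] - rec.data).max()
        assert quant < 0.01  # 16-bit quantization at the written range
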