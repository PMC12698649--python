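"""Entropy estimators against exhaustive oracles, closed forms and
structural invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vrcpt.complexity import (EntropyParams, FUZZYEN_DEFAULT, SAMPEN_DEFAULT,
                              batch_entropy, entropy_of_segment, epoch_entropy,
                              fuzzy_entropy, region_entropy, sample_entropy)
from ._oracles import fuzzyen_bruteforce, sampen_bruteforce


def _random_series(n_series=12, max_len=200, seed=123):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_series):
        n = int(rng.integers(12, max_len + 1))
        kind = rng.integers(3)
        if kind == 0:
            x = rng.standard_normal(n)
        elif kind == 1:
            x = np.sin(np.arange(n) * 0.3) + 0.3 * rng.standard_normal(n)
        else:
            x = rng.integers(-3, 4, size=n).astype(float)
            x += 1e-6 * rng.standard_normal(n)   # break exact ties
        out.append(x)
    return out


class TestOracleEquivalence:
    @pytest.mark.parametrize("idx", range(12))
    def test_sampen_matches_bruteforce(self, idx):
        x = _random_series()[idx]
        r = 0.25 * x.std()
        fast = sample_entropy(x, 2, r)
        slow = sampen_bruteforce(x, 2, r)
        if np.isinf(slow):
            assert np.isinf(fast)
        else:
            assert fast == pytest.approx(slow, rel=1e-10)

    @pytest.mark.parametrize("idx", range(12))
    def test_fuzzyen_matches_bruteforce(self, idx):
        x = _random_series()[idx]
        r = 0.2 * x.std()
        assert fuzzy_entropy(x, 2, r, 2) == pytest.approx(
            fuzzyen_bruteforce(x, 2, r, 2), rel=1e-10)

    def test_worked_sequence(self):
        x = [1, 2, 3, 2, 1, 2, 3, 2, 1]
        assert sample_entropy(x, 2, 0.5) == pytest.approx(
            sampen_bruteforce(x, 2, 0.5), rel=1e-12)
        assert fuzzy_entropy(x, 2, 0.2, 2) == pytest.approx(
            fuzzyen_bruteforce(x, 2, 0.2, 2), rel=1e-12)

    @pytest.mark.parametrize("m", [1, 3])
    def test_other_embedding_dimensions(self, m):
        x = np.random.default_rng(9).standard_normal(80)
        r = 0.3 * x.std()
        assert sample_entropy(x, m, r) == pytest.approx(
            sampen_bruteforce(x, m, r), rel=1e-10)
        assert fuzzy_entropy(x, m, r, 2) == pytest.approx(
            fuzzyen_bruteforce(x, m, r, 2), rel=1e-10)

    def test_batched_equals_scalar(self):
        rng = np.random.default_rng(5)
        segs = rng.standard_normal((8, 120))
        for params in (SAMPEN_DEFAULT, FUZZYEN_DEFAULT):
            batched = batch_entropy(segs, params)
            for i, x in enumerate(segs):
                assert batched[i] == pytest.approx(
                    entropy_of_segment(x, params), rel=1e-9)


class TestKnownValues:
    def test_constant_series_zero_with_absolute_r(self):
        x = np.full(60, 3.3)
        assert sample_entropy(x, 2, 0.2) == 0.0
        assert fuzzy_entropy(x, 2, 0.2, 2) == 0.0

    def test_iid_gaussian_closed_form(self):
        # for iid data the conditional match probability is
        # P(|X - Y| < r) = 2*Phi(r/(sigma*sqrt(2))) - 1
        from scipy.stats import norm

        rng = np.random.default_rng(42)
        x = rng.standard_normal(5000)
        value = sample_entropy(x, 2, 0.25 * x.std())
        expected = -np.log(2 * norm.cdf(0.25 / np.sqrt(2)) - 1)
        assert value == pytest.approx(expected, abs=0.1)

    def test_sampen_sentinel_when_no_m1_matches(self):
        x = np.array([0.0, 0.0, 0.0, 5.0, 0.0, 0.0, 10.0])
        assert np.isinf(sample_entropy(x, 2, 0.5))

    def test_short_series_and_bad_r_raise(self):
        with pytest.raises(ValueError):
            sample_entropy([1.0, 2.0, 3.0], m=2, r=0.5)
        with pytest.raises(ValueError):
            fuzzy_entropy(np.arange(50.0), m=2, r=0.0, n=2)
        with pytest.raises(ValueError):
            entropy_of_segment(np.zeros(50), SAMPEN_DEFAULT)


class TestInvariants:
    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(0, 10_000), st.sampled_from([0.5, -2.0, 10.0]))
    def test_sampen_scale_invariant_with_relative_r(self, seed, scale):
        # SampEn thresholds d < r, so d and r rescale together; FuzzyEn's
        # exponential membership exp(-d^n/r) is *not* scale-free for n > 1
        # (d^n grows as a^n while r grows as a), so only the n=1 variant is
        # checked for invariance
        x = np.random.default_rng(seed).standard_normal(60)
        a = entropy_of_segment(x, SAMPEN_DEFAULT)
        b = entropy_of_segment(scale * x, SAMPEN_DEFAULT)
        assert b == pytest.approx(a, rel=1e-9)
        lin = EntropyParams(metric="fuzzyen", m=2, r_factor=0.2, n=1)
        a = entropy_of_segment(x, lin)
        b = entropy_of_segment(scale * x, lin)
        assert b == pytest.approx(a, rel=1e-9)

    def test_fuzzyen_monotone_in_r(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            x = rng.standard_normal(80)
            rs = np.linspace(0.05, 1.5, 12) * x.std()
            vals = [fuzzy_entropy(x, 2, r, 2) for r in rs]
            assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_sampen_decreases_over_decades_of_r(self):
        # the finite-sample SampEn curve can wiggle locally, but across a
        # decade of tolerance it must fall
        rng = np.random.default_rng(12)
        for _ in range(5):
            x = rng.standard_normal(120)
            lo = sample_entropy(x, 2, 0.15 * x.std())
            hi = sample_entropy(x, 2, 1.5 * x.std())
            assert hi < lo

    def test_fuzzyen_more_robust_to_linear_trend(self):
        # local-mean removal absorbs slow trends: adding a ramp changes
        # FuzzyEn less than SampEn (tolerances held at the absolute values
        # of the untrended series)
        rng = np.random.default_rng(13)
        x = rng.standard_normal(150)
        trend = np.linspace(0.0, 4.0, 150)
        r_s, r_f = 0.25 * x.std(), 0.2 * x.std()
        d_samp = abs(sample_entropy(x + trend, 2, r_s) - sample_entropy(x, 2, r_s))
        d_fuzz = abs(fuzzy_entropy(x + trend, 2, r_f, 2) - fuzzy_entropy(x, 2, r_f, 2))
        assert d_fuzz < d_samp


class TestEpochEntropy:
    def test_identical_epochs_equal_single_epoch_value(self, make_epochs):
        rng = np.random.default_rng(3)
        base = rng.standard_normal(1000)
        ep = make_epochs(np.tile(base, (5, 1, 1)))
        tbl = epoch_entropy(ep, SAMPEN_DEFAULT, participant=0)
        post = base[200:]
        expected = entropy_of_segment(post, SAMPEN_DEFAULT)
        assert tbl["value"].iloc[0] == pytest.approx(expected, rel=1e-9)
        assert tbl["n_epochs_averaged"].iloc[0] == 5

    def test_segment_length_is_post_stimulus_only(self, make_epochs):
        ep = make_epochs(np.random.default_rng(4).standard_normal((2, 1, 1000)))
        assert int((ep.times_ms >= 0).sum()) == 800  # 0..800 ms at 1000 Hz

    def test_entropy_increases_with_noise_admixture(self, make_epochs):
        # more broadband admixture on a structured signal -> higher SampEn
        rng = np.random.default_rng(5)
        t = np.arange(1000) / 250.0
        carrier = np.sin(2 * np.pi * 5.0 * t)
        means = []
        for w in (0.1, 0.4, 0.8):
            data = carrier + w * rng.standard_normal((20, 1, 1000))
            tbl = epoch_entropy(make_epochs(data[:, :, :], sfreq=250.0),
                                SAMPEN_DEFAULT, participant=0)
            means.append(tbl["value"].iloc[0])
        assert means[0] < means[1] < means[2]

    def test_region_aggregation(self, montage, make_epochs):
        import pandas as pd

        rows = []
        for el, v in [("Pz", 1.0), ("P3", 3.0), ("Oz", 7.0)]:
            rows.append({"participant": 0, "condition": "N-D", "electrode": el,
                         "metric": "sampen", "value": v})
        reg = region_entropy(pd.DataFrame(rows), montage)
        reg = reg.set_index("region")["value"]
        assert reg["parietal"] == pytest.approx(2.0)
        assert reg["occipital"] == pytest.approx(7.0)
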