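"""Phase extraction, PLV engine, cochlear envelope, synchronizer classifier."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from syncsl.sync import (
    EnvelopeSignal,
    PhaseSeries,
    classify_synchronizers,
    cochlear_envelope,
    compute_plv,
    extract_phase,
)


def _sinusoid_envelope(freq, duration=20.0, rate=100.0):
    t = np.arange(int(duration * rate)) / rate
    return EnvelopeSignal(samples=1 + np.cos(2 * np.pi * freq * t), rate_hz=rate)


class TestExtractPhase:
    def test_pure_tone_phase_slope(self):
        ph = extract_phase(_sinusoid_envelope(4.5))
        slope = np.polyfit(
            np.arange(len(ph.theta))[200:-200] / 100.0,
            np.unwrap(ph.theta)[200:-200],
            1,
        )[0]
        assert abs(slope - 2 * np.pi * 4.5) / (2 * np.pi * 4.5) < 0.01

    def test_out_of_band_component_removed(self):
        t = np.arange(2000) / 100.0
        mixed = EnvelopeSignal(
            samples=1 + np.cos(2 * np.pi * 4.5 * t) + 0.8 * np.cos(2 * np.pi * 10 * t),
            rate_hz=100.0,
        )
        pure = _sinusoid_envelope(4.5)
        pm = extract_phase(mixed).theta[300:-300]
        pp = extract_phase(pure).theta[300:-300]
        diff = np.angle(np.exp(1j * (pm - pp)))
        assert np.sqrt(np.mean(diff**2)) < 0.05

    def test_white_noise_phase_well_defined(self):
        rng = np.random.default_rng(0)
        env = EnvelopeSignal(samples=rng.random(2000), rate_hz=100.0)
        ph = extract_phase(env)
        assert np.all(np.isfinite(ph.theta))
        assert np.all(np.abs(ph.theta) <= np.pi + 1e-12)

    def test_resampling_path(self):
        # 1 kHz input resampled to 100 Hz keeps the 4.5 Hz phase ramp
        t = np.arange(20_000) / 1000.0
        env = EnvelopeSignal(samples=1 + np.cos(2 * np.pi * 4.5 * t), rate_hz=1000.0)
        ph = extract_phase(env)
        assert ph.rate_hz == 100.0
        slope = np.polyfit(
            np.arange(len(ph.theta))[200:-200] / 100.0,
            np.unwrap(ph.theta)[200:-200],
            1,
        )[0]
        assert abs(slope - 2 * np.pi * 4.5) / (2 * np.pi * 4.5) < 0.01

    def test_short_input_names_minimum(self):
        with pytest.raises(ValueError, match="5 s"):
            extract_phase(_sinusoid_envelope(4.5, duration=3.0))


class TestComputePlv:
    def test_identical_phases_unit_plv(self):
        rng = np.random.default_rng(1)
        th = rng.uniform(-np.pi, np.pi, 2000)
        res = compute_plv(PhaseSeries(th), PhaseSeries(th))
        assert np.allclose(res.window_plvs, 1.0)
        assert res.mean_plv == pytest.approx(1.0)

    def test_constant_lag_unit_plv(self):
        rng = np.random.default_rng(2)
        th = rng.uniform(-np.pi, np.pi, 2000)
        res = compute_plv(PhaseSeries(th), PhaseSeries(th - np.pi / 4))
        assert res.mean_plv == pytest.approx(1.0)

    def test_two_sample_hand_computation(self):
        # |e^{i0} + e^{i pi/2}| / 2 = sqrt(2)/2
        res = compute_plv(
            PhaseSeries(np.array([0.0, np.pi / 2]), rate_hz=1.0),
            PhaseSeries(np.array([0.0, 0.0]), rate_hz=1.0),
            window_s=2.0,
            overlap_s=0.0,
        )
        assert res.mean_plv == pytest.approx(np.sqrt(2) / 2, abs=1e-12)

    def test_windowing_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        th1 = rng.uniform(-np.pi, np.pi, 1700)
        th2 = rng.uniform(-np.pi, np.pi, 1700)
        res = compute_plv(PhaseSeries(th1), PhaseSeries(th2))
        # oracle: explicit complex sums over 5 s windows hopped by 3 s at 100 Hz
        expected = []
        start = 0
        while start + 500 <= 1700:
            acc = 0j
            for t in range(start, start + 500):
                acc += np.exp(1j * (th1[t] - th2[t]))
            expected.append(abs(acc) / 500)
            start += 300
        np.testing.assert_allclose(res.window_plvs, expected, atol=1e-12)
        assert res.mean_plv == pytest.approx(np.mean(expected), abs=1e-12)
        assert res.t_per_window == 500

    def test_independent_phases_low_plv(self):
        rng = np.random.default_rng(4)
        n_low = 0
        n_seeds = 200
        for _ in range(n_seeds):
            th1 = rng.uniform(-np.pi, np.pi, 6000)
            th2 = rng.uniform(-np.pi, np.pi, 6000)
            if compute_plv(PhaseSeries(th1), PhaseSeries(th2)).mean_plv < 0.15:
                n_low += 1
        assert n_low >= 0.99 * n_seeds

    def test_hop_override(self):
        rng = np.random.default_rng(5)
        th = rng.uniform(-np.pi, np.pi, 2000)
        res = compute_plv(PhaseSeries(th), PhaseSeries(th), hop_s=2.0)
        assert len(res.window_plvs) == len(range(0, 2000 - 500 + 1, 200))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_plv(PhaseSeries(np.zeros(600)), PhaseSeries(np.zeros(700)))

    @settings(deadline=None, max_examples=20)
    @given(st.integers(0, 10_000), st.floats(-np.pi, np.pi))
    def test_offset_invariance_and_symmetry(self, seed, offset):
        rng = np.random.default_rng(seed)
        th1 = rng.uniform(-np.pi, np.pi, 800)
        th2 = rng.uniform(-np.pi, np.pi, 800)
        base = compute_plv(PhaseSeries(th1), PhaseSeries(th2))
        shifted = compute_plv(PhaseSeries(th1 + offset), PhaseSeries(th2))
        swapped = compute_plv(PhaseSeries(th2), PhaseSeries(th1))
        np.testing.assert_allclose(base.window_plvs, shifted.window_plvs, atol=1e-9)
        np.testing.assert_allclose(base.window_plvs, swapped.window_plvs, atol=1e-12)


class TestCochlearEnvelope:
    def test_am_tone_recovers_modulation_rate(self):
        fs = 16000.0
        t = np.arange(int(4 * fs)) / fs
        wav = (1 + 0.9 * np.cos(2 * np.pi * 4.5 * t)) * np.sin(2 * np.pi * 1000 * t)
        env = cochlear_envelope(wav, fs, n_channels=16)
        x = env.samples - np.mean(env.samples)
        freqs = np.fft.rfftfreq(len(x), 1 / fs)
        spec = np.abs(np.fft.rfft(x))
        sel = (freqs > 0.5) & (freqs < 20)
        peak = freqs[sel][np.argmax(spec[sel])]
        assert abs(peak - 4.5) < 0.3

    def test_silence_gives_zero_envelope(self):
        env = cochlear_envelope(np.zeros(16000), 16000.0, n_channels=8)
        assert np.allclose(env.samples, 0.0)

    def test_linearity_in_amplitude(self):
        rng = np.random.default_rng(6)
        wav = rng.standard_normal(8000)
        e1 = cochlear_envelope(wav, 16000.0, n_channels=8).samples
        e2 = cochlear_envelope(2 * wav, 16000.0, n_channels=8).samples
        np.testing.assert_allclose(e2, 2 * e1, rtol=1e-9)

    def test_empty_audio_rejected(self):
        with pytest.raises(ValueError):
            cochlear_envelope(np.array([]), 16000.0)


def test_plv_table_tidy_format():
    from syncsl.sync import PLVResult, plv_table

    res = PLVResult(window_plvs=np.array([0.4, 0.6]), mean_plv=0.5)
    df = plv_table({"P01": res}, block="sss")
    assert list(df.columns) == ["participant", "block", "window", "plv", "mean_plv"]
    assert len(df) == 2
    assert (df["mean_plv"] == 0.5).all()


def _optimal_split_oracle(values):
    """Exhaustive 1-D two-means: scan all split points of the sorted data."""
    v = np.sort(np.asarray(values, float))
    best = None
    for i in range(1, len(v)):
        lo, hi = v[:i], v[i:]
        sse = np.sum((lo - lo.mean()) ** 2) + np.sum((hi - hi.mean()) ** 2)
        if best is None or sse < best[0]:
            best = (sse, lo.mean(), hi.mean())
    return best[1], best[2]


class TestClassifySynchronizers:
    def test_worked_example(self):
        pool = np.array([0.1, 0.15, 0.2, 0.7, 0.75, 0.8])
        cls = classify_synchronizers(pool)
        assert cls.cluster_centers == pytest.approx((0.15, 0.75))
        assert cls.threshold == pytest.approx(0.45)
        assert cls.labels == ("low",) * 3 + ("high",) * 3

    @pytest.mark.parametrize("seed", range(30))
    def test_two_means_equals_exhaustive_split(self, seed):
        rng = np.random.default_rng(seed)
        pool = np.concatenate([
            rng.uniform(0.05, 0.4, rng.integers(4, 30)),
            rng.uniform(0.5, 0.95, rng.integers(4, 30)),
        ])
        cls = classify_synchronizers(pool)
        lo, hi = _optimal_split_oracle(pool)
        assert cls.cluster_centers[0] == pytest.approx(lo, abs=1e-10)
        assert cls.cluster_centers[1] == pytest.approx(hi, abs=1e-10)

    def test_matches_sklearn_kmeans(self):
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(99)
        pool = np.concatenate([rng.normal(0.25, 0.07, 40), rng.normal(0.7, 0.07, 40)])
        cls = classify_synchronizers(pool)
        km = KMeans(n_clusters=2, n_init=50, random_state=0).fit(pool[:, None])
        centers = np.sort(km.cluster_centers_.ravel())
        np.testing.assert_allclose(cls.cluster_centers, centers, atol=1e-8)

    def test_reference_pool_controls_threshold(self):
        ref = np.array([0.1, 0.15, 0.2, 0.7, 0.75, 0.8])
        cls = classify_synchronizers(np.array([0.3, 0.6]), reference_plvs=ref)
        assert cls.threshold == pytest.approx(0.45)
        assert cls.labels == ("low", "high")

    def test_tie_goes_low(self):
        ref = np.array([0.1, 0.2, 0.7, 0.8])
        cls = classify_synchronizers(np.array([0.45]), reference_plvs=ref)
        assert cls.threshold == pytest.approx(0.45)
        assert cls.labels == ("low",)

    def test_constant_pool_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            classify_synchronizers(np.full(6, 0.5))

    def test_small_pool_rejected(self):
        with pytest.raises(ValueError):
            classify_synchronizers(np.array([0.1, 0.9]))
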