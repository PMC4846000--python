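import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal

from gaitattn import (
    MVThresholds,
    bandpass_filter,
    detect_bad_channels,
    mv_threshold,
    mv_threshold_curve,
    mv_thresholds,
    notch_filter,
    reconstruct_channels,
    standardize,
)
from gaitattn.preprocess import preprocess
from gaitattn.simulate import corrupt_channels

from conftest import wrap_data

FS = 1200.0


def tone(freq, n=4800, fs=FS, amp=10.0):
    t = np.arange(n) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def session_with(channel0, fs=FS):
    data = np.zeros((32, len(channel0)), dtype=np.float32)
    data[0] = channel0
    return wrap_data(data, fs)


def rms(x):
    return float(np.sqrt(np.mean(np.asarray(x, dtype=np.float64) ** 2)))


class TestBandpass:
    def test_stopband_low(self):
        x = tone(0.05, n=4800 * 10)  # long enough for several cycles
        out = bandpass_filter(session_with(x))
        assert rms(out.data[0]) < 0.1 * rms(x)

    def test_passband(self):
        x = tone(10.0)
        out = bandpass_filter(session_with(x))
        assert abs(rms(out.data[0]) - rms(x)) < 0.05 * rms(x)

    def test_white_noise_out_of_band_power(self):
        # Out-of-band power measured beyond the 4th-order filter's
        # transition region (a Butterworth is 1/2-power at its own edge,
        # so power inside the transition band is unavoidable by design).
        rng = np.random.default_rng(0)
        x = rng.normal(0, 5, 48000)
        out = bandpass_filter(session_with(x))
        f, pxx = signal.periodogram(out.data[0].astype(np.float64), fs=FS)
        far_out = pxx[(f < 0.25) | (f > 115)].sum()
        assert far_out / pxx.sum() < 0.01

    def test_20db_attenuation_at_stopband_marks(self):
        for freq, n in ((0.1, 480000), (150.0, 48000)):
            x = tone(freq, n=n)
            out = bandpass_filter(session_with(x))
            interior = slice(n // 4, -n // 4)  # skip filtfilt edge ramps
            assert rms(out.data[0][interior]) < 0.1 * rms(x[interior])

    def test_fs_too_low_rejected(self):
        with pytest.raises(ValueError, match="too low"):
            bandpass_filter(session_with(tone(10, fs=150.0), fs=150.0))


class TestNotch:
    def test_50hz_removed(self):
        x = tone(50.0)
        out = notch_filter(session_with(x))
        assert rms(out.data[0]) < 0.1 * rms(x)

    def test_10hz_untouched(self):
        x = tone(10.0)
        out = notch_filter(session_with(x))
        assert abs(rms(out.data[0]) - rms(x)) < 0.02 * rms(x)

    def test_mixed_tone_periodogram(self):
        x = tone(10.0) + tone(50.0)
        out = notch_filter(session_with(x))
        f, pxx = signal.periodogram(out.data[0].astype(np.float64), fs=FS)
        p10 = pxx[np.argmin(np.abs(f - 10))]
        p50 = pxx[np.argmin(np.abs(f - 50))]
        assert p50 < 1e-2 * p10

    def test_neighboring_frequencies_preserved(self):
        for freq in (40.0, 60.0):
            x = tone(freq)
            out = notch_filter(session_with(x))
            # < 1 dB attenuation
            assert rms(out.data[0]) > 10 ** (-1 / 20) * rms(x)

    def test_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            notch_filter(session_with(tone(10, fs=80.0), fs=80.0), f0=50.0)


class TestDetectBadChannels:
    def test_all_within_range_empty(self):
        data = np.full((32, 400), 10.0, dtype=np.float32)
        assert detect_bad_channels(wrap_data(data, 100.0)) == set()

    def test_constant_200uv_flagged(self):
        data = np.full((32, 400), 10.0, dtype=np.float32)
        data[5] = 200.0
        session = wrap_data(data, 100.0)
        assert detect_bad_channels(session) == {session.montage.names[5]}

    def test_boundary_fraction_not_flagged(self):
        # exactly frac of the samples exceed the limit: strict > applies
        n = 400
        data = np.full((32, n), 10.0, dtype=np.float32)
        k = int(0.05 * n)
        data[3, :k] = 80.0
        session = wrap_data(data, 100.0)
        assert detect_bad_channels(session, frac=0.05) == set()
        data[3, k] = 80.0  # one more sample pushes it over
        session = wrap_data(data, 100.0)
        assert detect_bad_channels(session, frac=0.05) == {
            session.montage.names[3]
        }


class TestReconstruct:
    def test_constant_neighbors(self):
        data = np.full((32, 100), 3.0, dtype=np.float32)
        session = wrap_data(data, 100.0)
        m = session.montage
        bad = {"CZ"}
        data[m.index("CZ")] = 500.0
        out = reconstruct_channels(session, bad)
        np.testing.assert_allclose(out.data[m.index("CZ")], 3.0)

    def test_two_neighbor_mean(self):
        data = np.zeros((32, 12), dtype=np.float32)
        session = wrap_data(data, 100.0)
        m = session.montage
        # PO3's neighbors are exactly {POZ, P3}
        assert m.neighbors["PO3"] == frozenset({"POZ", "P3"})
        data[m.index("POZ")] = 1.0
        data[m.index("P3")] = 3.0
        out = reconstruct_channels(wrap_data(data, 100.0), {"PO3"})
        np.testing.assert_allclose(out.data[m.index("PO3")], 2.0)

    def test_matches_bruteforce_oracle(self, small_session):
        bad = {"PO7", "C3"}
        out = reconstruct_channels(small_session, bad)
        m = small_session.montage
        for label in bad:
            good = sorted(m.neighbors[label] - bad)
            expected = np.zeros(small_session.n_samples)
            for g in good:  # independent loop-based neighbor mean
                expected += small_session.data[m.index(g)]
            expected /= len(good)
            np.testing.assert_array_equal(
                out.data[m.index(label)],
                expected.astype(np.float32)
                if out.data.dtype == np.float32 else expected,
            )
        for c, name in enumerate(m.names):
            if name not in bad:
                np.testing.assert_array_equal(
                    out.data[c], small_session.data[c]
                )

    def test_reconstruction_is_linear_combination(self, small_session):
        out = reconstruct_channels(small_session, {"CPZ"})
        m = small_session.montage
        nbrs = sorted(m.neighbors["CPZ"])
        coeffs = np.linalg.lstsq(
            small_session.data[[m.index(g) for g in nbrs]].T.astype(
                np.float64
            ),
            out.data[m.index("CPZ")].astype(np.float64),
            rcond=None,
        )[0]
        np.testing.assert_allclose(coeffs, 1.0 / len(nbrs), atol=1e-4)

    def test_no_good_neighbor_rejected(self, small_session):
        m = small_session.montage
        bad = {"CZ"} | set(m.neighbors["CZ"])
        with pytest.raises(ValueError, match="no good neighbors"):
            reconstruct_channels(small_session, bad)

    def test_unknown_label_rejected(self, small_session):
        with pytest.raises(ValueError, match="unknown"):
            reconstruct_channels(small_session, {"OZ"})


class TestMVThreshold:
    def test_constant_signal(self):
        assert mv_threshold(np.full(100, 5.0), 7) == 5.0

    def test_hand_case(self):
        assert mv_threshold(np.array([1, 2, 3, 4, 5, 6.0]), 2) == 4.0

    def test_remainder_dropped(self):
        # epochs [1,2] and [3,4]; trailing 9 ignored
        assert mv_threshold(np.array([1, 2, 3, 4, 9.0]), 2) == 3.0

    def test_matches_two_loop_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 10, 12000)
        L = 1200
        n_epochs = len(x) // L
        total = 0.0
        for i in range(n_epochs):  # direct two-loop evaluation
            best = -np.inf
            for j in range(L):
                best = max(best, x[i * L + j])
            total += best
        assert mv_threshold(x, L) == total / n_epochs

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            mv_threshold(np.arange(5.0), 6)

    @given(
        scale=st.floats(min_value=0.01, max_value=100.0),
        seed=st.integers(0, 1000),
    )
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance(self, scale, seed):
        x = np.random.default_rng(seed).normal(0, 1, 240)
        left = mv_threshold(scale * x, 24)
        right = scale * mv_threshold(x, 24)
        assert left == pytest.approx(right, rel=1e-12)

    def test_absolute_option(self):
        x = np.array([-5.0, 1.0, -4.0, 2.0])
        assert mv_threshold(x, 2) == 1.5
        assert mv_threshold(x, 2, absolute=True) == 4.5


class TestMVCurve:
    def test_flat_for_constant(self):
        curve = mv_threshold_curve(np.full(120, 2.5), [1, 2, 5, 10, 60])
        assert all(v == 2.5 for _, v in curve)

    def test_l1_equals_mean(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 500)
        (_, v), = mv_threshold_curve(x, [1])
        assert v == pytest.approx(x.mean())

    @given(seed=st.integers(0, 500))
    @settings(max_examples=25, deadline=None)
    def test_monotone_over_multiples(self, seed):
        x = np.random.default_rng(seed).normal(0, 1, 240)
        for l1, l2 in [(1, 2), (2, 4), (4, 12), (12, 24), (24, 240)]:
            assert mv_threshold(x, l2) >= mv_threshold(x, l1) - 1e-12

    def test_l_exceeding_length_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            mv_threshold_curve(np.arange(10.0), [11])


class TestStandardize:
    def test_division_by_mean_threshold(self):
        data = np.full((32, 64), 6.0, dtype=np.float32)
        session = wrap_data(data, 16.0)
        values = np.array([2.0, 4.0] * 16)  # mean 3
        thr = MVThresholds(values=values, epoch_width_L=16, n_epochs_N=4)
        out = standardize(session, thr)
        assert out.denominator == 3.0
        np.testing.assert_allclose(out.data, 2.0)

    def test_gain_invariance(self, small_session):
        thr = mv_thresholds(small_session)
        base = standardize(small_session, thr)
        scaled_session = small_session.copy(data=small_session.data * 3.7)
        thr2 = mv_thresholds(scaled_session)
        scaled = standardize(scaled_session, thr2)
        np.testing.assert_allclose(scaled.data, base.data, rtol=2e-5)

    def test_all_zero_rejected(self):
        data = np.zeros((32, 64), dtype=np.float32)
        session = wrap_data(data, 16.0)
        thr = mv_thresholds(session, L=16)
        with pytest.raises(ValueError, match="zero denominator"):
            standardize(session, thr)

    def test_threshold_count_enforced(self, small_session):
        thr = MVThresholds(values=np.ones(5), epoch_width_L=10, n_epochs_N=1)
        with pytest.raises(ValueError, match="per channel"):
            standardize(small_session, thr)

    def test_idempotent_up_to_gain(self, small_session):
        thr = mv_thresholds(small_session)
        once = standardize(small_session, thr)
        thr2 = mv_thresholds(once.session)
        assert thr2.values == pytest.approx(
            thr.values / thr.mean, rel=1e-5
        )
        assert thr2.mean == pytest.approx(1.0, rel=1e-5)

    def test_default_l_is_one_second(self, small_session):
        thr = mv_thresholds(small_session)
        assert thr.epoch_width_L == int(small_session.fs)
        assert thr.values.shape == (32,)


class TestPipeline:
    def test_corrupted_channel_detected_and_repaired(self, small_config):
        from gaitattn import generate_session

        session = generate_session(small_config)
        session = corrupt_channels(session, [("PO7", 200.0)])
        standardized, report = preprocess(session)
        assert report["bad_channels"] == ["PO7"]
        assert report["reconstructed_from"]["PO7"] == sorted(
            session.montage.neighbors["PO7"]
        )
        m = session.montage
        assert np.abs(standardized.data[m.index("PO7")]).max() < 50.0
        assert report["exceed_fraction"]["PO7"] > 0.5

    def test_clean_session_untouched_by_repair(self, small_session):
        _, report = preprocess(small_session)
        assert report["bad_channels"] == []
        assert report["reconstructed_from"] == {}
        assert len(report["mv_threshold"]) == 32
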