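import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from accvi.calcium import (
    WindowError,
    compute_dff,
    detect_onset,
    preprocess_trace,
    robust_baseline,
    window_mean,
    zscore_event_aligned,
)
from accvi.calcium import test_responsiveness as responsiveness_screen  # avoid pytest collection

RATE = 30.0


def brute_force_f0(x):
    """Independent oracle: manual linear-interpolation percentiles + mask + mean."""
    s = sorted(x)
    n = len(s)

    def pct(q):
        pos = (n - 1) * q / 100.0
        lo, hi = int(np.floor(pos)), int(np.ceil(pos))
        return s[lo] + (pos - lo) * (s[hi] - s[lo])

    q25, q75 = pct(25), pct(75)
    kept = [v for v in x if q25 <= v <= q75]
    return sum(kept) / len(kept)


class TestDff:
    def test_constant_trace_is_zero(self):
        F = np.full((1, 1, 90), 3.7)
        dff, valid = compute_dff(F, RATE, 60)
        assert valid.all()
        assert np.allclose(dff, 0.0)

    def test_worked_percentile_baseline(self):
        """Baseline 1..8: q25 = 2.75, q75 = 6.25, F0 = mean(3,4,5,6) = 4.5."""
        assert robust_baseline(np.arange(1, 9)) == pytest.approx(4.5)

    def test_doubling_gives_unity(self):
        F = np.full((1, 1, 90), 2.0)
        F[0, 0, 60:] = 4.0
        dff, _ = compute_dff(F, RATE, 60)
        assert np.allclose(dff[0, 0, 60:], 1.0)

    def test_nonpositive_baseline_flagged(self):
        F = np.zeros((1, 1, 90))
        dff, valid = compute_dff(F, RATE, 60)
        assert not valid.any()
        assert np.isnan(dff).all()

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        hnp.arrays(
            float,
            st.integers(8, 40),
            elements=st.floats(0.1, 100, allow_nan=False),
        )
    )
    def test_matches_brute_force_oracle(self, baseline):
        n = len(baseline)
        F = np.concatenate([baseline, [1.0]])[None, None, :]
        dff, valid = compute_dff(F, RATE, n, baseline_window=(-n / RATE, 0.0))
        f0 = brute_force_f0(list(baseline))
        if f0 > 0:
            assert valid.all()
            assert dff[0, 0, -1] == pytest.approx((1.0 - f0) / f0, rel=1e-12)


class TestZscore:
    def test_hand_arithmetic(self):
        # baseline frames [0.05, 0.15]: mean 0.1, sd(ddof=1) = 0.0707...
        dff = np.full((1, 1, 10), 0.2)
        dff[0, 0, :2] = [0.05, 0.15]
        z, valid = zscore_event_aligned(dff, frame_rate=30, t0_frame=2, baseline_window=(-2 / 30, 0))
        assert valid.all()
        sd = np.sqrt(2 * 0.05**2)
        assert z[0, 0, 5] == pytest.approx((0.2 - 0.1) / sd)

    def test_scale_invariance(self, rng):
        dff = rng.normal(size=(2, 3, 90))
        z1, _ = zscore_event_aligned(dff, RATE, 60)
        z2, _ = zscore_event_aligned(5.0 * dff, RATE, 60)
        assert np.allclose(z1, z2, atol=1e-10)

    def test_zero_sd_flagged_invalid(self):
        dff = np.zeros((1, 1, 90))
        z, valid = zscore_event_aligned(dff, RATE, 60)
        assert not valid.any()


class TestPreprocess:
    def test_affine_invariance(self, rng):
        F = rng.normal(size=(1, 2, 120))
        a = preprocess_trace(F, RATE)
        b = preprocess_trace(3.0 * F + 11.0, RATE)
        assert np.allclose(a, b, atol=1e-10)

    def test_slow_signal_passes(self):
        t = np.arange(300) / RATE
        F = (0.5 + 0.4 * np.sin(2 * np.pi * 0.5 * t))[None, None, :]
        out = preprocess_trace(F, RATE)
        mid = slice(50, 250)
        scaled = (F[0, 0] - F.min()) / np.ptp(F)
        assert np.allclose(out[0, 0, mid], scaled[mid], atol=0.02)

    def test_10hz_attenuated_20db(self):
        t = np.arange(600) / RATE
        F = (0.5 + 0.4 * np.sin(2 * np.pi * 10 * t))[None, None, :]
        out = preprocess_trace(F, RATE)
        in_amp = np.std((F[0, 0] - F.min()) / np.ptp(F))
        out_amp = np.std(out[0, 0, 100:500] - out[0, 0, 100:500].mean())
        assert out_amp < in_amp / 10.0  # >= 20 dB

    def test_constant_trace_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="constant"):
            out = preprocess_trace(np.full((1, 1, 60), 2.0), RATE)
        assert np.allclose(out, 0.0)


class TestWindowMean:
    def test_constant_window(self):
        x = np.ones((1, 1, 90))
        assert window_mean(x, RATE, 60, (0, 1))[0, 0] == 1.0

    def test_ramp_mean_half(self):
        x = np.zeros((1, 1, 90))
        x[0, 0, 60:] = np.linspace(0, 1, 30)
        assert window_mean(x, RATE, 60, (0, 1))[0, 0] == pytest.approx(0.5, abs=1 / 30)

    def test_window_outside_recording_errors(self):
        with pytest.raises(WindowError):
            window_mean(np.ones((1, 1, 90)), RATE, 60, (5.0, 6.0))


class TestResponsiveness:
    def test_planted_activation_detected(self, rng):
        base = rng.normal(0, 1, (1, 50, 90))
        base[0, :, 60:] += 3.0
        res = responsiveness_screen(base, RATE, 60)
        assert res["direction"].iloc[0] == "activated"
        res_flip = responsiveness_screen(-base, RATE, 60)
        assert res_flip["direction"].iloc[0] == "suppressed"

    def test_zero_differences_give_p_one(self):
        res = responsiveness_screen(np.zeros((1, 10, 90)), RATE, 60)
        assert res["p_value"].iloc[0] == 1.0
        assert res["direction"].iloc[0] == "none"

    def test_too_few_trials_error(self):
        with pytest.raises(ValueError):
            responsiveness_screen(np.zeros((1, 4, 90)), RATE, 60)


class TestOnset:
    def _step_trials(self, rng, step_s, n_trials=40, snr=8.0):
        x = rng.normal(0, 1, (n_trials, 90))
        step_f = 60 + int(step_s * RATE)
        x[:, step_f:] += snr
        return x

    def test_step_onset_recovered(self, rng):
        onset = detect_onset(self._step_trials(rng, 0.2), RATE, 60)
        assert onset == pytest.approx(0.2, abs=2 / RATE)

    def test_flat_trace_undefined(self):
        # no evoked response anywhere: onset stays undefined rather than clamped
        onset = detect_onset(np.zeros((40, 90)), RATE, 60)
        assert np.isnan(onset)

    def test_earlier_step_earlier_onset(self, rng):
        early = detect_onset(self._step_trials(rng, 0.1), RATE, 60)
        late = detect_onset(self._step_trials(rng, 0.5), RATE, 60)
        assert early < late
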