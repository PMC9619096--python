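import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.signal import stft

from tonelab.dsp import (
    F0Track,
    VoicingSegmentation,
    Waveform,
    analyze,
    apply_gain_contour,
    estimate_f0,
    read_wav,
    resynthesize,
    segment_voicing,
    write_wav,
)
from tonelab.fixtures import SyllableSpec, synth_syllable

RATE = 16000


def pulse_train(f0: float, duration: float, rate: int = RATE) -> Waveform:
    phase = np.cumsum(np.full(int(duration * rate), f0)) / rate
    return Waveform((np.mod(phase, 1.0) < 0.05).astype(float), rate)


@pytest.fixture(scope="module")
def vowel():
    """A 0.5 s synthetic vowel with a known 150→300 Hz glide."""
    return synth_syllable(SyllableSpec(150, 300, 0.5, ((730, 90), (1090, 110), (2440, 170))))


@pytest.fixture(scope="module")
def flat_vowel():
    return synth_syllable(SyllableSpec(250, 250, 0.4, ((500, 90), (1000, 110), (2400, 180)),
                                       onset=0.03, noise_seed=5))


class TestEstimateF0:
    def test_pulse_train_median(self):
        track = estimate_f0(pulse_train(200.0, 1.0), 60, 400)
        voiced = track.f0[track.f0 > 0]
        assert np.median(voiced) == pytest.approx(200.0, abs=2.0)

    def test_white_noise_unvoiced(self):
        rng = np.random.default_rng(0)
        track = estimate_f0(Waveform(rng.standard_normal(RATE), RATE), 60, 400)
        assert np.all(track.f0 == 0)

    def test_glide_endpoints(self, vowel):
        track = estimate_f0(vowel, 60, 400)
        vi = np.flatnonzero(track.f0 > 0)
        assert track.f0[vi[0]] == pytest.approx(150, rel=0.05)
        assert track.f0[vi[-1]] == pytest.approx(300, rel=0.05)

    def test_deterministic(self, vowel):
        t1 = estimate_f0(vowel)
        t2 = estimate_f0(vowel)
        assert np.array_equal(t1.f0, t2.f0)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            estimate_f0(Waveform(np.ones(100), RATE), 60, 400)

    def test_band_validation(self, vowel):
        with pytest.raises(ValueError):
            estimate_f0(vowel, 400, 60)


class TestSegmentVoicing:
    def _track(self, voiced_mask, step=0.01):
        times = np.arange(len(voiced_mask)) * step
        f0 = np.where(voiced_mask, 200.0, 0.0)
        return F0Track(times, f0, step)

    def test_all_voiced_single_span(self):
        track = self._track(np.ones(80, dtype=bool))
        seg = segment_voicing(track, min_span=0.03)
        assert len(seg.spans) == 1
        a, b = seg.spans[0]
        assert a == pytest.approx(0.0, abs=0.01)
        assert b == pytest.approx(0.8, abs=0.01)

    def test_two_spans(self):
        mask = np.zeros(100, dtype=bool)
        mask[10:30] = True
        mask[50:90] = True
        seg = segment_voicing(self._track(mask), min_span=0.05)
        assert len(seg.spans) == 2

    def test_short_blip_removed(self):
        mask = np.zeros(100, dtype=bool)
        mask[40:42] = True  # 0.02 s blip
        seg = segment_voicing(self._track(mask), min_span=0.05)
        assert seg.spans == ()

    def test_negative_min_span_rejected(self):
        with pytest.raises(ValueError):
            segment_voicing(self._track(np.ones(10, dtype=bool)), min_span=-1)


class TestAnalyzeResynthesize:
    def test_silent_input_rejected(self):
        with pytest.raises(ValueError, match="silent"):
            analyze(Waveform(np.zeros(RATE) + 1e-9, RATE))

    def test_roundtrip_duration_exact(self, flat_vowel):
        track, env, voicing = analyze(flat_vowel)
        out = resynthesize(env, voicing, np.where(track.f0 > 0, track.f0, 100.0))
        assert len(out.samples) == len(flat_vowel.samples)

    def test_roundtrip_f0_within_3pct(self, vowel):
        track, env, voicing = analyze(vowel)
        out = resynthesize(env, voicing, np.where(track.f0 > 0, track.f0, 100.0))
        track2 = estimate_f0(out)
        both = (track.f0 > 0) & (track2.f0 > 0)
        assert both.sum() >= 0.9 * (track.f0 > 0).sum()
        rel = np.abs(track2.f0[both] - track.f0[both]) / track.f0[both]
        assert np.percentile(rel, 95) <= 0.03

    def test_roundtrip_voiced_log_spectral_distance(self, flat_vowel):
        """Identity resynthesis keeps voiced-frame spectra within 3 dB on average."""
        track, env, voicing = analyze(flat_vowel)
        out = resynthesize(env, voicing, np.where(track.f0 > 0, track.f0, 100.0))
        _, t, z_in = stft(flat_vowel.samples, RATE, nperseg=512)
        _, _, z_out = stft(out.samples, RATE, nperseg=512)
        lsd = []
        for i in np.flatnonzero(voicing.mask(t)):
            mi, mo = np.abs(z_in[:, i]), np.abs(z_out[:, i])
            keep = mi > mi.max() * 1e-2
            lsd.append(np.mean(np.abs(
                20 * np.log10((mo[keep] + 1e-12) / (mi[keep] + 1e-12)))))
        assert np.mean(lsd) <= 3.0

    def test_imposed_flat_300(self, flat_vowel):
        """A female-register flat 300 Hz target is realized within 3%."""
        track, env, voicing = analyze(flat_vowel)
        out = resynthesize(env, voicing, np.full_like(track.f0, 300.0))
        f0 = estimate_f0(out).f0
        assert np.median(f0[f0 > 0]) == pytest.approx(300.0, rel=0.03)

    def test_imposed_rise_100_220(self):
        """A male-register 100→220 Hz rise is realized within 5% at the endpoints."""
        male = synth_syllable(SyllableSpec(170, 170, 0.4, ((600, 90), (1100, 110), (2300, 180))))
        track, env, voicing = analyze(male)
        a, b = voicing.extent
        frac = np.clip((env.times - a) / (b - a), 0, 1)
        target = 100 + 120 * frac
        out = resynthesize(env, voicing, np.where(track.f0 > 0, target, 150.0))
        t2 = estimate_f0(out)
        vi = np.flatnonzero(t2.f0 > 0)
        slope, intercept = np.polyfit(t2.times[vi], t2.f0[vi], 1)
        assert slope * a + intercept == pytest.approx(100, rel=0.05)
        assert slope * b + intercept == pytest.approx(220, rel=0.05)

    def test_nonpositive_target_on_voiced_rejected(self, flat_vowel):
        track, env, voicing = analyze(flat_vowel)
        with pytest.raises(ValueError, match="positive"):
            resynthesize(env, voicing, np.zeros_like(track.f0))

    def test_resynthesis_noise_seeded(self, flat_vowel):
        track, env, voicing = analyze(flat_vowel)
        tgt = np.where(track.f0 > 0, track.f0, 100.0)
        a = resynthesize(env, voicing, tgt, seed=3)
        b = resynthesize(env, voicing, tgt, seed=3)
        c = resynthesize(env, voicing, tgt, seed=4)
        assert np.array_equal(a.samples, b.samples)
        assert not np.array_equal(a.samples, c.samples)


class TestGainContour:
    def test_zero_gain_identity(self, flat_vowel):
        _, _, voicing = analyze(flat_vowel)
        out = apply_gain_contour(flat_vowel, voicing, 0.0, 0.0)
        assert np.array_equal(out.samples, flat_vowel.samples)

    def test_closed_form_endpoints(self, flat_vowel):
        _, _, voicing = analyze(flat_vowel)
        out = apply_gain_contour(flat_vowel, voicing, -10.0, 10.0)
        t = np.arange(len(flat_vowel.samples)) / RATE
        idx = np.flatnonzero(voicing.mask(t))
        ratio0 = out.samples[idx[0]] / flat_vowel.samples[idx[0]]
        ratio1 = out.samples[idx[-1]] / flat_vowel.samples[idx[-1]]
        assert ratio0 == pytest.approx(10 ** (-10 / 20), rel=1e-9)
        assert ratio1 == pytest.approx(10 ** (10 / 20), rel=1e-9)

    def test_successive_ramps_cancel(self, flat_vowel):
        _, _, voicing = analyze(flat_vowel)
        out = apply_gain_contour(
            apply_gain_contour(flat_vowel, voicing, 10.0, -10.0),
            voicing, -10.0, 10.0)
        assert np.allclose(out.samples, flat_vowel.samples, atol=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(a=st.floats(-12, 12), b=st.floats(-12, 12),
           c=st.floats(-12, 12), d=st.floats(-12, 12))
    def test_gain_additivity(self, flat_vowel, a, b, c, d):
        """Applying (a,b) then (c,d) equals applying (a+c, b+d)."""
        _, _, voicing = analyze(flat_vowel)
        seq = apply_gain_contour(apply_gain_contour(flat_vowel, voicing, a, b),
                                 voicing, c, d)
        direct = apply_gain_contour(flat_vowel, voicing, a + c, b + d)
        assert np.allclose(seq.samples, direct.samples, rtol=1e-9, atol=1e-12)

    def test_empty_voicing_warns_and_passes_through(self, flat_vowel, caplog):
        with caplog.at_level("WARNING"):
            out = apply_gain_contour(flat_vowel, VoicingSegmentation(()), -10, 10)
        assert np.array_equal(out.samples, flat_vowel.samples)
        assert any("empty voicing" in r.message for r in caplog.records)

    def test_non_finite_gain_rejected(self, flat_vowel):
        _, _, voicing = analyze(flat_vowel)
        with pytest.raises(ValueError):
            apply_gain_contour(flat_vowel, voicing, np.inf, 0.0)


class TestWavIO:
    def test_pcm16_roundtrip(self, tmp_path, flat_vowel):
        path = tmp_path / "a.wav"
        write_wav(path, flat_vowel)
        back = read_wav(path)
        assert back.rate == flat_vowel.rate
        assert np.max(np.abs(back.samples - flat_vowel.samples)) < 1e-4

    def test_float32_roundtrip(self, tmp_path, flat_vowel):
        path = tmp_path / "a.wav"
        write_wav(path, flat_vowel, subtype="float32")
        back = read_wav(path)
        assert np.max(np.abs(back.samples - flat_vowel.samples)) < 1e-6


class TestWaveformValidation:
    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            Waveform(np.array([]), RATE)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            Waveform(np.array([0.0, np.nan]), RATE)

    def test_bad_rate_rejected(self):
        with pytest.raises(ValueError):
            Waveform(np.zeros(10), 0)
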