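"""Source-filter analysis/resynthesis for pitch-contour manipulation.

The engine decomposes speech into an excitation (F0 + voicing) and a
spectral envelope, then resynthesizes with an arbitrary target F0 while
keeping the envelope — hence timbre and duration — unchanged.  Voiced spans
are rendered as a harmonic bank whose per-harmonic amplitudes sample the
envelope at the new harmonic frequencies; unvoiced spans are re-rendered
from the envelope with random-phase (noise) excitation.  This is a
sinusoidal+noise scheme: no claim of waveform identity, only that F0,
spectral envelope, and duration round-trip within tolerances.

Analysis defaults: 5 ms frame step, 40 ms Hann window, F0 search band
60–400 Hz, voicing decided by normalized autocorrelation ≥ 0.45.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .contours import F0_FLOOR_HZ, F0_CEIL_HZ

__all__ = [
    "Waveform",
    "F0Track",
    "VoicingSegmentation",
    "SpectralEnvelope",
    "estimate_f0",
    "segment_voicing",
    "analyze",
    "resynthesize",
    "apply_gain_contour",
    "read_wav",
    "write_wav",
]

logger = logging.getLogger(__name__)

DEFAULT_FRAME_STEP_S = 0.005
DEFAULT_WINDOW_S = 0.040
VOICING_THRESHOLD = 0.45
DEFAULT_MIN_SPAN_S = 0.030
SILENCE_RMS = 1e-6
# frames whose local peak is below this fraction of the global peak are
# unvoiced by definition (residual formant ringing in fades is not voicing)
SILENCE_GATE_REL = 0.03
# fraction of Nyquist above which harmonics are dropped (guards aliasing)
HARMONIC_CEIL = 0.95


@dataclass(frozen=True)
class Waveform:
    """Mono audio: float samples (nominal range [−1, 1]) at ``rate`` Hz."""

    samples: np.ndarray
    rate: int

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples contain non-finite values")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))


@dataclass(frozen=True)
class F0Track:
    """Per-frame fundamental frequency; f0 == 0 marks an unvoiced frame."""

    times: np.ndarray
    f0: np.ndarray
    frame_step: float

    def __post_init__(self):
        times = np.asarray(self.times, dtype=np.float64)
        f0 = np.asarray(self.f0, dtype=np.float64)
        if times.shape != f0.shape:
            raise ValueError("times and f0 must have the same shape")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(f0 < 0):
            raise ValueError("f0 must be non-negative")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "f0", f0)

    @property
    def voiced(self) -> np.ndarray:
        return self.f0 > 0


@dataclass(frozen=True)
class VoicingSegmentation:
    """Sorted, non-overlapping (start_s, end_s) voiced intervals."""

    spans: tuple[tuple[float, float], ...]

    def __post_init__(self):
        spans = tuple((float(a), float(b)) for a, b in self.spans)
        for a, b in spans:
            if b <= a:
                raise ValueError(f"degenerate span ({a}, {b})")
        for (a0, b0), (a1, b1) in zip(spans, spans[1:]):
            if a1 < b0:
                raise ValueError("spans overlap or are unsorted")
        object.__setattr__(self, "spans", spans)

    def contains(self, t: float) -> bool:
        return any(a <= t < b for a, b in self.spans)

    def mask(self, times: np.ndarray) -> np.ndarray:
        m = np.zeros(len(times), dtype=bool)
        for a, b in self.spans:
            m |= (times >= a) & (times < b)
        return m

    @property
    def extent(self) -> tuple[float, float] | None:
        """(first voiced time, last voiced time) across all spans, or None."""
        if not self.spans:
            return None
        return self.spans[0][0], self.spans[-1][1]


@dataclass(frozen=True)
class SpectralEnvelope:
    """Per-frame magnitude envelope on a fixed frequency grid.

    Units: the value at frequency f is the time-domain amplitude a cosine at
    f would need to produce the observed windowed-spectrum level, so that
    resynthesis can place harmonics anywhere under the envelope.  For voiced
    frames the envelope interpolates measured harmonic amplitudes; for
    unvoiced frames it is the normalized magnitude spectrum itself.
    """

    times: np.ndarray
    freqs: np.ndarray
    envelope: np.ndarray  # shape (n_frames, n_freqs), values >= 0
    rate: int
    n_samples: int
    window_s: float = DEFAULT_WINDOW_S

    def __post_init__(self):
        env = np.asarray(self.envelope, dtype=np.float64)
        if env.shape != (len(self.times), len(self.freqs)):
            raise ValueError("envelope shape must be (n_frames, n_freqs)")
        if np.any(env < 0):
            raise ValueError("envelope values must be non-negative")
        object.__setattr__(self, "envelope", env)
        object.__setattr__(self, "times", np.asarray(self.times, dtype=np.float64))
        object.__setattr__(self, "freqs", np.asarray(self.freqs, dtype=np.float64))


# ---------------------------------------------------------------------------
# WAV I/O

def read_wav(path: str | Path) -> Waveform:
    """Read a mono or stereo WAV (PCM16/32 or float); stereo is averaged to mono."""
    rate, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if data.dtype.kind == "i":
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    elif data.dtype.kind == "u":  # uint8 WAV
        data = (data.astype(np.float64) - 128.0) / 128.0
    else:
        data = data.astype(np.float64)
    return Waveform(data, int(rate))


def write_wav(path: str | Path, wave: Waveform, subtype: str = "pcm16") -> None:
    """Write mono WAV as 16-bit PCM (default) or float32."""
    if subtype == "pcm16":
        clipped = np.clip(wave.samples, -1.0, 1.0)
        wavfile.write(str(path), wave.rate, (clipped * 32767.0).astype(np.int16))
    elif subtype == "float32":
        wavfile.write(str(path), wave.rate, wave.samples.astype(np.float32))
    else:
        raise ValueError(f"unsupported subtype {subtype!r}")


# ---------------------------------------------------------------------------
# framing helpers

def _frame_signal(x: np.ndarray, rate: int, frame_step: float, window_s: float):
    """Return (frames, centers_s). Frames are centered, zero-padded at edges."""
    flen = int(round(window_s * rate))
    flen += flen % 2  # even length
    hop = max(1, int(round(frame_step * rate)))
    half = flen // 2
    padded = np.pad(x, (half, half))
    n_frames = 1 + (len(x) - 1) // hop
    idx = np.arange(flen)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = padded[idx]
    centers = hop * np.arange(n_frames) / rate
    return frames, centers


def _nac_f0_frames(frames: np.ndarray, rate: int, fmin: float, fmax: float,
                   threshold: float = VOICING_THRESHOLD):
    """Normalized-autocorrelation F0 per frame (vectorized over frames).

    r[tau] = sum x[n] x[n+tau] / sqrt(sum_{n<L-tau} x[n]^2 * sum_{n>=tau} x[n]^2);
    candidate peaks compete on r minus a small octave cost proportional to
    log2(lag), which resolves the period ambiguity of pulse-like excitation
    (sub-harmonic peaks lose unless clearly stronger) without inviting
    octave-up errors; the winner is refined by parabolic interpolation.
    """
    octave_cost = 0.02
    n_frames, flen = frames.shape
    lag_min = max(2, int(np.floor(rate / fmax)))
    lag_max = int(np.ceil(rate / fmin))
    if lag_max >= flen - 2:
        raise ValueError(
            f"analysis window ({flen} samples) too short for fmin={fmin} Hz"
        )
    nfft = 1 << int(np.ceil(np.log2(2 * flen)))
    spec = np.fft.rfft(frames, nfft, axis=1)
    raw = np.fft.irfft(spec * np.conj(spec), nfft, axis=1)[:, : lag_max + 2]

    csum = np.concatenate(
        [np.zeros((n_frames, 1)), np.cumsum(frames**2, axis=1)], axis=1
    )
    total = csum[:, -1]
    taus = np.arange(lag_max + 2)
    # energy of x[0:L-tau] and x[tau:L]
    e_head = csum[:, flen - taus.clip(max=flen)]
    e_tail = total[:, None] - csum[:, taus.clip(max=flen)]
    denom = np.sqrt(e_head * e_tail)
    with np.errstate(invalid="ignore", divide="ignore"):
        nac = np.where(denom > 0, raw / denom, 0.0)
    nac = np.clip(nac, -1.0, 1.0)

    f0 = np.zeros(n_frames)
    strength = np.zeros(n_frames)
    frame_rms = np.sqrt(np.maximum(total, 0) / flen)
    frame_peak = np.abs(frames).max(axis=1)
    peak_gate = SILENCE_GATE_REL * frame_peak.max()
    band = nac[:, lag_min : lag_max + 1]
    for i in range(n_frames):
        if frame_rms[i] < SILENCE_RMS or frame_peak[i] < peak_gate:
            continue
        seg = band[i]
        # local maxima within the search band
        interior = (seg[1:-1] >= seg[:-2]) & (seg[1:-1] >= seg[2:])
        peaks = np.flatnonzero(interior) + 1
        if peaks.size == 0:
            continue
        if seg[peaks].max() < threshold:
            continue
        cand = peaks[seg[peaks] >= threshold]
        scores = seg[cand] - octave_cost * np.log2((cand + lag_min) / lag_min)
        k = cand[int(np.argmax(scores))]
        tau = k + lag_min
        # parabolic refinement around the integer lag
        y0, y1, y2 = nac[i, tau - 1], nac[i, tau], nac[i, tau + 1]
        denom_p = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom_p if abs(denom_p) > 1e-12 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
        f0_i = rate / (tau + delta)
        if fmin <= f0_i <= fmax:
            f0[i] = f0_i
            strength[i] = y1
    return f0, strength


def _despike_track(f0: np.ndarray, halfwidth: int = 2,
                   max_octave_jump: float = 0.3,
                   edge_jump: float = 0.1) -> np.ndarray:
    """Drop isolated voiced frames and local pitch-continuity outliers.

    Frames at voicing edges can contain less than two glottal cycles plus
    formant ringing, which yields sporadic spurious estimates.  A frame is
    relabelled unvoiced when its f0 deviates from the voiced neighbourhood
    median by more than 0.3 octave, when it has no voiced neighbours at
    all, or — for the first/last frame of a voiced run, the least reliable
    positions — when it jumps more than 0.1 octave from the adjacent
    interior frame.  Real intonation moves well under 0.05 octave per
    frame step, so these thresholds cannot clip genuine contours.
    """
    out = f0.copy()
    for _ in range(3):  # a removed spike may expose its partner
        voiced = out > 0
        cleaned = out.copy()
        for i in np.flatnonzero(voiced):
            lo, hi = max(0, i - halfwidth), min(len(out), i + halfwidth + 1)
            neigh = [out[j] for j in range(lo, hi) if j != i and out[j] > 0]
            if not neigh:
                cleaned[i] = 0.0
            elif abs(np.log2(out[i] / np.median(neigh))) > max_octave_jump:
                cleaned[i] = 0.0
            else:
                left = out[i - 1] if i > 0 else 0.0
                right = out[i + 1] if i + 1 < len(out) else 0.0
                if left <= 0 < right and abs(np.log2(out[i] / right)) > edge_jump:
                    cleaned[i] = 0.0  # run onset inconsistent with interior
                elif right <= 0 < left and abs(np.log2(out[i] / left)) > edge_jump:
                    cleaned[i] = 0.0  # run offset inconsistent with interior
        if np.array_equal(cleaned, out):
            break
        out = cleaned
    return out


def estimate_f0(wave: Waveform, fmin: float = F0_FLOOR_HZ, fmax: float = F0_CEIL_HZ,
                frame_step: float = DEFAULT_FRAME_STEP_S,
                window_s: float = DEFAULT_WINDOW_S,
                despike: bool = True) -> F0Track:
    """Track F0 by normalized autocorrelation; unvoiced frames get f0 = 0.

    Deterministic for fixed input and parameters.  ``despike`` applies the
    neighbourhood-median continuity filter (see :func:`_despike_track`).
    """
    if not (0 < fmin < fmax < wave.rate / 2):
        raise ValueError(f"need 0 < fmin < fmax < rate/2, got ({fmin}, {fmax})")
    if wave.duration < 2.0 / fmin:
        raise ValueError(
            f"signal too short ({wave.duration:.3f} s) to estimate F0 down to {fmin} Hz"
        )
    window_s = max(window_s, 2.2 / fmin)
    frames, centers = _frame_signal(wave.samples, wave.rate, frame_step, window_s)
    f0, _ = _nac_f0_frames(frames, wave.rate, fmin, fmax)
    if despike:
        f0 = _despike_track(f0)
    return F0Track(centers, f0, frame_step)


def segment_voicing(track: F0Track, min_span: float = DEFAULT_MIN_SPAN_S) -> VoicingSegmentation:
    """Maximal runs of voiced frames, dropping runs shorter than ``min_span``."""
    if min_span < 0:
        raise ValueError("min_span must be non-negative")
    voiced = track.voiced
    spans: list[tuple[float, float]] = []
    half = track.frame_step / 2
    i = 0
    n = len(voiced)
    while i < n:
        if voiced[i]:
            j = i
            while j + 1 < n and voiced[j + 1]:
                j += 1
            start = max(0.0, track.times[i] - half)
            end = track.times[j] + half
            if end - start >= min_span:
                spans.append((start, end))
            i = j + 1
        else:
            i += 1
    return VoicingSegmentation(tuple(spans))


def _harmonic_amplitudes(frame: np.ndarray, window: np.ndarray, rate: int,
                         freqs_hz: np.ndarray) -> np.ndarray:
    """Amplitude of a cosine at each frequency, measured through the window."""
    n = np.arange(len(frame))
    wf = frame * window
    basis = np.exp(-2j * np.pi * np.outer(freqs_hz, n) / rate)
    return 2.0 * np.abs(basis @ wf) / window.sum()


def analyze(wave: Waveform, fmin: float = F0_FLOOR_HZ, fmax: float = F0_CEIL_HZ,
            frame_step: float = DEFAULT_FRAME_STEP_S,
            window_s: float = DEFAULT_WINDOW_S,
            min_span: float = DEFAULT_MIN_SPAN_S,
            ) -> tuple[F0Track, SpectralEnvelope, VoicingSegmentation]:
    """Decompose into excitation (F0 + voicing) and spectral envelope.

    The three products share one frame grid.  Voiced-frame envelopes are
    linear interpolations of the measured harmonic amplitudes across
    frequency; unvoiced-frame envelopes are the windowed magnitude spectrum.
    """
    if wave.rms() < SILENCE_RMS:
        raise ValueError("input is silent (RMS < 1e-6); nothing to analyze")
    track = estimate_f0(wave, fmin, fmax, frame_step, window_s)
    voicing = segment_voicing(track, min_span)
    window_s_eff = max(window_s, 2.2 / fmin)

    frames, centers = _frame_signal(wave.samples, wave.rate, frame_step, window_s_eff)
    flen = frames.shape[1]
    window = np.hanning(flen)
    wsum = window.sum()
    nfft = 1 << int(np.ceil(np.log2(flen)))
    freqs = np.fft.rfftfreq(nfft, 1.0 / wave.rate)

    # voicing mask on the frame grid (segmentation may have pruned blips)
    vmask = voicing.mask(centers) & track.voiced
    env = np.empty((len(centers), len(freqs)))
    spec_mag = 2.0 * np.abs(np.fft.rfft(frames * window, nfft, axis=1)) / wsum
    nyq = wave.rate / 2
    for i in range(len(centers)):
        if vmask[i]:
            f0_i = track.f0[i]
            k_max = int(np.floor(HARMONIC_CEIL * nyq / f0_i))
            harm_f = f0_i * np.arange(1, k_max + 1)
            amps = _harmonic_amplitudes(frames[i], window, wave.rate, harm_f)
            # anchor at DC and Nyquist so interpolation decays off the comb
            xs = np.concatenate([[0.0], harm_f, [nyq]])
            ys = np.concatenate([[amps[0]], amps, [0.0]])
            env[i] = np.interp(freqs, xs, ys)
        else:
            env[i] = spec_mag[i]
    envelope = SpectralEnvelope(centers, freqs, env, wave.rate,
                                len(wave.samples), window_s_eff)
    return track, envelope, voicing


def _target_on_samples(times: np.ndarray, values: np.ndarray, n: int, rate: int) -> np.ndarray:
    t = np.arange(n) / rate
    return np.interp(t, times, values)


def resynthesize(env: SpectralEnvelope, voicing: VoicingSegmentation,
                 target_f0: np.ndarray, seed: int = 0) -> Waveform:
    """Render audio from the envelope with a new excitation F0.

    ``target_f0`` gives per-frame target F0 in Hz on the analysis frame grid;
    it must be positive on voiced frames.  Output duration equals the
    analyzed input's sample count exactly.  Voiced spans are a harmonic bank
    with amplitudes sampled from the envelope at the target harmonic
    frequencies; unvoiced regions are random-phase noise shaped by the
    envelope (seeded, hence reproducible).
    """
    target_f0 = np.asarray(target_f0, dtype=np.float64)
    if target_f0.shape != env.times.shape:
        raise ValueError("target_f0 must be defined on the analysis frame grid")
    rate, n_out = env.rate, env.n_samples
    vmask = voicing.mask(env.times)
    if np.any(target_f0[vmask] <= 0):
        raise ValueError("target F0 must be positive on voiced frames")

    out = np.zeros(n_out)
    t_samp = np.arange(n_out) / rate
    nyq = rate / 2

    # --- voiced component: per-span harmonic bank -------------------------
    for a, b in voicing.spans:
        i0, i1 = int(np.floor(a * rate)), min(n_out, int(np.ceil(b * rate)))
        if i1 <= i0:
            continue
        idx = np.arange(i0, i1)
        span_frames = np.flatnonzero((env.times >= a) & (env.times < b))
        if span_frames.size == 0:
            continue
        ft = env.times[span_frames]
        fv = target_f0[span_frames]
        f0_s = np.interp(t_samp[idx], ft, fv)
        k_max = int(np.floor(HARMONIC_CEIL * nyq / fv.max()))
        k_max = max(k_max, 1)
        ks = np.arange(1, k_max + 1)
        # per-frame harmonic amplitudes from the envelope at k * f0_target
        amps_f = np.empty((span_frames.size, k_max))
        for j, fi in enumerate(span_frames):
            harm_f = ks * fv[j]
            amps_f[j] = np.interp(harm_f, env.freqs, env.envelope[fi])
            amps_f[j, harm_f > HARMONIC_CEIL * nyq] = 0.0
        # interpolate amplitudes frame→sample (linear in time)
        pos = np.interp(t_samp[idx], ft, np.arange(span_frames.size, dtype=float))
        lo = np.floor(pos).astype(int)
        hi = np.minimum(lo + 1, span_frames.size - 1)
        w = (pos - lo)[:, None]
        amps_s = amps_f[lo] * (1 - w) + amps_f[hi] * w  # (n_span, k_max)
        phase = 2 * np.pi * np.cumsum(f0_s) / rate
        sig = np.einsum("sk,sk->s", amps_s, np.cos(np.outer(phase, ks)))
        # short raised-cosine edges to avoid clicks at span boundaries
        edge = min(int(0.005 * rate), sig.size // 2)
        if edge > 0:
            ramp = 0.5 * (1 - np.cos(np.pi * np.arange(edge) / edge))
            sig[:edge] *= ramp
            sig[-edge:] *= ramp[::-1]
        out[idx] += sig

    # --- unvoiced component: envelope-shaped noise, power-calibrated OLA --
    rng = np.random.default_rng(seed)
    flen = int(round(env.window_s * rate))
    flen += flen % 2
    half = flen // 2
    window = np.hanning(flen)
    wsum = window.sum()
    w2sum = (window**2).sum()
    nfft = (len(env.freqs) - 1) * 2
    acc = np.zeros(n_out + 2 * flen)
    norm = np.zeros(n_out + 2 * flen)
    for i, tc in enumerate(env.times):
        if vmask[i]:
            continue
        mag = env.envelope[i]
        # frame power implied by the envelope: env_b = 2|Y_b|/wsum with Y the
        # windowed-frame spectrum; Parseval gives E[x^2] for the raw frame
        y2 = (mag * wsum / 2.0) ** 2
        p_y = (y2[0] + 2.0 * y2[1:-1].sum() + y2[-1]) / nfft
        p_x = p_y / w2sum
        if p_x < SILENCE_RMS**2:
            continue
        u = rng.standard_normal(flen)
        shaped = np.fft.irfft(np.fft.rfft(u, nfft) * mag, nfft)[:flen]
        srms = np.sqrt(np.mean(shaped**2))
        if srms > 0:
            shaped *= np.sqrt(p_x) / srms
        start = int(round(tc * rate)) - half + flen  # acc is padded by flen
        acc[start : start + flen] += shaped * window
        norm[start : start + flen] += window**2
    ok = norm > 1e-8
    acc[ok] /= np.sqrt(norm[ok])
    # noise only outside voiced spans (binary excitation model)
    unvoiced_samples = ~voicing.mask(t_samp)
    out[unvoiced_samples] += acc[flen : flen + n_out][unvoiced_samples]
    return Waveform(out, rate)


def apply_gain_contour(wave: Waveform, voicing: VoicingSegmentation,
                       gain_start: float, gain_end: float) -> Waveform:
    """Impose a linear dB ramp over the voiced portion of the signal.

    The ramp is anchored at the first and last voiced sample across all
    spans; voiced sample n is scaled by 10**(g(n)/20) with g linear in time.
    Unvoiced samples are untouched.  (0, 0) is the identity.
    """
    if not (np.isfinite(gain_start) and np.isfinite(gain_end)):
        raise ValueError("gains must be finite")
    extent = voicing.extent
    if extent is None:
        logger.warning("apply_gain_contour: empty voicing; returning input unchanged")
        return wave
    out = wave.samples.copy()
    t_samp = np.arange(len(out)) / wave.rate
    mask = voicing.mask(t_samp)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        logger.warning("apply_gain_contour: no voiced samples; returning input unchanged")
        return wave
    # anchor the ramp on the actual first/last voiced sample
    if idx[-1] > idx[0]:
        frac = (idx - idx[0]) / (idx[-1] - idx[0])
    else:
        frac = np.zeros(idx.size)
    g_db = gain_start + frac * (gain_end - gain_start)
    out[mask] *= 10.0 ** (g_db / 20.0)
    return Waveform(out, wave.rate)
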