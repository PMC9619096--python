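"""Synthetic disyllabic word generator standing in for studio recordings.

Each word is two formant-synthesized syllables separated by a silent gap.
The source is a Rosenberg-style glottal pulse train with a linear F0 glide,
filtered through a cascade of second-order formant resonators; an optional
unvoiced noise burst models a plosive/fricative onset.  The second syllable
always carries Tone 1 (flat F0: ≈250 Hz female, ≈170 Hz male) so that the
pitch/loudness manipulation pipeline has a well-defined target syllable.
Intelligible Mandarin phonetics and naturalness are explicit non-goals —
the fixtures only need to be analyzable speech-like signals with known
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .dsp import Waveform

__all__ = ["SyllableSpec", "WordFixture", "synth_syllable", "make_word_set"]

DEFAULT_RATE = 16000
EDGE_FADE_S = 0.020
TONE1_F0 = {"female": 250.0, "male": 170.0}

# (F1, F2, F3) centers and bandwidths for a handful of vowel-like timbres
_VOWELS = {
    "a": ((730, 90), (1090, 110), (2440, 170)),
    "i": ((390, 80), (1990, 120), (2550, 180)),
    "u": ((380, 80), (940, 100), (2300, 170)),
    "o": ((500, 90), (1000, 110), (2400, 180)),
    "e": ((530, 90), (1840, 120), (2480, 180)),
}


@dataclass(frozen=True)
class SyllableSpec:
    """Parameters of one synthetic syllable (voiced vowel, optional onset burst)."""

    f0_start: float
    f0_end: float
    duration: float  # voiced duration, s
    formants: tuple[tuple[float, float], ...]  # (center Hz, bandwidth Hz)
    onset: float = 0.0  # noise-burst duration, s (0 = none)
    amp: float = 0.3
    noise_seed: int = 0

    def __post_init__(self):
        if self.duration <= 0.05:
            raise ValueError("voiced duration must exceed 50 ms")
        if self.f0_start <= 0 or self.f0_end <= 0:
            raise ValueError("F0 endpoints must be positive")


@dataclass(frozen=True)
class WordFixture:
    """A disyllable: two syllable specs, a silent gap, and tone annotation."""

    word_id: str
    speaker: str
    syllables: tuple[SyllableSpec, ...]
    tones: tuple[int, ...]
    gap: float = 0.080
    lead: float = 0.050

    def __post_init__(self):
        if len(self.syllables) != len(self.tones):
            raise ValueError("one tone per syllable required")
        if 1 not in self.tones:
            raise ValueError("a Di-style word needs at least one Tone-1 syllable")

    def render(self, rate: int = DEFAULT_RATE) -> Waveform:
        """Deterministically synthesize the full word."""
        pieces = [np.zeros(int(round(self.lead * rate)))]
        for i, spec in enumerate(self.syllables):
            pieces.append(synth_syllable(spec, rate).samples)
            if i < len(self.syllables) - 1:
                pieces.append(np.zeros(int(round(self.gap * rate))))
        pieces.append(np.zeros(int(round(self.lead * rate))))
        return Waveform(np.concatenate(pieces), rate)

    def annotation(self, rate: int = DEFAULT_RATE) -> list[dict]:
        """Per-syllable segments [{start, end, tone}] whose cut points lie in silence.

        Each segment extends halfway into the adjacent gaps, so slicing at the
        boundaries never cuts through voiced material.
        """
        lead_n = int(round(self.lead * rate))
        gap_n = int(round(self.gap * rate))
        syl_n = [int(round(s.onset * rate)) + int(round(s.duration * rate))
                 for s in self.syllables]
        n = len(self.syllables)
        total_n = 2 * lead_n + (n - 1) * gap_n + sum(syl_n)
        segs = []
        cursor = 0  # start of this segment, in samples
        pos = lead_n  # start of this syllable's sound
        for i in range(n):
            sound_end = pos + syl_n[i]
            end = sound_end + (gap_n // 2 if i < n - 1 else lead_n)
            if i == n - 1:
                end = total_n
            segs.append({"start": cursor / rate, "end": end / rate,
                         "tone": self.tones[i]})
            cursor = end
            pos = sound_end + gap_n
        return segs


def _rosenberg_pulse_train(f0_inst: np.ndarray, rate: int) -> np.ndarray:
    """Glottal flow derivative for an instantaneous-F0 trajectory.

    Rosenberg model: flow opens over 40% and closes over 20% of each cycle;
    the derivative of the flow is used as the excitation (spectrally richer,
    as in real voicing).
    """
    phase = np.cumsum(f0_inst) / rate
    phi = np.mod(phase, 1.0)
    to, tc = 0.40, 0.20
    flow = np.zeros_like(phi)
    opening = phi < to
    closing = (phi >= to) & (phi < to + tc)
    flow[opening] = 0.5 * (1 - np.cos(np.pi * phi[opening] / to))
    flow[closing] = np.cos(0.5 * np.pi * (phi[closing] - to) / tc)
    deriv = np.diff(flow, prepend=flow[0])
    return deriv


def _formant_filter(x: np.ndarray, formants, rate: int) -> np.ndarray:
    """Cascade of unity-peak-gain second-order resonators."""
    y = x
    for fc, bw in formants:
        if fc >= rate / 2:
            raise ValueError(f"formant {fc} Hz at or above Nyquist ({rate/2} Hz)")
        r = np.exp(-np.pi * bw / rate)
        theta = 2 * np.pi * fc / rate
        a = np.array([1.0, -2.0 * r * np.cos(theta), r * r])
        # normalize so the resonator has unit gain at its center frequency
        w, h = sps.freqz([1.0], a, worN=[theta], fs=2 * np.pi)
        y = sps.lfilter([1.0 / np.abs(h[0])], a, y)
    return y


def synth_syllable(spec: SyllableSpec, rate: int = DEFAULT_RATE) -> Waveform:
    """Render one syllable: optional noise burst then a voiced formant vowel."""
    n_voiced = int(round(spec.duration * rate))
    f0_inst = np.linspace(spec.f0_start, spec.f0_end, n_voiced)
    source = _rosenberg_pulse_train(f0_inst, rate)
    voiced = _formant_filter(source, spec.formants, rate)
    fade = min(int(EDGE_FADE_S * rate), n_voiced // 4)
    envelope = np.ones(n_voiced)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(fade) / fade))
    envelope[:fade] = ramp
    envelope[-fade:] = ramp[::-1]
    voiced *= envelope
    peak = np.max(np.abs(voiced))
    if peak > 0:
        voiced *= spec.amp / peak

    if spec.onset > 0:
        n_onset = int(round(spec.onset * rate))
        rng = np.random.default_rng(spec.noise_seed)
        # broadband high-frequency burst (plosive-like); keeping it out of
        # the F0 search band avoids narrowband ringing that mimics voicing
        sos = sps.butter(4, 2500, "highpass", fs=rate, output="sos")
        burst = sps.sosfilt(sos, rng.standard_normal(n_onset))
        bfade = min(int(0.005 * rate), n_onset // 2)
        if bfade > 0:
            bramp = 0.5 * (1 - np.cos(np.pi * np.arange(bfade) / bfade))
            burst[:bfade] *= bramp
            burst[-bfade:] *= bramp[::-1]
        bpeak = np.max(np.abs(burst))
        if bpeak > 0:
            burst *= 0.3 * spec.amp / bpeak
        samples = np.concatenate([burst, voiced])
    else:
        samples = voiced
    return Waveform(samples, rate)


def make_word_set(n_words: int, gender: str, seed: int,
                  rate: int = DEFAULT_RATE) -> list[WordFixture]:
    """Generate ``n_words`` reproducible disyllables for one speaker.

    The first syllable carries a non-manipulated tone (2 or 4, with a
    natural rising/falling glide in the speaker's register); the second is
    always Tone 1, flat at ≈250 Hz (female) / ≈170 Hz (male), which is the
    syllable the corpus builder will resynthesize.  Male fixtures stay
    within 80–220 Hz, female within 180–320 Hz.
    """
    if n_words < 1:
        raise ValueError("n_words must be >= 1")
    if gender not in TONE1_F0:
        raise ValueError(f"unknown gender {gender!r}")
    rng = np.random.default_rng(seed)
    vowel_names = sorted(_VOWELS)
    base_t1 = TONE1_F0[gender]
    words = []
    for w in range(n_words):
        tone1 = int(rng.choice([2, 4]))
        if gender == "female":
            lo, hi = 190.0, 300.0
        else:
            lo, hi = 110.0, 210.0
        a = float(rng.uniform(lo, lo + 0.3 * (hi - lo)))
        b = float(rng.uniform(hi - 0.3 * (hi - lo), hi))
        f0a, f0b = (a, b) if tone1 == 2 else (b, a)
        v1, v2 = rng.choice(vowel_names, size=2, replace=True)
        syl1 = SyllableSpec(
            f0_start=f0a, f0_end=f0b,
            duration=float(rng.uniform(0.25, 0.35)),
            formants=_VOWELS[str(v1)],
            onset=float(rng.uniform(0.02, 0.05)),
            noise_seed=int(rng.integers(0, 2**31 - 1)),
        )
        t1_f0 = base_t1 + float(rng.uniform(-10, 10))
        syl2 = SyllableSpec(
            f0_start=t1_f0, f0_end=t1_f0,
            duration=float(rng.uniform(0.28, 0.38)),
            formants=_VOWELS[str(v2)],
            onset=float(rng.uniform(0.0, 0.04)),
            noise_seed=int(rng.integers(0, 2**31 - 1)),
        )
        words.append(WordFixture(
            word_id=f"w{w + 1:02d}", speaker=gender,
            syllables=(syl1, syl2), tones=(tone1, 1),
        ))
    return words
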