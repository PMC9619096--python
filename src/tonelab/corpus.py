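"""Factorial cue-dissociated corpus builder.

Every Tone-1 syllable of every base word is resynthesized with each of the
nine pitch contours, then amplitude-modulated with each of the three
loudness contours, yielding words × speakers × 9 × 3 tokens.  When the
pitch and loudness categories agree the token is labelled "Cov"
(covarying, 1/3 of tokens); otherwise "Conf" (conflicting).  All tokens
are RMS-normalized so overall level carries no cue.

Non-Tone-1 syllables pass through analysis/resynthesis with their measured
F0 (identity manipulation) so every syllable in the corpus shares the same
processing artifacts — this avoids a processed-vs-natural confound.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dsp
from .contours import (
    ContourCategory,
    LoudnessContourSpec,
    PitchContourSpec,
    builtin_loudness_specs,
    builtin_pitch_specs,
    tone_of,
)
from .dsp import Waveform
from .fixtures import WordFixture

__all__ = [
    "Recording",
    "StimulusToken",
    "CorpusManifest",
    "label_congruence",
    "normalize_rms",
    "build_corpus",
    "recordings_from_fixtures",
    "verify_token_f0",
]

logger = logging.getLogger(__name__)

DEFAULT_RMS_TARGET = 0.05


@dataclass(frozen=True)
class Recording:
    """One base disyllable: audio plus per-syllable segments [{start, end, tone}]."""

    word_id: str
    speaker: str
    wave: Waveform
    segments: tuple[dict, ...]

    def __post_init__(self):
        object.__setattr__(self, "segments", tuple(dict(s) for s in self.segments))
        dur = self.wave.duration
        for seg in self.segments:
            if not (0 <= seg["start"] < seg["end"] <= dur + 1e-6):
                raise ValueError(
                    f"{self.word_id}/{self.speaker}: segment {seg} outside signal"
                )


@dataclass(frozen=True)
class StimulusToken:
    """One resynthesized corpus token and its factorial-design labels."""

    token_id: str
    word_id: str
    speaker: str
    pitch_spec: PitchContourSpec
    loudness_spec: LoudnessContourSpec
    rms: float
    audio_path: str | None = None
    manip_spans: tuple[tuple[float, float], ...] = ()

    @property
    def pitch_tone(self) -> int:
        return tone_of(self.pitch_spec.category)

    @property
    def loudness_category(self) -> ContourCategory:
        return self.loudness_spec.category

    @property
    def congruence(self) -> str:
        return label_congruence(self.pitch_spec.category, self.loudness_spec.category)


@dataclass
class CorpusManifest:
    """The factorial token table (words × speakers × 9 pitch × 3 loudness)."""

    tokens: list[StimulusToken]
    rms_target: float
    build_seed: int

    def __post_init__(self):
        keys = [(t.word_id, t.speaker, t.pitch_spec.category.value,
                 t.pitch_spec.index, t.loudness_spec.category.value)
                for t in self.tokens]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate token keys in manifest")

    def __len__(self) -> int:
        return len(self.tokens)

    def by_id(self, token_id: str) -> StimulusToken:
        return self._index()[token_id]

    def _index(self) -> dict[str, StimulusToken]:
        if not hasattr(self, "_idx"):
            self._idx = {t.token_id: t for t in self.tokens}
        return self._idx

    @property
    def token_ids(self) -> list[str]:
        return [t.token_id for t in self.tokens]

    def count(self, congruence: str | None = None) -> int:
        if congruence is None:
            return len(self.tokens)
        return sum(t.congruence == congruence for t in self.tokens)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for t in self.tokens:
            rows.append({
                "token_id": t.token_id,
                "word_id": t.word_id,
                "speaker": t.speaker,
                "pitch_start_hz": t.pitch_spec.start_hz,
                "pitch_end_hz": t.pitch_spec.end_hz,
                "pitch_cat": t.pitch_spec.category.value,
                "pitch_tone": t.pitch_tone,
                "loud_start_db": t.loudness_spec.start_db,
                "loud_end_db": t.loudness_spec.end_db,
                "loud_cat": t.loudness_spec.category.value,
                "congruence": t.congruence,
                "rms": t.rms,
                "path": t.audio_path or "",
            })
        return pd.DataFrame(rows)

    def save(self, path: str | Path) -> None:
        """Write manifest.csv plus a JSON sidecar with full specs."""
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        sidecar = {
            "rms_target": self.rms_target,
            "build_seed": self.build_seed,
            "tokens": {
                t.token_id: {
                    "pitch_spec": t.pitch_spec.to_dict(),
                    "loudness_spec": t.loudness_spec.to_dict(),
                    "manip_spans": [list(s) for s in t.manip_spans],
                }
                for t in self.tokens
            },
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "CorpusManifest":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        tokens = []
        for _, row in df.iterrows():
            side = sidecar["tokens"][row.token_id]
            ps = side["pitch_spec"]
            ls = side["loudness_spec"]
            tokens.append(StimulusToken(
                token_id=row.token_id, word_id=row.word_id, speaker=row.speaker,
                pitch_spec=PitchContourSpec(ps["start_hz"], ps["end_hz"],
                                            ContourCategory(ps["category"]),
                                            ps["speaker_gender"], ps["index"]),
                loudness_spec=LoudnessContourSpec(ls["start_db"], ls["end_db"],
                                                  ContourCategory(ls["category"])),
                rms=float(row.rms),
                audio_path=row.path if isinstance(row.path, str) and row.path else None,
                manip_spans=tuple(tuple(s) for s in side["manip_spans"]),
            ))
        return cls(tokens, float(sidecar["rms_target"]), int(sidecar["build_seed"]))


def label_congruence(pitch_cat: ContourCategory, loud_cat: ContourCategory) -> str:
    """"Cov" when the pitch and loudness contour categories agree, else "Conf"."""
    return "Cov" if ContourCategory(pitch_cat) is ContourCategory(loud_cat) else "Conf"


def normalize_rms(waves: list[Waveform],
                  target_rms: float = DEFAULT_RMS_TARGET,
                  names: list[str] | None = None) -> list[Waveform]:
    """Scale each waveform to the target RMS; warn if scaling causes clipping."""
    out = []
    for i, w in enumerate(waves):
        name = names[i] if names else f"#{i}"
        rms = w.rms()
        if rms < dsp.SILENCE_RMS:
            raise ValueError(f"token {name} is silent; cannot normalize RMS")
        scaled = w.samples * (target_rms / rms)
        n_clip = int(np.sum(np.abs(scaled) > 1.0))
        if n_clip:
            warnings.warn(f"token {name}: {n_clip} samples clip after normalization")
        out.append(Waveform(scaled, w.rate))
    return out


def recordings_from_fixtures(fixtures: list[WordFixture],
                             rate: int = 16000) -> list[Recording]:
    """Render synthetic word fixtures into corpus-builder input recordings."""
    return [
        Recording(f.word_id, f.speaker, f.render(rate), tuple(f.annotation(rate)))
        for f in fixtures
    ]


def _contour_target(track: "dsp.F0Track", voicing: "dsp.VoicingSegmentation",
                    spec: PitchContourSpec) -> np.ndarray:
    """Per-frame target F0: the contour anchored on the voiced extent.

    Unvoiced frames keep the (positive-filled) measured F0; they are never
    rendered harmonically, the value only keeps interpolation well-defined.
    """
    extent = voicing.extent
    t0, t1 = extent
    frac = np.clip((track.times - t0) / max(t1 - t0, 1e-9), 0.0, 1.0)
    contour = spec.start_hz + frac * (spec.end_hz - spec.start_hz)
    fallback = np.where(track.f0 > 0, track.f0, np.median(contour))
    return np.where(voicing.mask(track.times), contour, fallback)


def build_corpus(recordings: list[Recording],
                 pitch_grids: dict[str, list[PitchContourSpec]] | None = None,
                 loudness_grid: list[LoudnessContourSpec] | None = None,
                 rms_target: float = DEFAULT_RMS_TARGET,
                 seed: int = 0,
                 out_dir: str | Path | None = None,
                 ) -> tuple[CorpusManifest, dict[str, Waveform]]:
    """Build the full factorial corpus from base recordings.

    Returns the manifest and the token audio keyed by token id.  When
    ``out_dir`` is given, 16-bit PCM WAVs and ``manifest.csv`` (+ JSON
    sidecar) are written there.  Words with missing or invalid annotation
    are skipped with a logged report, not fatal.
    """
    if pitch_grids is None:
        pitch_grids = {}
    if loudness_grid is None:
        loudness_grid = builtin_loudness_specs()

    tokens: list[StimulusToken] = []
    audio: dict[str, Waveform] = {}
    skipped: list[str] = []

    for rec_i, rec in enumerate(recordings):
        key = f"{rec.word_id}_{rec.speaker}"
        if not rec.segments:
            logger.error("recording %s has no syllable annotation; skipped", key)
            skipped.append(key)
            continue
        if not any(seg["tone"] == 1 for seg in rec.segments):
            logger.error("recording %s has no Tone-1 syllable; skipped", key)
            skipped.append(key)
            continue
        pitch_specs = pitch_grids.get(rec.speaker) or builtin_pitch_specs(rec.speaker)

        rate = rec.wave.rate
        # analyze every syllable once; identity-resynthesize non-Tone-1 ones
        try:
            syllables = []
            for si, seg in enumerate(rec.segments):
                i0 = int(round(seg["start"] * rate))
                i1 = int(round(seg["end"] * rate))
                piece = Waveform(rec.wave.samples[i0:i1], rate)
                track, env, voicing = dsp.analyze(piece)
                if seg["tone"] == 1 and voicing.extent is None:
                    raise ValueError("Tone-1 syllable has no voiced span")
                syllables.append((seg, i0, i1, track, env, voicing))
        except ValueError as exc:
            logger.error("recording %s failed analysis (%s); skipped", key, exc)
            skipped.append(key)
            continue

        noise_seed = (seed * 1000003 + rec_i * 101) % (2**31)
        identity_parts: dict[int, np.ndarray] = {}
        for si, (seg, i0, i1, track, env, voicing) in enumerate(syllables):
            if seg["tone"] != 1:
                ident_f0 = np.where(track.f0 > 0, track.f0,
                                    max(np.median(track.f0[track.f0 > 0]), 60.0)
                                    if np.any(track.f0 > 0) else 100.0)
                identity_parts[si] = dsp.resynthesize(
                    env, voicing, ident_f0, seed=noise_seed + si).samples

        for pspec in pitch_specs:
            # resynthesize each Tone-1 syllable once per pitch spec
            pitch_parts: dict[int, tuple[np.ndarray, "dsp.VoicingSegmentation"]] = {}
            for si, (seg, i0, i1, track, env, voicing) in enumerate(syllables):
                if seg["tone"] == 1:
                    target = _contour_target(track, voicing, pspec)
                    res = dsp.resynthesize(env, voicing, target,
                                           seed=noise_seed + si)
                    pitch_parts[si] = (res.samples, voicing)
            for lspec in loudness_grid:
                samples = rec.wave.samples.copy()
                manip_spans: list[tuple[float, float]] = []
                for si, (seg, i0, i1, track, env, voicing) in enumerate(syllables):
                    if seg["tone"] == 1:
                        part, vseg = pitch_parts[si]
                        shaped = dsp.apply_gain_contour(
                            Waveform(part, rate), vseg,
                            lspec.start_db, lspec.end_db)
                        samples[i0:i1] = shaped.samples
                        if vseg.extent is not None:
                            a, b = vseg.extent
                            manip_spans.append((seg["start"] + a, seg["start"] + b))
                    else:
                        samples[i0:i1] = identity_parts[si]
                token_id = (f"{rec.word_id}_{rec.speaker}_"
                            f"{pspec.category.value}{pspec.index}_"
                            f"{lspec.category.value}")
                audio[token_id] = Waveform(samples, rate)
                tokens.append(StimulusToken(
                    token_id=token_id, word_id=rec.word_id, speaker=rec.speaker,
                    pitch_spec=pspec, loudness_spec=lspec, rms=np.nan,
                    manip_spans=tuple(manip_spans),
                ))

    if skipped:
        logger.warning("skipped %d recording(s): %s", len(skipped), skipped)

    ids = [t.token_id for t in tokens]
    normalized = normalize_rms([audio[i] for i in ids], rms_target, names=ids)
    audio = dict(zip(ids, normalized))
    tokens = [
        StimulusToken(t.token_id, t.word_id, t.speaker, t.pitch_spec,
                      t.loudness_spec, audio[t.token_id].rms(),
                      t.audio_path, t.manip_spans)
        for t in tokens
    ]

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        relinked = []
        for t in tokens:
            fname = f"{t.token_id}.wav"
            dsp.write_wav(out_dir / fname, audio[t.token_id])
            relinked.append(StimulusToken(
                t.token_id, t.word_id, t.speaker, t.pitch_spec, t.loudness_spec,
                t.rms, fname, t.manip_spans))
        tokens = relinked
        manifest = CorpusManifest(tokens, rms_target, seed)
        manifest.save(out_dir / "manifest.csv")
    else:
        manifest = CorpusManifest(tokens, rms_target, seed)
    return manifest, audio


SLOPE_DEAD_ZONE_HZ_S = 10.0


def verify_token_f0(token: StimulusToken, wave: Waveform,
                    edge_trim_s: float = 0.025) -> dict:
    """Re-estimate a token's F0 over its manipulated span and check the contour.

    A line is fitted to the voiced-frame F0 (edge frames trimmed to avoid
    boundary bias) and extrapolated to the span ends.  The measured category
    is the slope sign with a ±10 Hz/s dead zone around flat.
    """
    if not token.manip_spans:
        raise ValueError(f"token {token.token_id} has no manipulated span recorded")
    a = min(s[0] for s in token.manip_spans)
    b = max(s[1] for s in token.manip_spans)
    track = dsp.estimate_f0(wave)
    sel = (track.times >= a) & (track.times <= b) & (track.f0 > 0)
    times, f0 = track.times[sel], track.f0[sel]
    if len(times) < 4:
        return {"token_id": token.token_id, "ok": False, "reason": "too few voiced frames"}
    inner = (times >= times[0] + edge_trim_s) & (times <= times[-1] - edge_trim_s)
    if inner.sum() >= 4:
        times_fit, f0_fit = times[inner], f0[inner]
    else:
        times_fit, f0_fit = times, f0
    slope, intercept = np.polyfit(times_fit, f0_fit, 1)
    est_start = slope * a + intercept
    est_end = slope * b + intercept
    if slope > SLOPE_DEAD_ZONE_HZ_S:
        measured = ContourCategory.RISING
    elif slope < -SLOPE_DEAD_ZONE_HZ_S:
        measured = ContourCategory.FALLING
    else:
        measured = ContourCategory.FLAT
    spec = token.pitch_spec
    return {
        "token_id": token.token_id,
        "ok": True,
        "measured_category": measured,
        "category_match": measured is spec.category,
        "est_start_hz": float(est_start),
        "est_end_hz": float(est_end),
        "start_rel_err": abs(est_start - spec.start_hz) / spec.start_hz,
        "end_rel_err": abs(est_end - spec.end_hz) / spec.end_hz,
        "slope_hz_s": float(slope),
    }
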