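"""Pitch and loudness contour grids for cue-dissociated Mandarin tone stimuli.

Mandarin lexical tones carry meaning through the pitch trajectory of a
syllable: Tone 1 is high and flat, Tone 2 rises, Tone 4 falls (Tone 3, the
dipping tone, is deliberately absent from this stimulus design).  The corpus
imposes one of nine linear F0 contours — three per category, in a register
appropriate to the speaker's voice — crossed with three loudness (dB gain)
contours, so that the primary pitch cue and the secondary loudness cue vary
independently.

The built-in grids live in ``data/contours.json``; new speakers can be added
by supplying a config file with the same schema, no code changes needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from enum import Enum
from importlib import resources
from pathlib import Path

__all__ = [
    "ContourCategory",
    "PitchContourSpec",
    "LoudnessContourSpec",
    "builtin_pitch_specs",
    "builtin_loudness_specs",
    "load_contour_config",
    "sample_contour",
    "tone_of",
    "category_of_tone",
]


class ContourCategory(str, Enum):
    """Direction class of a linear contour: high-flat, rising, or falling."""

    FLAT = "flat"
    RISING = "rising"
    FALLING = "falling"


# Bijection between contour categories and the three Mandarin tones used here.
_TONE_OF = {
    ContourCategory.FLAT: 1,
    ContourCategory.RISING: 2,
    ContourCategory.FALLING: 4,
}
_CATEGORY_OF = {v: k for k, v in _TONE_OF.items()}

F0_FLOOR_HZ = 60.0
F0_CEIL_HZ = 400.0


def tone_of(category: ContourCategory) -> int:
    """Map a contour category to its lexical tone (flat→1, rising→2, falling→4)."""
    return _TONE_OF[ContourCategory(category)]


def category_of_tone(tone: int) -> ContourCategory:
    """Inverse of :func:`tone_of`."""
    try:
        return _CATEGORY_OF[int(tone)]
    except KeyError:
        raise ValueError(f"no contour category for tone {tone}; valid tones are 1, 2, 4")


@dataclass(frozen=True)
class PitchContourSpec:
    """A linear F0 trajectory from ``start_hz`` to ``end_hz`` over the voiced span.

    ``index`` numbers the spec 1..3 within its category, ordered as in the
    built-in grid (highest/widest first).
    """

    start_hz: float
    end_hz: float
    category: ContourCategory
    speaker_gender: str
    index: int

    def __post_init__(self):
        cat = ContourCategory(self.category)
        object.__setattr__(self, "category", cat)
        if not (F0_FLOOR_HZ <= self.start_hz <= F0_CEIL_HZ
                and F0_FLOOR_HZ <= self.end_hz <= F0_CEIL_HZ):
            raise ValueError(
                f"contour endpoints ({self.start_hz}, {self.end_hz}) outside "
                f"[{F0_FLOOR_HZ}, {F0_CEIL_HZ}] Hz"
            )
        if cat is ContourCategory.FLAT and self.start_hz != self.end_hz:
            raise ValueError("flat contour requires start_hz == end_hz")
        if cat is ContourCategory.RISING and not self.start_hz < self.end_hz:
            raise ValueError("rising contour requires start_hz < end_hz")
        if cat is ContourCategory.FALLING and not self.start_hz > self.end_hz:
            raise ValueError("falling contour requires start_hz > end_hz")

    @property
    def tone(self) -> int:
        return tone_of(self.category)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["category"] = self.category.value
        return d


@dataclass(frozen=True)
class LoudnessContourSpec:
    """A linear dB gain ramp applied over the voiced span of the target syllable."""

    start_db: float
    end_db: float
    category: ContourCategory

    def __post_init__(self):
        object.__setattr__(self, "category", ContourCategory(self.category))

    @property
    def implied_tone(self) -> int:
        """Tone a listener relying on the loudness contour alone would infer."""
        return tone_of(self.category)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["category"] = self.category.value
        return d


def load_contour_config(path: str | Path | None = None) -> dict:
    """Load a contour grid config (the shipped default when ``path`` is None)."""
    if path is None:
        text = resources.files("tonelab.data").joinpath("contours.json").read_text()
    else:
        text = Path(path).read_text()
    return json.loads(text)


def builtin_pitch_specs(gender: str, config: dict | None = None) -> list[PitchContourSpec]:
    """The nine F0 contours for one speaker: 3 flat, 3 rising, 3 falling.

    Female register spans 120–300 Hz, male 80–220 Hz, reflecting natural
    voice ranges; within a category the three contours share their anchor
    (e.g. female rises all start at 150 Hz and end at 300/250/200 Hz).
    """
    cfg = config if config is not None else load_contour_config()
    try:
        grid = cfg["speakers"][gender]
    except KeyError:
        raise ValueError(
            f"unknown speaker gender {gender!r}; available: {sorted(cfg['speakers'])}"
        )
    specs: list[PitchContourSpec] = []
    for cat in ContourCategory:
        entries = grid[cat.value]
        for i, entry in enumerate(entries, start=1):
            if cat is ContourCategory.FLAT:
                start = end = float(entry)
            else:
                start, end = float(entry[0]), float(entry[1])
            specs.append(PitchContourSpec(start, end, cat, gender, i))
    if len(specs) != 9:
        raise ValueError(f"contour grid for {gender!r} has {len(specs)} specs, expected 9")
    return specs


def builtin_loudness_specs(config: dict | None = None) -> list[LoudnessContourSpec]:
    """The three gain contours: 0 dB flat, −10→+10 dB rising, +10→−10 dB falling."""
    cfg = config if config is not None else load_contour_config()
    return [
        LoudnessContourSpec(float(se[0]), float(se[1]), ContourCategory(cat))
        for cat, se in cfg["gains_db"].items()
    ]


def sample_contour(spec: PitchContourSpec, t_rel: float) -> float:
    """Evaluate a linear contour at relative time ``t_rel`` ∈ [0, 1] of the voiced span."""
    if not 0.0 <= t_rel <= 1.0:
        raise ValueError(f"t_rel={t_rel} outside [0, 1]")
    return spec.start_hz + t_rel * (spec.end_hz - spec.start_hz)
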