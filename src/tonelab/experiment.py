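"""Forced-choice tone recognition experiment bookkeeping.

A session plan randomizes the disyllabic (Di) tokens into 6 equal blocks of
a 3-alternative forced choice (tones 1, 2, 4), with a monosyllabic (Mono)
4AFC block — natural recordings, abstract here — inserted between Di blocks
3 and 4.  Scoring is strictly pitch-based: a response is correct iff it
names the tone implied by the token's pitch contour, regardless of the
loudness contour, and that correctness drives the trial feedback.

The engine is headless: it plans, scores and logs; audio presentation,
GUIs and timing are out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus import CorpusManifest, StimulusToken

__all__ = [
    "DI_TASK",
    "MONO_TASK",
    "MonoToken",
    "SessionPlan",
    "TrialRecord",
    "ResponseLog",
    "make_mono_set",
    "make_session_plan",
    "score_trial",
    "group_sessions",
]

DI_TASK = "Di-3AFC"
MONO_TASK = "Mono-4AFC"
DI_ALTERNATIVES = (1, 2, 4)
MONO_ALTERNATIVES = (1, 2, 3, 4)
N_DI_BLOCKS = 6


@dataclass(frozen=True)
class MonoToken:
    """An abstract natural monosyllable: id and true lexical tone (1–4).

    In natural recordings all cues covary, so the true tone is both the
    pitch-implied and the secondary-cue-implied tone.
    """

    token_id: str
    tone: int

    def __post_init__(self):
        if self.tone not in MONO_ALTERNATIVES:
            raise ValueError(f"Mono tone must be in {MONO_ALTERNATIVES}")


def make_mono_set(n_words: int = 25) -> list[MonoToken]:
    """The Mono comparison set: ``n_words`` monosyllables × 4 tones."""
    return [MonoToken(f"mono{w + 1:02d}_t{t}", t)
            for w in range(n_words) for t in MONO_ALTERNATIVES]


@dataclass(frozen=True)
class SessionPlan:
    """Ordered experiment blocks: (block_id, task, token ids in presentation order)."""

    blocks: tuple[tuple[str, str, tuple[str, ...]], ...]
    seed: int

    @property
    def di_blocks(self) -> list[tuple[str, str, tuple[str, ...]]]:
        return [b for b in self.blocks if b[1] == DI_TASK]

    @property
    def trial_ids(self) -> list[tuple[str, str, int]]:
        """Flat list of (token_id, task, session_index) in presentation order."""
        out = []
        for bi, (_, task, ids) in enumerate(self.blocks):
            for tid in ids:
                out.append((tid, task, bi + 1))
        return out

    def __len__(self) -> int:
        return sum(len(b[2]) for b in self.blocks)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"seed": self.seed,
             "blocks": [{"block_id": b, "task": t, "tokens": list(ids)}
                        for b, t, ids in self.blocks]}, indent=1))


def make_session_plan(manifest: CorpusManifest,
                      mono_ids: list[str] | None = None,
                      seed: int = 0,
                      n_di_blocks: int = N_DI_BLOCKS) -> SessionPlan:
    """Randomize Di tokens into equal 3AFC blocks, Mono 4AFC in the middle.

    The partition and within-block order are driven solely by ``seed``.
    The Mono block sits between Di blocks ``n//2`` and ``n//2 + 1`` (blocks
    3 and 4 for the standard six).
    """
    di_ids = list(manifest.token_ids)
    if len(di_ids) % n_di_blocks != 0:
        raise ValueError(
            f"{len(di_ids)} Di tokens not divisible into {n_di_blocks} equal "
            f"blocks; pass n_di_blocks explicitly to override"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(di_ids))
    block_size = len(di_ids) // n_di_blocks
    di_blocks = [
        tuple(di_ids[j] for j in order[i * block_size:(i + 1) * block_size])
        for i in range(n_di_blocks)
    ]
    blocks: list[tuple[str, str, tuple[str, ...]]] = []
    half = n_di_blocks // 2
    di_no = 0
    for i in range(n_di_blocks):
        if i == half and mono_ids:
            mono_order = rng.permutation(len(mono_ids))
            blocks.append(("Mono", MONO_TASK,
                           tuple(mono_ids[j] for j in mono_order)))
        di_no += 1
        blocks.append((f"Di{di_no}", DI_TASK, di_blocks[i]))
    return SessionPlan(tuple(blocks), seed)


@dataclass(frozen=True)
class TrialRecord:
    """One forced-choice presentation with pitch-based scoring."""

    token_id: str
    session_index: int
    task: str
    n_alternatives: int
    stimulus_tone: int
    response_tone: int
    correct: bool
    congruence: str | None = None  # Di only
    feedback_shown: bool = True


@dataclass
class ResponseLog:
    """All trials of one subject, with cohort metadata."""

    subject_id: str
    group: str  # "CI" or "NH"
    trials: list[TrialRecord] = field(default_factory=list)
    listening_experience_years: float | None = None

    def append(self, trial: TrialRecord) -> None:
        self.trials.append(trial)

    def di_trials(self) -> list[TrialRecord]:
        return [t for t in self.trials if t.task == DI_TASK]

    def mono_trials(self) -> list[TrialRecord]:
        return [t for t in self.trials if t.task == MONO_TASK]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([t.__dict__ for t in self.trials])

    def save(self, path: str | Path) -> None:
        """CSV of trials preceded by a commented JSON header with metadata."""
        header = json.dumps({
            "subject_id": self.subject_id, "group": self.group,
            "listening_experience_years": self.listening_experience_years,
        })
        with open(path, "w") as fh:
            fh.write(f"# {header}\n")
            self.to_dataframe().to_csv(fh, index=False)

    @classmethod
    def load(cls, path: str | Path) -> "ResponseLog":
        with open(path) as fh:
            first = fh.readline()
            meta = json.loads(first.lstrip("# ").strip()) if first.startswith("#") \
                else {"subject_id": "unknown", "group": "CI"}
            df = pd.read_csv(fh)
        log = cls(meta["subject_id"], meta["group"],
                  listening_experience_years=meta.get("listening_experience_years"))
        for _, row in df.iterrows():
            cong = row.get("congruence")
            log.append(TrialRecord(
                token_id=row.token_id, session_index=int(row.session_index),
                task=row.task, n_alternatives=int(row.n_alternatives),
                stimulus_tone=int(row.stimulus_tone),
                response_tone=int(row.response_tone), correct=bool(row.correct),
                congruence=None if pd.isna(cong) else cong,
                feedback_shown=bool(row.feedback_shown)))
        return log


def score_trial(token: StimulusToken | MonoToken, response_tone: int,
                session_index: int = 1, feedback_shown: bool = True) -> TrialRecord:
    """Score one trial: correct iff the response matches the pitch-implied tone.

    Di tokens allow responses {1, 2, 4} (3AFC); Mono tokens {1, 2, 3, 4}.
    The loudness contour never enters the scoring.
    """
    if isinstance(token, MonoToken):
        allowed, task = MONO_ALTERNATIVES, MONO_TASK
        stim_tone, congruence = token.tone, None
    else:
        allowed, task = DI_ALTERNATIVES, DI_TASK
        stim_tone, congruence = token.pitch_tone, token.congruence
    if response_tone not in allowed:
        raise ValueError(
            f"response {response_tone} not among the {len(allowed)} alternatives "
            f"{allowed} for task {task}"
        )
    return TrialRecord(
        token_id=token.token_id, session_index=session_index, task=task,
        n_alternatives=len(allowed), stimulus_tone=stim_tone,
        response_tone=response_tone, correct=(response_tone == stim_tone),
        congruence=congruence, feedback_shown=feedback_shown)


def group_sessions(log: ResponseLog, grouping: str = "pairs",
                   plan: SessionPlan | None = None) -> dict[str, list[TrialRecord]]:
    """Partition a complete log for training-effect and headline analyses.

    ``pairs``:   Di sessions {1,2}, {3,4}, {5,6} (training-effect contrast).
    ``pooled``:  Di sessions 3–6 (the headline score, after training settles).
    ``thirds``:  the Mono block split into three consecutive parts; the 100
                 trials split 34/33/33, earlier parts taking the remainder.
    """
    if plan is not None:
        expected = len(plan)
        if len(log.trials) != expected:
            missing = expected - len(log.trials)
            raise ValueError(f"incomplete log: {missing} of {expected} trials missing")
    di = log.di_trials()
    di_sessions = sorted({t.session_index for t in di})
    if grouping == "pairs":
        if len(di_sessions) % 2:
            raise ValueError("pairs grouping needs an even number of Di sessions")
        out = {}
        for i in range(0, len(di_sessions), 2):
            pair = di_sessions[i:i + 2]
            out[f"Di{i + 1}&{i + 2}"] = [t for t in di if t.session_index in pair]
        return out
    if grouping == "pooled":
        late = di_sessions[2:]
        return {"Di3-6": [t for t in di if t.session_index in late]}
    if grouping == "thirds":
        mono = log.mono_trials()
        n = len(mono)
        base, rem = divmod(n, 3)
        sizes = [base + (1 if i < rem else 0) for i in range(3)]
        out, start = {}, 0
        for i, size in enumerate(sizes):
            out[f"Mono-part{i + 1}"] = mono[start:start + size]
            start += size
        return out
    raise ValueError(f"unknown grouping {grouping!r}")
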