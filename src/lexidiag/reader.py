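"""Parametric virtual reader and single-trial recognition model.

A :class:`ReaderProfile` captures the quantities that vary between children in
tachistoscopic pseudoword experiments: how many letters can be recognized
simultaneously as a function of fixation (presentation) time, the verbal
reaction time (VRT) the reader needs before pronunciation can start, a
residual lapse rate, an eye-movement strategy, an optional homonymous visual
field defect, compliance with external guidance, and letter pairs whose
sounds are confusable at pronunciation.

The recognition model is deliberately simple: a pseudoword is read correctly
within one fixation if and only if every letter is inside the seen window,
the word is no longer than the capacity at that fixation time, the allowed
VRT covers the required VRT, and neither a lapse nor a grapheme confusion
occurs.  Letter-level errors carry no positional structure: conditional on a
capacity or lapse error, the error position is uniform over letter positions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import yaml
from numpy.random import Generator, default_rng
from scipy import stats

from ._errors import ConfigurationError

__all__ = [
    "TIME_GRID_MS",
    "VRT_FLOOR_MS",
    "VRT_PRESETS",
    "Strategy",
    "DefectSide",
    "Compensation",
    "VisualFieldDefect",
    "ReaderProfile",
    "TrialOutcome",
    "visible_window",
    "recognize",
    "letters_recognized",
    "sample_cohort",
    "save_cohort_jsonl",
    "load_cohort_jsonl",
]

#: Fixation-time grid (ms) on which capacities are defined by default.
TIME_GRID_MS: tuple[int, ...] = (250, 300, 350, 400, 450, 500)

#: Physiological lower bound used when truncating the VRT distribution.
VRT_FLOOR_MS: float = 200.0

#: (mean, SD) of the normal VRT distribution before positive truncation.
VRT_PRESETS: dict[str, tuple[float, float]] = {
    "low_vrt": (1316.0, 712.0),
    "high_vrt": (1670.0, 641.0),
}

#: Letter-capacity ceilings observed in the study cohorts and their sampling
#: probabilities ("few" children reach six letters).
CEILING_SUPPORT: tuple[int, ...] = (3, 4, 5, 6)
CEILING_PROBS: tuple[float, ...] = (0.3, 0.3, 0.3, 0.1)

#: Probability that a confusable letter pair is actually exchanged at
#: pronunciation, per occurrence.
CONFUSION_PROB: float = 0.5


class Strategy(str, Enum):
    """Unguided eye-movement / reading strategies."""

    whole_word = "whole_word"
    staircase_segments = "staircase_segments"
    searching = "searching"
    hypermetric_no_correction = "hypermetric_no_correction"
    letter_by_letter = "letter_by_letter"


class DefectSide(str, Enum):
    left = "left"
    right = "right"


class Compensation(str, Enum):
    none = "none"
    gaze_to_end = "gaze_to_end"
    gaze_to_beginning = "gaze_to_beginning"


@dataclass(frozen=True)
class VisualFieldDefect:
    """Homonymous visual field defect with an optional compensatory gaze
    strategy.

    Directing the gaze to the end of the segment compensates a *right*-sided
    defect (more letters fall into the intact left hemifield); directing it
    to the beginning compensates a *left*-sided defect.  Other pairings are
    rejected.
    """

    side: DefectSide
    foveal_involvement: bool = True
    compensation: Compensation = Compensation.none

    def __post_init__(self):
        object.__setattr__(self, "side", DefectSide(self.side))
        object.__setattr__(self, "compensation", Compensation(self.compensation))
        if (
            self.compensation is Compensation.gaze_to_end
            and self.side is not DefectSide.right
        ):
            raise ConfigurationError(
                "gaze_to_end only compensates a right-sided defect"
            )
        if (
            self.compensation is Compensation.gaze_to_beginning
            and self.side is not DefectSide.left
        ):
            raise ConfigurationError(
                "gaze_to_beginning only compensates a left-sided defect"
            )

    def to_dict(self) -> dict:
        return {
            "side": self.side.value,
            "foveal_involvement": self.foveal_involvement,
            "compensation": self.compensation.value,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "VisualFieldDefect":
        return cls(
            side=DefectSide(d["side"]),
            foveal_involvement=bool(d.get("foveal_involvement", True)),
            compensation=Compensation(d.get("compensation", "none")),
        )


def _normalize_confusions(pairs: Iterable) -> frozenset[frozenset[str]]:
    out = set()
    for pair in pairs:
        letters = frozenset(str(c).lower() for c in pair)
        if len(letters) != 2:
            raise ConfigurationError(
                f"grapheme confusion {pair!r} is not an unordered pair of two letters"
            )
        out.add(letters)
    return frozenset(out)


@dataclass
class ReaderProfile:
    """Per-child quantities varied in the pseudoword experiments."""

    capacity_by_time: dict[int, int]
    required_vrt_ms: float
    lapse_rate: float = 0.0
    strategy: Strategy = Strategy.whole_word
    field_defect: Optional[VisualFieldDefect] = None
    compliance: float = 1.0
    grapheme_confusions: frozenset[frozenset[str]] = field(default_factory=frozenset)

    def __post_init__(self):
        self.strategy = Strategy(self.strategy)
        self.capacity_by_time = {
            int(t): int(c) for t, c in sorted(self.capacity_by_time.items())
        }
        if not self.capacity_by_time:
            raise ConfigurationError("capacity_by_time must not be empty")
        caps = [self.capacity_by_time[t] for t in sorted(self.capacity_by_time)]
        if any(c < 0 for c in caps):
            raise ConfigurationError("capacities must be non-negative")
        if any(b < a for a, b in zip(caps, caps[1:])):
            raise ConfigurationError(
                "capacity_by_time must be monotone non-decreasing in time"
            )
        if not 0 <= caps[-1] <= 8:
            raise ConfigurationError("capacity ceiling must lie in 0..8")
        if not self.required_vrt_ms > 0:
            raise ConfigurationError("required_vrt_ms must be positive")
        if not 0.0 <= self.lapse_rate <= 0.05:
            raise ConfigurationError("lapse_rate must lie in [0, 0.05]")
        if not 0.0 <= self.compliance <= 1.0:
            raise ConfigurationError("compliance must lie in [0, 1]")
        self.grapheme_confusions = _normalize_confusions(self.grapheme_confusions)

    # -- capacity queries ---------------------------------------------------

    def capacity(self, presentation_ms: int) -> int:
        """Capacity at ``presentation_ms``, clamping down to the nearest
        defined grid time at or below (the experiments only use a 50 ms
        grid)."""
        times = sorted(self.capacity_by_time)
        if presentation_ms < times[0]:
            raise ValueError(
                f"presentation time {presentation_ms} ms is below the defined "
                f"grid (min {times[0]} ms)"
            )
        t = max(t for t in times if t <= presentation_ms)
        return self.capacity_by_time[t]

    @property
    def ceiling(self) -> int:
        """Capacity at the longest defined fixation time."""
        return self.capacity_by_time[max(self.capacity_by_time)]

    def time_needed(self, length: int) -> Optional[int]:
        """Minimal defined fixation time at which ``length`` letters can be
        recognized simultaneously, or ``None`` if the ceiling is too low."""
        for t in sorted(self.capacity_by_time):
            if self.capacity_by_time[t] >= length:
                return t
        return None

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "capacity_by_time": dict(self.capacity_by_time),
            "required_vrt_ms": float(self.required_vrt_ms),
            "lapse_rate": float(self.lapse_rate),
            "strategy": self.strategy.value,
            "field_defect": self.field_defect.to_dict() if self.field_defect else None,
            "compliance": float(self.compliance),
            "grapheme_confusions": sorted("".join(sorted(p)) for p in self.grapheme_confusions),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ReaderProfile":
        defect = d.get("field_defect")
        return cls(
            capacity_by_time={int(k): int(v) for k, v in d["capacity_by_time"].items()},
            required_vrt_ms=float(d["required_vrt_ms"]),
            lapse_rate=float(d.get("lapse_rate", 0.0)),
            strategy=Strategy(d.get("strategy", "whole_word")),
            field_defect=VisualFieldDefect.from_dict(defect) if defect else None,
            compliance=float(d.get("compliance", 1.0)),
            grapheme_confusions=frozenset(
                frozenset(p) for p in d.get("grapheme_confusions", [])
            ),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ReaderProfile":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ReaderProfile":
        return cls.from_dict(json.loads(text))

    def with_(self, **kwargs) -> "ReaderProfile":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class TrialOutcome:
    """Outcome of one recognition attempt."""

    correct: bool
    visible_indices: frozenset[int]
    error_position: Optional[int]
    vrt_used_ms: float


def visible_window(
    word_length: int,
    fixation_index: int,
    defect: Optional[VisualFieldDefect] = None,
) -> frozenset[int]:
    """Set of 0-based letter positions that fall into the seeing field.

    With no defect, or a defect sparing the fovea (the word is assumed to lie
    within the spared central field), every position is visible.  A
    right-sided foveal defect masks everything right of the fixated letter; a
    left-sided foveal defect masks everything left of it.  A compensatory
    gaze strategy overrides the caller's fixation index: ``gaze_to_end``
    fixates the last letter, ``gaze_to_beginning`` the first.
    """
    if word_length < 1:
        raise ValueError("word_length must be positive")
    if not 0 <= fixation_index < word_length:
        raise ValueError(
            f"fixation_index {fixation_index} outside word of length {word_length}"
        )
    if defect is None or not defect.foveal_involvement:
        return frozenset(range(word_length))
    if defect.compensation is Compensation.gaze_to_end:
        fixation_index = word_length - 1
    elif defect.compensation is Compensation.gaze_to_beginning:
        fixation_index = 0
    if defect.side is DefectSide.right:
        return frozenset(range(0, fixation_index + 1))
    return frozenset(range(fixation_index, word_length))


def _as_rng(rng_seed: Union[int, Generator]) -> Generator:
    if isinstance(rng_seed, Generator):
        return rng_seed
    return default_rng(rng_seed)


def _middle_index(length: int) -> int:
    # even length fixates left of center, matching the segment-plan tie-break
    return (length - 1) // 2


def recognize(
    reader: ReaderProfile,
    word: str,
    presentation_ms: int,
    allowed_vrt_ms: float,
    rng_seed: Union[int, Generator],
    fixation_index: Optional[int] = None,
) -> TrialOutcome:
    """Simulate one tachistoscopic recognition attempt.

    The attempt is correct iff the whole word is inside the seen window, the
    word is within capacity at ``presentation_ms``, the allowed VRT covers
    the required VRT, no lapse occurs, and no grapheme confusion occurs.
    Error positions for window/capacity/lapse errors are drawn uniformly
    (over unseen positions for window errors, over all positions otherwise);
    a pure VRT failure is not a letter-level error and carries no position.
    """
    if not word:
        raise ValueError("word must be non-empty")
    if presentation_ms <= 0 or allowed_vrt_ms <= 0:
        raise ValueError("times must be positive")
    rng = _as_rng(rng_seed)
    n = len(word)
    fix = _middle_index(n) if fixation_index is None else fixation_index
    visible = visible_window(n, fix, reader.field_defect)

    cap = reader.capacity(presentation_ms)
    window_ok = len(visible) == n
    capacity_ok = n <= cap
    vrt_ok = allowed_vrt_ms >= reader.required_vrt_ms

    # fixed draw order keeps trials reproducible across condition branches
    lapse = rng.random() < reader.lapse_rate if reader.lapse_rate > 0 else False
    confused_positions: list[int] = []
    if reader.grapheme_confusions:
        confusable = {c for pair in reader.grapheme_confusions for c in pair}
        for i, ch in enumerate(word.lower()):
            if ch in confusable and rng.random() < CONFUSION_PROB:
                confused_positions.append(i)

    correct = window_ok and capacity_ok and vrt_ok and not lapse and not confused_positions

    error_position: Optional[int] = None
    if not correct:
        if not window_ok:
            unseen = sorted(set(range(n)) - visible)
            error_position = int(rng.choice(unseen))
        elif not capacity_ok or lapse:
            error_position = int(rng.integers(0, n))
        elif confused_positions:
            error_position = int(rng.choice(confused_positions))
        # VRT-only failure: premature pronunciation, no letter-level error

    vrt_used = reader.required_vrt_ms if vrt_ok else float(allowed_vrt_ms)
    return TrialOutcome(
        correct=correct,
        visible_indices=visible,
        error_position=error_position,
        vrt_used_ms=float(vrt_used),
    )


def letters_recognized(
    reader: ReaderProfile,
    word: str,
    presentation_ms: int,
    fixation_index: Optional[int] = None,
) -> int:
    """Number of letters visually identified in one fixation: letters inside
    the seen window, limited to the ``capacity`` letters nearest the fixated
    letter (ties resolved leftward).  Used by the natural-word guessing rule."""
    n = len(word)
    fix = _middle_index(n) if fixation_index is None else fixation_index
    visible = visible_window(n, fix, reader.field_defect)
    cap = reader.capacity(presentation_ms)
    if cap <= 0:
        return 0
    by_distance = sorted(range(n), key=lambda i: (abs(i - fix), i))
    window = set(by_distance[: min(cap, n)])
    return len(window & visible)


def sample_cohort(
    n: int,
    preset: str = "low_vrt",
    rng_seed: Union[int, Generator] = 0,
) -> list[ReaderProfile]:
    """Draw a synthetic cohort emulating the study populations.

    Capacity ceilings come from {3,4,5,6} with probabilities (.3,.3,.3,.1);
    each reader reaches the ceiling at a threshold time drawn uniformly from
    {350,...,500} ms and loses one letter per 50 ms below it (floored at two
    letters).  Required VRTs are positive-truncated normal draws with the
    preset's mean/SD, truncated at 200 ms.  Defaults: whole-word strategy,
    compliance 0.9, lapse rate 0.02.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if preset not in VRT_PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(VRT_PRESETS)}")
    rng = _as_rng(rng_seed)
    mean, sd = VRT_PRESETS[preset]
    ceilings = rng.choice(CEILING_SUPPORT, size=n, p=CEILING_PROBS)
    thresholds = rng.choice((350, 400, 450, 500), size=n)
    a = (VRT_FLOOR_MS - mean) / sd
    vrts = stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)
    cohort = []
    for ceiling, thr, vrt in zip(ceilings.tolist(), thresholds.tolist(), vrts.tolist()):
        capacity = {
            t: ceiling if t >= thr else max(2, ceiling - (thr - t) // 50)
            for t in TIME_GRID_MS
        }
        cohort.append(
            ReaderProfile(
                capacity_by_time=capacity,
                required_vrt_ms=float(vrt),
                lapse_rate=0.02,
                strategy=Strategy.whole_word,
                compliance=0.9,
            )
        )
    return cohort


def save_cohort_jsonl(cohort: Sequence[ReaderProfile], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for profile in cohort:
            fh.write(profile.to_json() + "\n")


def load_cohort_jsonl(path) -> list[ReaderProfile]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(ReaderProfile.from_json(line))
    return out
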