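"""Unguided versus computer-guided reading simulation and effect sizes.

Unguided readers choose their own parameters, and those self-chosen
parameters embody the causal mechanisms of reading failure: fixations that
are too short (250 ms), attempts to recognize more letters than the
simultaneous-recognition capacity allows, premature pronunciation (the
self-chosen verbal reaction time is 80% of the required one), searching or
hypermetric eye-movement strategies, and letter guessing on natural words.
Guided reading enforces the reader's own diagnosed parameters segment by
segment — segment length, fixation time, saccade target, and pronunciation
cue — and withholds the next segment until the current one is read correctly,
so errors remain only where the reader does not comply with the guidance or
lapses.

The self-chosen constants (250 ms fixation, 0.8x required VRT, guess
probabilities 0.5/0.1, regression rate 0.1 per transition, hypermetric excess
of two letters) are fixed model constants: the mechanisms are documented
clinically but their rates are not, so they are pinned once and reported with
results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from numpy.random import Generator, SeedSequence, default_rng
from scipy import stats

from ._errors import SessionAbortedError
from .pseudowords import ClusterInventory, builtin_inventory, builtin_lexicon, generate_list
from .reader import ReaderProfile, Strategy, letters_recognized, recognize, sample_cohort
from .segmentation import segment_text
from .staircase import StaircaseConfig, run_staircase

__all__ = [
    "SELF_FIXATION_MS",
    "SELF_VRT_FACTOR",
    "GUESS_P_HIGH",
    "GUESS_P_LOW",
    "REGRESSION_RATE",
    "HYPERMETRIC_EXCESS",
    "SACCADE_MS",
    "SegmentRecord",
    "ReadingSession",
    "TherapyOutcome",
    "simulate_unguided",
    "simulate_guided",
    "error_reduction",
    "hedges_g",
    "PositionProfile",
    "error_position_profile",
    "standard_therapy_text",
    "cohort_experiment",
]

SELF_FIXATION_MS = 250  #: self-chosen fixation duration in unguided reading
SELF_VRT_FACTOR = 0.8  #: premature pronunciation: fraction of the required VRT
GUESS_P_HIGH = 0.5  #: guess success when >= half the letters were recognized
GUESS_P_LOW = 0.1  #: guess success otherwise
REGRESSION_RATE = 0.1  #: isolated single regressions per transition
HYPERMETRIC_EXCESS = 2  #: letters by which hypermetric amplitudes overshoot
SACCADE_MS = 30  #: time cost per saccade in the reading-time model

#: Word-length mix (letters -> probability) of the standard therapy text,
#: chosen to resemble running text for young readers: mostly short function
#: and content words with a tail of longer words.
WORD_LENGTH_PROBS: dict[int, float] = {
    2: 0.15,
    3: 0.25,
    4: 0.20,
    5: 0.15,
    6: 0.10,
    7: 0.07,
    8: 0.08,
}


class Mode(str, Enum):
    unguided = "unguided"
    guided = "guided"


@dataclass(frozen=True)
class SegmentRecord:
    text: str
    attempted_length: int
    fixation_ms: int
    allowed_vrt_ms: float
    correct: bool
    error_position: Optional[int] = None


@dataclass
class ReadingSession:
    mode: Mode
    records: list[SegmentRecord]
    total_time_ms: float

    @property
    def total_segments(self) -> int:
        return len(self.records)

    @property
    def total_errors(self) -> int:
        return sum(1 for r in self.records if not r.correct)


@dataclass
class TherapyOutcome:
    errors_unguided: int
    errors_guided: int
    reduction_percent: float
    hedges_g: float
    per_reader: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "errors_unguided": int(self.errors_unguided),
            "errors_guided": int(self.errors_guided),
            "reduction_percent": float(self.reduction_percent),
            "hedges_g": float(self.hedges_g),
            "n_readers": int(len(self.per_reader)),
        }


def _as_rng(seed: Union[int, Generator]) -> Generator:
    return seed if isinstance(seed, Generator) else default_rng(seed)


def _trial_seed(rng: Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def _words(text: str) -> list[str]:
    from .segmentation import _words as words

    return words(text)


def _guess(reader: ReaderProfile, recognized: int, length: int, rng: Generator) -> bool:
    """Natural-word guessing: familiar words can be guessed from partial
    letter information."""
    p = GUESS_P_HIGH if recognized >= length / 2 else GUESS_P_LOW
    return rng.random() < p


def _self_vrt(reader: ReaderProfile) -> float:
    return SELF_VRT_FACTOR * reader.required_vrt_ms


def simulate_unguided(
    reader: ReaderProfile,
    text: str,
    inventory: Optional[ClusterInventory] = None,
    rng_seed: Union[int, Generator] = 0,
    regression_rate: float = REGRESSION_RATE,
) -> ReadingSession:
    """Simulate one unguided reading pass over ``text``.

    Attempt units follow the reader's strategy; per attempt, correctness is
    evaluated with the self-chosen parameters, and failed natural words may
    still be guessed.  Isolated regressions are inserted per transition with
    probability ``regression_rate``; they only cost time and are drawn from a
    separate random stream, so they never alter correctness.
    """
    if not text.strip():
        raise ValueError("text must be non-empty")
    inventory = inventory or builtin_inventory("de")
    ss = SeedSequence(_trial_seed(_as_rng(rng_seed)) if not isinstance(rng_seed, int) else rng_seed)
    corr_ss, reg_ss = ss.spawn(2)
    rng = default_rng(corr_ss)
    rng_reg = default_rng(reg_ss)

    records: list[SegmentRecord] = []
    time_ms = 0.0
    strategy = reader.strategy
    cap250 = reader.capacity(SELF_FIXATION_MS)

    for word in _words(text):
        n = len(word)
        if strategy in (Strategy.whole_word, Strategy.searching):
            out = recognize(reader, word, SELF_FIXATION_MS, _self_vrt(reader), _trial_seed(rng))
            correct = out.correct
            pos = out.error_position
            if not correct:
                correct = _guess(reader, letters_recognized(reader, word, SELF_FIXATION_MS), n, rng)
                if correct:
                    pos = None
            records.append(
                SegmentRecord(word, n, SELF_FIXATION_MS, _self_vrt(reader), correct, pos)
            )
            time_ms += SELF_FIXATION_MS + SACCADE_MS
            if strategy is Strategy.searching:
                # back-and-forth searching fixations before settling
                time_ms += 2 * (SELF_FIXATION_MS + SACCADE_MS)
        elif strategy is Strategy.staircase_segments:
            # self-split into capacity-sized segments read at adequate
            # self-chosen times: correct but slow
            plan = segment_text(word, max(2, reader.ceiling), inventory)
            for seg in plan.segments:
                t = reader.time_needed(len(seg)) or max(reader.capacity_by_time)
                out = recognize(reader, seg.text, t, reader.required_vrt_ms, _trial_seed(rng))
                records.append(
                    SegmentRecord(
                        seg.text, len(seg), t, reader.required_vrt_ms, out.correct, out.error_position
                    )
                )
                time_ms += t + SACCADE_MS
        elif strategy is Strategy.hypermetric_no_correction:
            stride = reader.ceiling + HYPERMETRIC_EXCESS
            recognized = 0
            covered = 0
            windows = 0
            while windows * stride < n:
                w = min(reader.ceiling, n - windows * stride)
                recognized += min(cap250, w)
                covered += w
                windows += 1
            gap_positions = [
                i for i in range(n) if (i % stride) >= reader.ceiling
            ]
            correct = covered == n and recognized == n and _self_vrt(reader) >= reader.required_vrt_ms
            pos: Optional[int] = None
            if not correct:
                correct = _guess(reader, recognized, n, rng)
                if not correct and gap_positions:
                    pos = int(rng.choice(gap_positions))
                elif not correct:
                    pos = int(rng.integers(0, n))
            records.append(
                SegmentRecord(word, n, SELF_FIXATION_MS, _self_vrt(reader), correct, pos)
            )
            time_ms += windows * (SELF_FIXATION_MS + SACCADE_MS)
        elif strategy is Strategy.letter_by_letter:
            recognized = sum(min(cap250, 1) for _ in word)
            correct = recognized == n and _self_vrt(reader) >= reader.required_vrt_ms
            pos = None
            if not correct:
                correct = _guess(reader, recognized, n, rng)
                if not correct:
                    pos = int(rng.integers(0, n))
            records.append(
                SegmentRecord(word, n, SELF_FIXATION_MS, _self_vrt(reader), correct, pos)
            )
            time_ms += n * (SELF_FIXATION_MS + SACCADE_MS)
        else:  # pragma: no cover
            raise ValueError(f"unknown strategy {strategy}")
        if regression_rate > 0 and rng_reg.random() < regression_rate:
            # isolated single regression: re-fixation plus two saccades,
            # time only, never a change of outcome
            time_ms += SELF_FIXATION_MS + 2 * SACCADE_MS

    return ReadingSession(mode=Mode.unguided, records=records, total_time_ms=time_ms)


def simulate_guided(
    reader: ReaderProfile,
    text: str,
    capacity: int,
    fixation_ms: int,
    allowed_vrt_ms: float,
    inventory: Optional[ClusterInventory] = None,
    rng_seed: Union[int, Generator] = 0,
    max_attempts_per_segment: int = 10_000,
) -> ReadingSession:
    """Simulate computer-guided reading at the reader's diagnosed parameters.

    The text is segmented at ``capacity``; on each segment the reader obeys
    the guidance with probability ``reader.compliance`` (enforced fixation
    time and pronunciation cue), otherwise the self-chosen unguided
    parameters apply for that attempt.  The next segment is withheld until
    the current one is read correctly; a segment counts as one error if its
    first attempt fails, regardless of how many re-attempts follow.
    """
    if fixation_ms % 50 != 0 or int(allowed_vrt_ms) % 50 != 0:
        raise ValueError("guided parameters must lie on the 50 ms grids")
    inventory = inventory or builtin_inventory("de")
    rng = _as_rng(rng_seed)
    plan = segment_text(text, capacity, inventory)

    records: list[SegmentRecord] = []
    time_ms = 0.0
    for seg in plan.segments:
        first_correct: Optional[bool] = None
        first_pos: Optional[int] = None
        attempts = 0
        while True:
            attempts += 1
            if attempts > max_attempts_per_segment:
                raise SessionAbortedError(
                    f"segment {seg.text!r} not read correctly after {attempts - 1} attempts"
                )
            compliant = rng.random() < reader.compliance
            if compliant:
                out = recognize(reader, seg.text, fixation_ms, allowed_vrt_ms, _trial_seed(rng))
                time_ms += fixation_ms + SACCADE_MS
            else:
                out = recognize(
                    reader, seg.text, SELF_FIXATION_MS, _self_vrt(reader), _trial_seed(rng)
                )
                time_ms += SELF_FIXATION_MS + SACCADE_MS
            if first_correct is None:
                first_correct = out.correct
                first_pos = out.error_position
            if out.correct:
                break
        records.append(
            SegmentRecord(
                seg.text, len(seg), fixation_ms, allowed_vrt_ms, bool(first_correct), first_pos
            )
        )
    return ReadingSession(mode=Mode.guided, records=records, total_time_ms=time_ms)


def error_reduction(errors_before: int, errors_after: int) -> float:
    """Percentage decrease in errors, ``100 * (before - after) / before``."""
    if errors_before <= 0:
        raise ValueError("errors_before must be positive")
    return 100.0 * (errors_before - errors_after) / errors_before


def hedges_g(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Hedges' g: standardized mean difference with small-sample correction.

    g = ((mean_a - mean_b) / s_pooled) * (1 - 3 / (4 (n_a + n_b) - 9)),
    where s_pooled is the df-weighted pooled sample standard deviation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var <= 0:
        raise ValueError("pooled variance is zero; effect size undefined")
    correction = 1.0 - 3.0 / (4.0 * (na + nb) - 9.0)
    return float((a.mean() - b.mean()) / math.sqrt(pooled_var) * correction)


@dataclass(frozen=True)
class PositionProfile:
    item_length: int
    counts: tuple[int, ...]
    chi2: float
    pvalue: float


def error_position_profile(
    sessions: Sequence[ReadingSession],
    item_length: Optional[int] = None,
) -> PositionProfile:
    """Per-position error frequencies with a chi-square uniformity statistic.

    Only letter-level errors (records with an error position) contribute.  If
    ``item_length`` is not given, the most frequent attempted length among
    errors is profiled.
    """
    positions: list[tuple[int, int]] = []
    for session in sessions:
        for rec in session.records:
            if not rec.correct and rec.error_position is not None:
                positions.append((rec.error_position, rec.attempted_length))
    if not positions:
        raise ValueError("no letter-level errors recorded")
    if item_length is None:
        lengths = [L for _, L in positions]
        item_length = max(set(lengths), key=lengths.count)
    selected = [p for p, L in positions if L == item_length]
    counts = [0] * item_length
    for p in selected:
        counts[p] += 1
    chi2, pvalue = stats.chisquare(counts)
    return PositionProfile(item_length, tuple(counts), float(chi2), float(pvalue))


def standard_therapy_text(
    rng_seed: Union[int, Generator] = 0,
    target_segments: int = 200,
    reference_capacity: int = 4,
    lexicon: Optional[Sequence[str]] = None,
) -> str:
    """Synthetic reading material for therapy experiments.

    Words are pronounceable pseudoword stand-ins for natural text (the
    simulator treats them as guessable familiar words) with the
    :data:`WORD_LENGTH_PROBS` length mix; words are appended until the text
    splits into ``target_segments`` segments at ``reference_capacity``.
    """
    rng = _as_rng(rng_seed)
    lex = list(lexicon) if lexicon is not None else builtin_lexicon("de")
    pools = {
        length: list(generate_list(length, 25, lex, rng))
        for length in WORD_LENGTH_PROBS
    }
    lengths = np.array(sorted(WORD_LENGTH_PROBS))
    probs = np.array([WORD_LENGTH_PROBS[k] for k in lengths], dtype=float)
    probs /= probs.sum()
    words: list[str] = []
    segments = 0
    while segments < target_segments:
        length = int(rng.choice(lengths, p=probs))
        words.append(pools[length][int(rng.integers(0, len(pools[length])))])
        segments += math.ceil(length / reference_capacity)
    return " ".join(words)


def cohort_experiment(
    n_readers: int = 50,
    rng_seed: int = 1,
    text: Optional[str] = None,
    preset: str = "low_vrt",
    config: Optional[StaircaseConfig] = None,
    inventory: Optional[ClusterInventory] = None,
) -> TherapyOutcome:
    """Full diagnose-then-treat experiment on a synthetic cohort.

    Each reader is diagnosed with the adaptive staircase; guided reading then
    enforces that reader's own recovered segment length, fixation time, and
    verbal reaction time.  Error counts are pooled across the cohort for the
    reduction percentage; Hedges' g compares per-reader unguided versus
    guided error counts (positive when guidance reduces errors).
    """
    config = config or StaircaseConfig()
    inventory = inventory or builtin_inventory("de")
    ss = SeedSequence(rng_seed)
    seed_cohort, seed_text, seed_sessions = ss.spawn(3)
    cohort = sample_cohort(n_readers, preset, default_rng(seed_cohort))
    if text is None:
        text = standard_therapy_text(default_rng(seed_text))

    rows = []
    session_rng = default_rng(seed_sessions)
    for idx, reader in enumerate(cohort):
        seed_diag, seed_ung, seed_gui = (
            int(session_rng.integers(0, 2**31 - 1)) for _ in range(3)
        )
        diag = run_staircase(reader, None, config, seed_diag)
        capacity = diag.ceiling if diag.ceiling is not None else 2
        fixation = diag.min_time_for_length.get(capacity, config.max_time_ms)
        vrt = diag.vrt_estimate_ms if diag.vrt_estimate_ms is not None else config.vrt_ceiling_ms
        unguided = simulate_unguided(reader, text, inventory, seed_ung)
        guided = simulate_guided(reader, text, capacity, fixation, float(vrt), inventory, seed_gui)
        rows.append(
            {
                "reader": idx,
                "ceiling_true": reader.ceiling,
                "ceiling_est": capacity,
                "vrt_true_ms": reader.required_vrt_ms,
                "vrt_est_ms": vrt,
                "fixation_ms": fixation,
                "errors_unguided": unguided.total_errors,
                "errors_guided": guided.total_errors,
                "segments_guided": guided.total_segments,
                "words_unguided": unguided.total_segments,
            }
        )
    per_reader = pd.DataFrame(rows)
    errors_u = int(per_reader["errors_unguided"].sum())
    errors_g = int(per_reader["errors_guided"].sum())
    return TherapyOutcome(
        errors_unguided=errors_u,
        errors_guided=errors_g,
        reduction_percent=error_reduction(errors_u, errors_g),
        hedges_g=hedges_g(per_reader["errors_unguided"], per_reader["errors_guided"]),
        per_reader=per_reader,
    )
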