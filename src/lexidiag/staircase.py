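"""Adaptive tachistoscopic pseudoword staircase.

The protocol presents lists of pronounceable pseudowords at controlled
fixation (presentation) times and recovers, per reader, the number of letters
recognizable at each fixation time and the verbal reaction time (VRT) the
reader needs.  It follows the clinical sequence: 3-letter items at 250 ms;
length increases while the criterion (at least 95% of a 20-item list correct)
is met; on a visual-capacity failure the fixation time increases in 50 ms
steps up to 500 ms; when a failed item is nonetheless spelled correctly, the
failure is attributed to pronunciation timing and the minimal sufficient VRT
is located by bisection on a 50 ms grid.

During capacity phases the allowed VRT is kept generous so pronunciation
timing never confounds the capacity estimate; the VRT sweep runs afterwards
at the reader's best (length, time) condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Optional, Protocol, Sequence, Union

from numpy.random import Generator, SeedSequence, default_rng

from ._errors import ConfigurationError, SessionAbortedError
from .pseudowords import builtin_lexicon, generate_list
from .reader import ReaderProfile, recognize, visible_window

__all__ = [
    "StaircaseConfig",
    "Phase",
    "TrialRecord",
    "DiagnosticResult",
    "Responder",
    "SimulatedResponder",
    "PseudowordSource",
    "list_criterion",
    "run_staircase",
    "CAUSE_TOO_MANY_LETTERS",
    "CAUSE_SHORT_FIXATION",
    "CAUSE_SHORT_VRT",
]

CAUSE_TOO_MANY_LETTERS = "trying to recognize too many letters"
CAUSE_SHORT_FIXATION = "too short a fixation time"
CAUSE_SHORT_VRT = "too short a verbal reaction time"

#: Slack added to the longest fixation time to form the "generous" allowed
#: VRT used during capacity phases.
GENEROUS_VRT_SLACK_MS = 3000


@dataclass(frozen=True)
class StaircaseConfig:
    """Protocol constants; defaults are the clinical values."""

    start_length: int = 3
    start_time_ms: int = 250
    time_step_ms: int = 50
    max_time_ms: int = 500
    list_size: int = 20
    pass_fraction: float = 0.95
    max_length: int = 8
    vrt_grid_ms: int = 50
    #: upper bound for the extended VRT search (covers extreme readers)
    vrt_ceiling_ms: int = 20000
    #: VRT above this clinic norm is reported as a cause of impairment
    vrt_norm_ms: int = 1000

    def __post_init__(self):
        if self.time_step_ms <= 0 or self.vrt_grid_ms <= 0:
            raise ConfigurationError("steps must be positive")
        if (self.max_time_ms - self.start_time_ms) % self.time_step_ms != 0:
            raise ConfigurationError(
                "start_time + k*time_step must reach max_time exactly"
            )
        if not 0 < self.pass_fraction <= 1:
            raise ConfigurationError("pass_fraction must lie in (0, 1]")
        if self.start_length < 1 or self.max_length < self.start_length:
            raise ConfigurationError("invalid length range")

    @property
    def generous_vrt_ms(self) -> int:
        return self.max_time_ms + GENEROUS_VRT_SLACK_MS

    @property
    def time_grid(self) -> tuple[int, ...]:
        return tuple(
            range(self.start_time_ms, self.max_time_ms + 1, self.time_step_ms)
        )


class Phase(str, Enum):
    length_sweep = "length_sweep"
    time_sweep = "time_sweep"
    spell_check = "spell_check"
    vrt_sweep = "vrt_sweep"


@dataclass(frozen=True)
class TrialRecord:
    item: str
    presentation_ms: int
    allowed_vrt_ms: float
    correct: bool
    phase: Phase


@dataclass
class DiagnosticResult:
    """Recovered reader parameters and attributed causes."""

    capacity_estimate: dict[int, int]
    min_time_for_length: dict[int, int]
    vrt_estimate_ms: Optional[int]
    trial_log: list[TrialRecord]
    causes: list[str]

    @property
    def ceiling(self) -> Optional[int]:
        return max(self.min_time_for_length) if self.min_time_for_length else None

    def to_dict(self) -> dict:
        return {
            "capacity_estimate": dict(self.capacity_estimate),
            "min_time_for_length": dict(self.min_time_for_length),
            "vrt_estimate_ms": self.vrt_estimate_ms,
            "causes": list(self.causes),
            "n_trials": len(self.trial_log),
        }


class Responder(Protocol):
    """One reader (simulated or interactive) answering one item at a time."""

    def attempt(self, item: str, presentation_ms: int, allowed_vrt_ms: float) -> bool:
        ...

    def spell_check(self, item: str, presentation_ms: int) -> bool:
        """Whether the item was visually recognized (probed by asking the
        child to spell/write it after a failed pronunciation)."""
        ...


class SimulatedResponder:
    """Responder backed by a :class:`ReaderProfile`.

    The spelling probe uses the visual-recognition ground truth: the item was
    seen iff its length is within capacity at the presentation time and the
    whole word falls into the seen window.
    """

    def __init__(self, reader: ReaderProfile, rng_seed: Union[int, Generator] = 0):
        self.reader = reader
        self._rng = rng_seed if isinstance(rng_seed, Generator) else default_rng(rng_seed)

    def attempt(self, item: str, presentation_ms: int, allowed_vrt_ms: float) -> bool:
        seed = int(self._rng.integers(0, 2**31 - 1))
        return recognize(self.reader, item, presentation_ms, allowed_vrt_ms, seed).correct

    def spell_check(self, item: str, presentation_ms: int) -> bool:
        n = len(item)
        visible = visible_window(n, (n - 1) // 2, self.reader.field_defect)
        return len(visible) == n and n <= self.reader.capacity(presentation_ms)


class PseudowordSource:
    """Supplies a fresh pseudoword list per administered list."""

    def __init__(
        self,
        lexicon: Optional[Sequence[str]] = None,
        rng_seed: Union[int, Generator] = 0,
    ):
        self.lexicon = list(lexicon) if lexicon is not None else builtin_lexicon("de")
        self._rng = rng_seed if isinstance(rng_seed, Generator) else default_rng(rng_seed)

    def __call__(self, item_length: int, list_size: int) -> list[str]:
        return list(generate_list(item_length, list_size, self.lexicon, self._rng))


def list_criterion(correct_count: int, list_size: int, pass_fraction: float) -> bool:
    """Pass iff at least ``ceil(pass_fraction * list_size)`` items were read
    correctly (19 of 20 at the default 95% criterion)."""
    if not 0 <= correct_count <= list_size:
        raise ValueError("correct_count must lie in [0, list_size]")
    return correct_count >= math.ceil(pass_fraction * list_size)


def _administer(
    responder: Responder,
    source: Callable[[int, int], Sequence[str]],
    length: int,
    time_ms: int,
    allowed_vrt_ms: float,
    phase: Phase,
    config: StaircaseConfig,
    log: list[TrialRecord],
) -> tuple[bool, list[str]]:
    """Run one full list; return (criterion met, failed items)."""
    try:
        items = source(length, config.list_size)
    except Exception as exc:  # pseudoword supply is part of the session
        raise SessionAbortedError(f"pseudoword source failed: {exc}", log) from exc
    failed = []
    correct = 0
    for item in items:
        try:
            ok = responder.attempt(item, time_ms, allowed_vrt_ms)
        except Exception as exc:
            raise SessionAbortedError(f"responder failed: {exc}", log) from exc
        log.append(TrialRecord(item, time_ms, float(allowed_vrt_ms), bool(ok), phase))
        if ok:
            correct += 1
        else:
            failed.append(item)
    return list_criterion(correct, config.list_size, config.pass_fraction), failed


def _vrt_bisect(
    responder: Responder,
    source: Callable[[int, int], Sequence[str]],
    length: int,
    time_ms: int,
    config: StaircaseConfig,
    log: list[TrialRecord],
) -> Optional[int]:
    """Minimal allowed VRT (on the grid) at which the list criterion holds at
    (length, time).  The search covers [one grid step, generous VRT]; if even
    the generous allowance fails, the upper bound doubles up to
    ``vrt_ceiling_ms`` before giving up."""
    grid = config.vrt_grid_ms

    def probe(v: int) -> bool:
        ok, _ = _administer(
            responder, source, length, time_ms, v, Phase.vrt_sweep, config, log
        )
        return ok

    lo = grid
    hi = config.generous_vrt_ms
    while not probe(hi):
        if hi >= config.vrt_ceiling_ms:
            return None
        hi = min(hi * 2, config.vrt_ceiling_ms)
    if probe(lo):
        return lo
    # invariant: fail at lo, pass at hi; bisect on the grid
    lo_i, hi_i = lo // grid, math.ceil(hi / grid)
    while hi_i - lo_i > 1:
        mid = (lo_i + hi_i) // 2
        if probe(mid * grid):
            hi_i = mid
        else:
            lo_i = mid
    return hi_i * grid


def run_staircase(
    reader: Union[ReaderProfile, Responder],
    lists: Union[Callable[[int, int], Sequence[str]], PseudowordSource, None],
    config: Optional[StaircaseConfig] = None,
    rng_seed: int = 0,
) -> DiagnosticResult:
    """Run the full adaptive session against a reader profile or responder.

    State machine: administer a list at the current (length, time) with a
    generous allowed VRT; on pass increase the length; on fail probe whether
    the first failed item was spelled correctly.  If it was not (a visual
    failure), increase the time; if it was, the failure is non-visual, so the
    minimal sufficient VRT is located and the same condition is retried once
    (a second non-visual failure at the same condition ends the session as
    VRT-limited).  The session ends when the length fails at the maximal time
    or the maximal length passes; a final VRT sweep at the best passing
    condition fills the VRT estimate if no mid-run sweep did.
    """
    config = config or StaircaseConfig()
    ss = SeedSequence(rng_seed)
    seed_responder, seed_source = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
    responder: Responder
    if isinstance(reader, ReaderProfile):
        responder = SimulatedResponder(reader, seed_responder)
    else:
        responder = reader
    source = lists if lists is not None else PseudowordSource(rng_seed=seed_source)

    log: list[TrialRecord] = []
    min_time_for_length: dict[int, int] = {}
    length = config.start_length
    time_ms = config.start_time_ms
    generous = float(config.generous_vrt_ms)
    vrt_estimate: Optional[int] = None
    vrt_limited = False
    retried: set[tuple[int, int]] = set()
    best: Optional[tuple[int, int]] = None

    phase = Phase.length_sweep
    while True:
        passed, failed_items = _administer(
            responder, source, length, time_ms, generous, phase, config, log
        )
        if passed:
            min_time_for_length[length] = time_ms
            best = (length, time_ms)
            if length >= config.max_length:
                break
            length += 1
            phase = Phase.length_sweep
            continue
        probe_item = failed_items[0]
        try:
            spelled = responder.spell_check(probe_item, time_ms)
        except Exception as exc:
            raise SessionAbortedError(f"spelling probe failed: {exc}", log) from exc
        log.append(
            TrialRecord(probe_item, time_ms, generous, bool(spelled), Phase.spell_check)
        )
        if spelled:
            # visually recognized yet mispronounced: a pronunciation-timing
            # (or lapse) failure, never a capacity failure
            if (length, time_ms) in retried:
                vrt_limited = True
                break
            retried.add((length, time_ms))
            found = _vrt_bisect(responder, source, length, time_ms, config, log)
            if found is None:
                vrt_limited = True
                break
            vrt_estimate = found
            generous = float(max(generous, found + 10 * config.vrt_grid_ms))
            continue  # retry the same condition with the updated allowance
        if time_ms >= config.max_time_ms:
            break
        time_ms += config.time_step_ms
        phase = Phase.time_sweep

    if best is not None and vrt_estimate is None and not vrt_limited:
        vrt_estimate = _vrt_bisect(responder, source, best[0], best[1], config, log)
        if vrt_estimate is None:
            vrt_limited = True

    capacity_estimate: dict[int, int] = {}
    for t in config.time_grid:
        passing = [L for L, mt in min_time_for_length.items() if mt <= t]
        if passing:
            capacity_estimate[t] = max(passing)

    causes: list[str] = []
    ceiling = max(min_time_for_length) if min_time_for_length else None
    if ceiling is None or ceiling < config.max_length:
        causes.append(CAUSE_TOO_MANY_LETTERS)
    if any(t > config.start_time_ms for t in min_time_for_length.values()) or (
        ceiling is None
    ):
        causes.append(CAUSE_SHORT_FIXATION)
    if vrt_limited or (vrt_estimate is not None and vrt_estimate > config.vrt_norm_ms):
        causes.append(CAUSE_SHORT_VRT)

    return DiagnosticResult(
        capacity_estimate=capacity_estimate,
        min_time_for_length=min_time_for_length,
        vrt_estimate_ms=vrt_estimate,
        trial_log=log,
        causes=causes,
    )
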