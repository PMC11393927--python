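"""Text segmentation, fixation planning, and gap detection.

To read without errors, text must be divided into word segments no longer
than the number of letters the reader can recognize simultaneously, segments
must follow one another without gaps, no segment boundary may fall inside an
unsplittable grapheme cluster, and saccade amplitudes must not exceed the
recognizable segment length.  Hypermetric saccades whose amplitudes exceed
the recognized window leave gaps of unread letters; :func:`find_gaps` makes
those gaps explicit.

Coordinates are 0-based, half-open, over the letters-only stream (whitespace
and punctuation are preserved for display but never counted).
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from ._errors import UnsegmentableTextError
from .pseudowords import ClusterInventory, cluster_spans, split_points

__all__ = ["Segment", "SegmentPlan", "GapReport", "segment_text", "plan_saccades", "find_gaps"]

_WORD_RE = re.compile(r"\w+", re.UNICODE)


def _words(text: str) -> list[str]:
    """Letter runs of ``text`` (digits and underscores dropped)."""
    out = []
    for token in _WORD_RE.findall(text):
        letters = "".join(ch for ch in token if unicodedata.category(ch).startswith("L"))
        if letters:
            out.append(letters)
    return out


@dataclass(frozen=True)
class Segment:
    start: int  # global letter-stream index, inclusive
    end: int  # exclusive
    text: str

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SegmentPlan:
    segments: tuple[Segment, ...]
    capacity: int
    fixation_targets: tuple[int, ...] = ()
    amplitudes: tuple[int, ...] = ()

    @property
    def stream(self) -> str:
        return "".join(s.text for s in self.segments)

    @property
    def stream_length(self) -> int:
        return self.segments[-1].end if self.segments else 0

    def to_dict(self) -> dict:
        return {
            "coordinates": "letters-only stream, 0-based, half-open",
            "capacity": self.capacity,
            "segments": [[s.start, s.end, s.text] for s in self.segments],
            "fixation_targets": list(self.fixation_targets),
            "amplitudes": list(self.amplitudes),
        }


@dataclass(frozen=True)
class GapReport:
    """Letters never covered by a fixated window, in stream order."""

    skipped: tuple[tuple[tuple[int, int], Optional[str]], ...]

    @property
    def empty(self) -> bool:
        return not self.skipped

    def texts(self) -> list[Optional[str]]:
        return [t for _, t in self.skipped]


def segment_text(
    text: str,
    capacity: int,
    inventory: ClusterInventory,
) -> SegmentPlan:
    """Split ``text`` into contiguous segments of at most ``capacity``
    letters, never cutting a grapheme cluster.

    Greedy left-to-right within each word: take up to ``capacity`` letters
    and shorten to the nearest allowed boundary if that would split a
    longest-match cluster.  Word boundaries are always allowed.  A cluster
    longer than ``capacity`` makes the input unsegmentable.
    """
    if capacity < 2:
        raise ValueError("capacity must be >= 2")
    segments: list[Segment] = []
    offset = 0
    for word in _words(text):
        for start, end in cluster_spans(word, inventory):
            if end - start > capacity:
                raise UnsegmentableTextError(word[start:end], capacity)
        allowed = split_points(word, inventory) | {len(word)}
        pos = 0
        while pos < len(word):
            k = min(capacity, len(word) - pos)
            while k > 0 and (pos + k) not in allowed:
                k -= 1
            if k == 0:  # unreachable once over-long clusters are rejected
                raise UnsegmentableTextError(word[pos : pos + capacity + 1], capacity)
            segments.append(Segment(offset + pos, offset + pos + k, word[pos : pos + k]))
            pos += k
        offset += len(word)
    return SegmentPlan(segments=tuple(segments), capacity=capacity)


def plan_saccades(plan: SegmentPlan) -> SegmentPlan:
    """Fill fixation targets (middle letter of each segment; even lengths
    fixate left of center) and saccade amplitudes (differences of consecutive
    global fixation indices)."""
    if not plan.segments:
        raise ValueError("plan has no segments")
    targets = tuple(s.start + (len(s) - 1) // 2 for s in plan.segments)
    amplitudes = tuple(b - a for a, b in zip(targets, targets[1:]))
    return replace(plan, fixation_targets=targets, amplitudes=amplitudes)


def find_gaps(
    fixations: Sequence[tuple[int, int]],
    stream_length: int,
    stream: Optional[str] = None,
) -> GapReport:
    """Report letters not covered by any fixated window.

    ``fixations`` are (global fixation index, window length) pairs with
    strictly increasing indices.  A window of length ``w`` fixated at ``c``
    covers ``[c - (w-1)//2, c + w//2]`` (same left-of-center convention as
    :func:`plan_saccades`).  If ``stream`` is given, the skipped text is
    attached to each gap.
    """
    indices = [c for c, _ in fixations]
    if any(b <= a for a, b in zip(indices, indices[1:])):
        raise ValueError("fixation indices must be strictly increasing")
    covered = [False] * stream_length
    for c, w in fixations:
        lo = max(0, c - (w - 1) // 2)
        hi = min(stream_length, c + w // 2 + 1)
        for i in range(lo, hi):
            covered[i] = True
    skipped: list[tuple[tuple[int, int], Optional[str]]] = []
    i = 0
    while i < stream_length:
        if covered[i]:
            i += 1
            continue
        j = i
        while j < stream_length and not covered[j]:
            j += 1
        skipped.append(((i, j), stream[i:j] if stream is not None else None))
        i = j
    return GapReport(skipped=tuple(skipped))
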