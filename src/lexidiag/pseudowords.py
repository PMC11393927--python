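"""Pronounceable pseudoword generation and grapheme-cluster bookkeeping.

Pseudowords are pronounceable non-words: every adjacent letter pair (bigram)
of a generated item is attested in a reference lexicon, but the item itself
is not a lexicon word.  Bigram attestation is the operational stand-in for
pronounceability; the studies this models state only the attestation
property, not a construction procedure.

Cluster inventories list multi-letter grapheme clusters that map to a single
phoneme ("sch", "ie", "eaux", ...) and must never be split across reading
segments.  Matching is longest-first, left to right.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence, Union

from numpy.random import Generator, default_rng

from ._errors import ConfigurationError, GenerationExhaustedError

__all__ = [
    "ClusterInventory",
    "PseudowordList",
    "builtin_inventory",
    "builtin_lexicon",
    "load_lexicon",
    "generate_list",
    "split_points",
    "cluster_spans",
]

_MAX_REJECTIONS = 100_000


@dataclass(frozen=True)
class ClusterInventory:
    """Unsplittable grapheme clusters for one language."""

    language: str
    clusters: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        normalized = frozenset(c.lower() for c in self.clusters)
        for c in normalized:
            if len(c) < 2:
                raise ConfigurationError(
                    f"cluster {c!r} must have at least two letters"
                )
        object.__setattr__(self, "clusters", normalized)

    @property
    def max_length(self) -> int:
        return max((len(c) for c in self.clusters), default=0)

    def by_length_desc(self) -> list[str]:
        return sorted(self.clusters, key=lambda c: (-len(c), c))


def builtin_inventory(language: str) -> ClusterInventory:
    """Shipped default inventory for ``language`` ('de', 'en' or 'fr').

    Entries beyond the canonical examples are editable defaults; callers can
    construct their own :class:`ClusterInventory` from config instead.
    """
    data = json.loads(
        resources.files("lexidiag.data").joinpath("clusters.json").read_text("utf-8")
    )
    if language not in data:
        raise KeyError(f"no builtin inventory for language {language!r}")
    return ClusterInventory(language=language, clusters=frozenset(data[language]))


def builtin_lexicon(language: str = "de") -> list[str]:
    """Small shipped reference lexicon (one word per line, lowercase)."""
    if language != "de":
        raise KeyError(f"no builtin lexicon for language {language!r}")
    text = resources.files("lexidiag.data").joinpath("lexicon_de.txt").read_text("utf-8")
    return [w.strip() for w in text.splitlines() if w.strip()]


def load_lexicon(path) -> list[str]:
    """Read a plain-text lexicon, one word per line (UTF-8)."""
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


@dataclass(frozen=True)
class PseudowordList:
    items: tuple[str, ...]
    item_length: int
    list_size: int = 20

    def __post_init__(self):
        if len(self.items) != self.list_size:
            raise ConfigurationError("items must contain exactly list_size entries")
        if any(len(w) != self.item_length for w in self.items):
            raise ConfigurationError("all items must have exactly item_length letters")

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)


def _bigram_transitions(lexicon: Sequence[str]) -> dict[str, tuple[str, ...]]:
    trans: dict[str, set[str]] = {}
    for word in lexicon:
        w = word.lower()
        for a, b in zip(w, w[1:]):
            trans.setdefault(a, set()).add(b)
    return {a: tuple(sorted(bs)) for a, bs in sorted(trans.items())}


def generate_list(
    item_length: int,
    list_size: int,
    lexicon: Sequence[str],
    rng_seed: Union[int, Generator],
    *,
    max_rejections: int = _MAX_REJECTIONS,
) -> PseudowordList:
    """Sample ``list_size`` distinct pseudowords of ``item_length`` letters.

    Items are built as bigram chains: a random attested bigram starts the
    chain, each further letter must form an attested bigram with its
    predecessor.  Chains that are lexicon members (case-folded), duplicates,
    or dead ends are rejected.  After ``max_rejections`` rejected chains a
    :class:`GenerationExhaustedError` is raised.
    """
    if item_length < 2:
        raise ValueError("item_length must be >= 2")
    if list_size < 1:
        raise ValueError("list_size must be >= 1")
    if not lexicon:
        raise ValueError("lexicon must be non-empty")
    rng = rng_seed if isinstance(rng_seed, Generator) else default_rng(rng_seed)
    trans = _bigram_transitions(lexicon)
    starts = tuple(sorted(trans))
    if not starts:
        raise GenerationExhaustedError("lexicon contains no bigrams")
    forbidden = {w.lower() for w in lexicon}

    items: list[str] = []
    seen: set[str] = set()
    rejections = 0
    while len(items) < list_size:
        chars = [starts[rng.integers(0, len(starts))]]
        ok = True
        for _ in range(item_length - 1):
            nxt = trans.get(chars[-1])
            if not nxt:
                ok = False
                break
            chars.append(nxt[rng.integers(0, len(nxt))])
        candidate = "".join(chars)
        if ok and candidate not in forbidden and candidate not in seen:
            items.append(candidate)
            seen.add(candidate)
            continue
        rejections += 1
        if rejections >= max_rejections:
            raise GenerationExhaustedError(
                f"could not assemble {list_size} pseudowords of length "
                f"{item_length} after {rejections} rejections"
            )
    return PseudowordList(items=tuple(items), item_length=item_length, list_size=list_size)


def cluster_spans(word: str, inventory: ClusterInventory) -> list[tuple[int, int]]:
    """Longest-match cluster occurrences in ``word`` as half-open (start, end)
    spans, scanned left to right; overlapping occurrences resolve leftmost."""
    w = word.lower()
    ordered = inventory.by_length_desc()
    spans: list[tuple[int, int]] = []
    i = 0
    while i < len(w):
        for cluster in ordered:
            if w.startswith(cluster, i):
                spans.append((i, i + len(cluster)))
                i += len(cluster)
                break
        else:
            i += 1
    return spans


def split_points(word: str, inventory: ClusterInventory) -> set[int]:
    """Internal boundary positions (between index ``i-1`` and ``i``) at which
    ``word`` may be split without cutting a grapheme cluster."""
    if not word:
        raise ValueError("word must be non-empty")
    allowed = set(range(1, len(word)))
    for start, end in cluster_spans(word, inventory):
        allowed -= set(range(start + 1, end))
    return allowed
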