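"""Necessary/sufficient condition classification over monotone outcome
oracles, and cause attribution for reading failure.

The conceptual model: let the *universe* be the finite set of conditions
under which a person reads flawlessly (at some performance level L).  An
*oracle* maps each subset of met conditions to pass/fail and is expected to
be monotone (meeting an extra condition never breaks reading).  The engine
extracts, by exhaustive enumeration, the minimal clauses (prime implicates)
of the pass-function:

* singleton clauses are *irreplaceable necessary conditions* (the set Γ,
  ``gamma``): remove one and reading fails no matter what else holds;
* multi-element clauses are sets of *replaceable sufficient conditions*
  (Λ1..Λp, ``lambda_sets``): the conditions inside one set are
  interchangeable, but at least one per set must be met;
* conditions in no clause are *superfluous*: they never change the outcome.

A classification is *canonical* when the multi-element clauses are pairwise
disjoint and the conjunctive form (⋀Γ) ∧ (⋀i ⋁Λi) reproduces the oracle on
every subset.  Cause attribution is only defined on canonical
classifications: an unmet Γ member is an irreplaceable necessary cause, a Λ
set none of whose members is met is a replaceable sufficient cause (reported
at set level), and an unmet superfluous condition is not a cause.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations
from typing import Callable, Iterable, Mapping, Optional, Sequence

from ._errors import (
    ConfigurationError,
    NonCanonicalClassificationError,
    NonMonotoneOracleError,
)

__all__ = [
    "EXHAUSTIVE_LIMIT",
    "ConditionUniverse",
    "Oracle",
    "CausalClassification",
    "CauseCategory",
    "CauseReport",
    "check_monotone",
    "extract_classification",
    "diagnose_causes",
]

#: Hard cap on the universe size for exhaustive enumeration (2^n subsets).
EXHAUSTIVE_LIMIT = 20


@dataclass(frozen=True)
class ConditionUniverse:
    """Ordered set of condition identifiers with human-readable labels."""

    conditions: tuple[str, ...]
    labels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "conditions", tuple(self.conditions))
        if len(set(self.conditions)) != len(self.conditions):
            raise ConfigurationError("condition identifiers must be unique")
        if len(self.conditions) > EXHAUSTIVE_LIMIT:
            raise ConfigurationError(
                f"exhaustive mode supports at most {EXHAUSTIVE_LIMIT} conditions"
            )

    def subsets(self) -> Iterable[frozenset[str]]:
        for r in range(len(self.conditions) + 1):
            for combo in combinations(self.conditions, r):
                yield frozenset(combo)

    def label(self, identifier: str) -> str:
        return dict(self.labels).get(identifier, identifier)


class Oracle:
    """Outcome function over subsets of met conditions (True = pass)."""

    def __init__(self, fn: Callable[[frozenset[str]], bool]):
        self._fn = fn

    def __call__(self, met: Iterable[str]) -> bool:
        return bool(self._fn(frozenset(met)))

    @classmethod
    def from_callable(cls, fn: Callable[[frozenset[str]], bool]) -> "Oracle":
        return cls(fn)

    @classmethod
    def from_score(
        cls, score: Callable[[frozenset[str]], float], level: float
    ) -> "Oracle":
        """Threshold a numeric performance score at level L."""
        return cls(lambda met: score(met) >= level)

    @classmethod
    def from_truth_table(cls, rows: Sequence[Mapping]) -> "Oracle":
        """Rows of ``{"met": [...], "outcome": "pass"|"fail"}`` covering every
        subset that will ever be queried."""
        table = {
            frozenset(row["met"]): str(row["outcome"]).lower() in ("pass", "true", "1")
            for row in rows
        }

        def fn(met: frozenset[str]) -> bool:
            if met not in table:
                raise KeyError(f"truth table has no row for {sorted(met)}")
            return table[met]

        return cls(fn)

    @classmethod
    def from_formula(
        cls,
        gamma: Iterable[str],
        lambda_sets: Iterable[Iterable[str]],
    ) -> "Oracle":
        g = frozenset(gamma)
        lams = [frozenset(l) for l in lambda_sets]
        return cls(lambda met: g <= met and all(met & lam for lam in lams))

    @classmethod
    def from_json(cls, text: str) -> "Oracle":
        doc = json.loads(text)
        if "truth_table" in doc:
            return cls.from_truth_table(doc["truth_table"])
        if "gamma" in doc or "lambda" in doc:
            return cls.from_formula(doc.get("gamma", []), doc.get("lambda", []))
        raise ConfigurationError(
            "oracle JSON must contain either 'truth_table' or 'gamma'/'lambda'"
        )


@dataclass(frozen=True)
class CausalClassification:
    gamma: frozenset[str]
    lambda_sets: tuple[frozenset[str], ...]
    superfluous: frozenset[str]
    canonical: bool
    witness: Optional[frozenset[str]] = None

    def __post_init__(self):
        groups = [self.gamma, *self.lambda_sets, self.superfluous]
        for a, b in combinations(range(len(groups)), 2):
            if groups[a] & groups[b]:
                raise ConfigurationError("classification groups must be disjoint")
        for lam in self.lambda_sets:
            if len(lam) < 2:
                raise ConfigurationError(
                    "every interchangeable set must contain more than one condition"
                )

    def predicted_pass(self, met: Iterable[str]) -> bool:
        met = frozenset(met)
        return self.gamma <= met and all(met & lam for lam in self.lambda_sets)

    def to_dict(self) -> dict:
        return {
            "gamma": sorted(self.gamma),
            "lambda_sets": [sorted(l) for l in self.lambda_sets],
            "superfluous": sorted(self.superfluous),
            "canonical": self.canonical,
            "witness": sorted(self.witness) if self.witness is not None else None,
        }


class CauseCategory(str, Enum):
    irreplaceable_necessary_cause = "irreplaceable_necessary_cause"
    replaceable_sufficient_cause = "replaceable_sufficient_cause"
    not_a_cause = "not_a_cause"


@dataclass(frozen=True)
class CauseReport:
    """Per unmet condition (Γ members, superfluous) or unmet set (Λ sets):
    its causal category for the observed reading failure."""

    entries: tuple[tuple[frozenset[str], CauseCategory], ...]
    predicted_fail: bool

    def causes(self) -> list[frozenset[str]]:
        return [
            group
            for group, cat in self.entries
            if cat is not CauseCategory.not_a_cause
        ]

    def to_dict(self) -> dict:
        return {
            "entries": [
                {"conditions": sorted(g), "category": c.value} for g, c in self.entries
            ],
            "predicted_fail": self.predicted_fail,
        }


def check_monotone(
    universe: ConditionUniverse, oracle: Oracle
) -> tuple[bool, Optional[tuple[frozenset[str], frozenset[str]]]]:
    """Exhaustively verify that adding a met condition never turns a pass
    into a fail; on violation return the witnessing (subset, superset) pair."""
    for met in universe.subsets():
        if not oracle(met):
            continue
        for extra in universe.conditions:
            if extra in met:
                continue
            larger = met | {extra}
            if not oracle(larger):
                return False, (met, larger)
    return True, None


def _minimal_clauses(
    universe: ConditionUniverse, oracle: Oracle
) -> list[frozenset[str]]:
    """Prime implicates of the monotone pass-function: minimal condition sets
    C such that reading fails whenever no element of C is met.  Equivalently
    (by monotonicity) the minimal C with oracle(universe \\ C) = fail."""
    full = frozenset(universe.conditions)
    failing: list[frozenset[str]] = [
        c for c in universe.subsets() if not oracle(full - c)
    ]
    minimal = []
    for c in failing:
        if not any(other < c for other in failing):
            minimal.append(c)
    return sorted(minimal, key=lambda c: (len(c), sorted(c)))


def _merge_overlapping(sets: Sequence[frozenset[str]]) -> list[frozenset[str]]:
    merged: list[set[str]] = []
    for s in sets:
        hits = [m for m in merged if m & s]
        for m in hits:
            merged.remove(m)
        merged.append(set(s).union(*hits) if hits else set(s))
    return [frozenset(m) for m in merged]


def extract_classification(
    universe: ConditionUniverse, oracle: Oracle
) -> CausalClassification:
    """Classify every condition as irreplaceable necessary (Γ), member of an
    interchangeable sufficient set (Λi), or superfluous.

    Non-monotone oracles are rejected.  When the multi-element clauses
    overlap, the pass-function has no disjoint conjunctive form: the clauses
    are merged into disjoint candidate sets, ``canonical`` is False, and
    ``witness`` holds a subset on which the merged form disagrees with the
    oracle (if any).
    """
    ok, pair = check_monotone(universe, oracle)
    if not ok:
        raise NonMonotoneOracleError(*pair)

    clauses = _minimal_clauses(universe, oracle)
    if any(len(c) == 0 for c in clauses):
        # the oracle fails even when everything is met: no conjunctive form
        return CausalClassification(
            gamma=frozenset(),
            lambda_sets=(),
            superfluous=frozenset(universe.conditions),
            canonical=False,
            witness=frozenset(universe.conditions),
        )

    gamma = frozenset(c for clause in clauses if len(clause) == 1 for c in clause)
    multi = [c for c in clauses if len(c) >= 2]
    disjoint = all(not (a & b) for a, b in combinations(multi, 2))
    lambda_sets = multi if disjoint else _merge_overlapping(multi)
    in_some = gamma | frozenset().union(*lambda_sets) if lambda_sets else gamma
    superfluous = frozenset(universe.conditions) - in_some

    candidate = CausalClassification(
        gamma=gamma,
        lambda_sets=tuple(sorted(lambda_sets, key=lambda l: sorted(l))),
        superfluous=superfluous,
        canonical=True,  # provisional; verified exhaustively below
    )
    witness = None
    for met in universe.subsets():
        if candidate.predicted_pass(met) != oracle(met):
            witness = met
            break
    canonical = disjoint and witness is None
    if canonical:
        return candidate
    return CausalClassification(
        gamma=gamma,
        lambda_sets=candidate.lambda_sets,
        superfluous=superfluous,
        canonical=False,
        witness=witness,
    )


def diagnose_causes(
    classification: CausalClassification, met_conditions: Iterable[str]
) -> CauseReport:
    """Attribute causes of reading failure given the conditions actually met.

    Only canonical classifications support attribution.  Reading is predicted
    to fail iff at least one cause is reported.
    """
    if not classification.canonical:
        raise NonCanonicalClassificationError(
            "cause attribution requires a canonical classification"
        )
    met = frozenset(met_conditions)
    entries: list[tuple[frozenset[str], CauseCategory]] = []
    for cond in sorted(classification.gamma):
        if cond not in met:
            entries.append(
                (frozenset([cond]), CauseCategory.irreplaceable_necessary_cause)
            )
    for lam in classification.lambda_sets:
        if not lam & met:
            entries.append((lam, CauseCategory.replaceable_sufficient_cause))
    for cond in sorted(classification.superfluous):
        if cond not in met:
            entries.append((frozenset([cond]), CauseCategory.not_a_cause))
    predicted_fail = any(
        cat is not CauseCategory.not_a_cause for _, cat in entries
    )
    return CauseReport(entries=tuple(entries), predicted_fail=predicted_fail)
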