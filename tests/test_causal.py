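"""Causal-condition engine: monotonicity, classification, attribution."""

from itertools import combinations

import pytest
from numpy.random import default_rng

from lexidiag._errors import (
    NonCanonicalClassificationError,
    NonMonotoneOracleError,
)
from lexidiag.causal import (
    CauseCategory,
    ConditionUniverse,
    Oracle,
    check_monotone,
    diagnose_causes,
    extract_classification,
)

# The worked clinical example: pseudowords are readable when letter size OR
# presentation time is sufficient, AND the background is white, yellow, or
# blue (the backgrounds are interchangeable).
WORKED_UNIVERSE = ConditionUniverse(
    conditions=("size5mm", "time400ms", "bg_white", "bg_yellow", "bg_blue")
)
WORKED_ORACLE = Oracle.from_formula(
    gamma=[], lambda_sets=[["size5mm", "time400ms"], ["bg_white", "bg_yellow", "bg_blue"]]
)


def random_monotone_oracle(conditions, rng) -> Oracle:
    """Random monotone pass-function: union of up-sets of a few random
    minimal passing subsets."""
    k = int(rng.integers(1, 4))
    minimal = [
        frozenset(c for c in conditions if rng.random() < 0.5) for _ in range(k)
    ]
    return Oracle(lambda met: any(m <= met for m in minimal))


class TestCheckMonotone:
    def test_constant_pass_is_monotone(self):
        ok, witness = check_monotone(WORKED_UNIVERSE, Oracle(lambda met: True))
        assert ok and witness is None

    def test_parity_oracle_caught_with_witness(self):
        universe = ConditionUniverse(conditions=("a", "b", "c"))
        oracle = Oracle(lambda met: len(met) % 2 == 0)
        ok, (smaller, larger) = check_monotone(universe, oracle)
        assert not ok
        assert smaller < larger and oracle(smaller) and not oracle(larger)

    def test_worked_example_is_monotone(self):
        ok, _ = check_monotone(WORKED_UNIVERSE, WORKED_ORACLE)
        assert ok


class TestExtractClassification:
    def test_worked_example_yields_two_interchangeable_sets(self):
        result = extract_classification(WORKED_UNIVERSE, WORKED_ORACLE)
        assert result.gamma == frozenset()
        assert sorted(sorted(l) for l in result.lambda_sets) == [
            ["bg_blue", "bg_white", "bg_yellow"],
            ["size5mm", "time400ms"],
        ]
        assert result.superfluous == frozenset()
        assert result.canonical

    def test_pure_conjunction_is_all_gamma(self):
        universe = ConditionUniverse(conditions=("c1", "c2", "c3"))
        oracle = Oracle(lambda met: {"c1", "c2", "c3"} <= met)
        result = extract_classification(universe, oracle)
        assert result.gamma == {"c1", "c2", "c3"}
        assert result.lambda_sets == ()
        assert result.superfluous == frozenset()
        assert result.canonical

    def test_superfluous_conditions_detected(self):
        universe = ConditionUniverse(conditions=("a", "b", "noise"))
        oracle = Oracle(lambda met: "a" in met and "b" in met)
        result = extract_classification(universe, oracle)
        assert result.superfluous == {"noise"}

    def test_non_monotone_oracle_rejected(self):
        universe = ConditionUniverse(conditions=("a", "b"))
        with pytest.raises(NonMonotoneOracleError):
            extract_classification(universe, Oracle(lambda met: len(met) % 2 == 0))

    def test_random_oracles_reconstruct_or_witness(self):
        """Over 200 random monotone oracles on up to 6 conditions: whenever
        the classification is canonical its conjunctive form reproduces the
        oracle on every subset; whenever it is not, any witness is a genuine
        disagreement."""
        rng = default_rng(31)
        for _ in range(200):
            n = int(rng.integers(2, 7))
            conditions = tuple(f"c{i}" for i in range(n))
            universe = ConditionUniverse(conditions=conditions)
            oracle = random_monotone_oracle(conditions, rng)
            result = extract_classification(universe, oracle)
            everything = (
                result.gamma
                | frozenset().union(*result.lambda_sets, frozenset())
                | result.superfluous
            )
            assert everything == frozenset(conditions)
            if result.canonical:
                for met in universe.subsets():
                    assert result.predicted_pass(met) == oracle(met)
            elif result.witness is not None:
                assert result.predicted_pass(result.witness) != oracle(result.witness)

    def test_classification_invariant_under_condition_relabelling(self):
        base = extract_classification(WORKED_UNIVERSE, WORKED_ORACLE)
        permuted_universe = ConditionUniverse(
            conditions=("bg_blue", "bg_white", "time400ms", "size5mm", "bg_yellow")
        )
        permuted = extract_classification(permuted_universe, WORKED_ORACLE)
        assert set(base.lambda_sets) == set(permuted.lambda_sets)
        assert base.gamma == permuted.gamma


class TestDiagnoseCauses:
    @pytest.fixture
    def classification(self):
        return extract_classification(WORKED_UNIVERSE, WORKED_ORACLE)

    def test_one_condition_per_set_suffices(self, classification):
        report = diagnose_causes(classification, {"time400ms", "bg_white"})
        assert not report.predicted_fail
        assert report.causes() == []

    def test_missing_background_set_is_replaceable_sufficient_cause(self, classification):
        report = diagnose_causes(classification, {"size5mm", "time400ms"})
        causes = report.causes()
        assert causes == [frozenset({"bg_blue", "bg_white", "bg_yellow"})]
        assert report.predicted_fail
        categories = dict(report.entries)
        assert (
            categories[frozenset({"bg_blue", "bg_white", "bg_yellow"})]
            is CauseCategory.replaceable_sufficient_cause
        )

    def test_everything_met_means_no_causes(self, classification):
        report = diagnose_causes(classification, WORKED_UNIVERSE.conditions)
        assert not report.predicted_fail and report.causes() == []

    def test_unmet_gamma_is_irreplaceable_necessary_cause(self):
        universe = ConditionUniverse(conditions=("fix", "seg", "extra"))
        oracle = Oracle(lambda met: {"fix", "seg"} <= met)
        classification = extract_classification(universe, oracle)
        report = diagnose_causes(classification, {"seg"})
        categories = dict(report.entries)
        assert categories[frozenset({"fix"})] is CauseCategory.irreplaceable_necessary_cause
        assert categories[frozenset({"extra"})] is CauseCategory.not_a_cause

    def test_restoring_a_gamma_condition_flips_fail_to_pass(self):
        universe = ConditionUniverse(conditions=("fix", "seg"))
        oracle = Oracle(lambda met: {"fix", "seg"} <= met)
        classification = extract_classification(universe, oracle)
        assert diagnose_causes(classification, {"seg"}).predicted_fail
        assert not diagnose_causes(classification, {"seg", "fix"}).predicted_fail

    def test_cause_report_matches_oracle_for_all_subsets(self):
        """Predicted failure iff at least one cause, on every subset, for a
        spread of canonical oracles."""
        rng = default_rng(5)
        for _ in range(50):
            n = int(rng.integers(2, 7))
            conditions = tuple(f"c{i}" for i in range(n))
            universe = ConditionUniverse(conditions=conditions)
            oracle = random_monotone_oracle(conditions, rng)
            classification = extract_classification(universe, oracle)
            if not classification.canonical:
                continue
            for met in universe.subsets():
                report = diagnose_causes(classification, met)
                assert report.predicted_fail == (not oracle(met))

    def test_non_canonical_classification_refused(self):
        universe = ConditionUniverse(conditions=("a", "b", "c"))
        # (a or b) and (b or c): overlapping interchangeable sets
        oracle = Oracle(lambda met: bool(met & {"a", "b"}) and bool(met & {"b", "c"}))
        classification = extract_classification(universe, oracle)
        assert not classification.canonical
        with pytest.raises(NonCanonicalClassificationError):
            diagnose_causes(classification, {"a"})


def test_oracle_from_truth_table_and_formula_agree():
    conditions = ("x", "y")
    formula = Oracle.from_formula(gamma=["x"], lambda_sets=[])
    rows = [
        {"met": sorted(met), "outcome": "pass" if formula(met) else "fail"}
        for met in ConditionUniverse(conditions=conditions).subsets()
    ]
    table = Oracle.from_truth_table(rows)
    for met in ConditionUniverse(conditions=conditions).subsets():
        assert table(met) == formula(met)
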