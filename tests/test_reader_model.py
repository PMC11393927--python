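"""Virtual-reader model: visual windows, recognition, cohort sampling."""

import numpy as np
import pytest
from scipy import stats

from lexidiag._errors import ConfigurationError
from lexidiag.reader import (
    TIME_GRID_MS,
    Compensation,
    DefectSide,
    ReaderProfile,
    VisualFieldDefect,
    letters_recognized,
    load_cohort_jsonl,
    recognize,
    sample_cohort,
    save_cohort_jsonl,
    visible_window,
)

RIGHT_FOVEAL = VisualFieldDefect(side="right", foveal_involvement=True)
LEFT_FOVEAL = VisualFieldDefect(side="left", foveal_involvement=True)


class TestVisibleWindow:
    def test_no_defect_sees_everything(self):
        assert visible_window(5, 2, None) == frozenset(range(5))

    def test_right_foveal_defect_masks_word_end(self):
        assert visible_window(6, 2, RIGHT_FOVEAL) == frozenset({0, 1, 2})

    def test_left_foveal_defect_masks_word_beginning(self):
        assert visible_window(6, 2, LEFT_FOVEAL) == frozenset({2, 3, 4, 5})

    def test_gaze_to_end_compensation_restores_full_window(self):
        defect = VisualFieldDefect("right", True, "gaze_to_end")
        for fixation in range(6):
            assert visible_window(6, fixation, defect) == frozenset(range(6))

    def test_non_foveal_defect_spares_central_field(self):
        defect = VisualFieldDefect("right", foveal_involvement=False)
        assert visible_window(6, 2, defect) == frozenset(range(6))

    def test_invalid_fixation_rejected(self):
        with pytest.raises(ValueError):
            visible_window(4, 4, None)

    @pytest.mark.parametrize(
        "side,comp",
        [("left", "gaze_to_end"), ("right", "gaze_to_beginning")],
    )
    def test_incompatible_compensation_rejected(self, side, comp):
        with pytest.raises(ConfigurationError):
            VisualFieldDefect(side=side, compensation=comp)

    def test_compensation_window_is_superset_for_all_lengths(self):
        """Compensatory gaze never loses letters relative to no compensation."""
        pairs = [
            (VisualFieldDefect("right", True), VisualFieldDefect("right", True, "gaze_to_end")),
            (VisualFieldDefect("left", True), VisualFieldDefect("left", True, "gaze_to_beginning")),
        ]
        for plain, compensated in pairs:
            for n in range(1, 13):
                for fix in range(n):
                    assert visible_window(n, fix, plain) <= visible_window(n, fix, compensated)


class TestRecognize:
    def test_all_conditions_met_reads_correctly(self, example_reader):
        out = recognize(example_reader, "blumen", 500, 1500, rng_seed=0)
        assert out.correct and out.error_position is None
        assert out.vrt_used_ms == 1400.0

    def test_short_vrt_blocks_pronunciation(self, example_reader):
        out = recognize(example_reader, "blumen", 500, 1200, rng_seed=0)
        assert not out.correct
        assert out.error_position is None  # premature pronunciation, no letter error
        assert out.vrt_used_ms == 1200.0

    def test_capacity_exceeded_fails_with_letter_error(self, example_reader):
        out = recognize(example_reader, "blumen", 250, 1500, rng_seed=0)
        assert not out.correct and out.error_position in range(6)

    def test_deterministic_given_seed(self, example_reader):
        reader = example_reader.with_(lapse_rate=0.05)
        runs = [recognize(reader, "haus", 500, 1500, rng_seed=42) for _ in range(3)]
        assert runs[0] == runs[1] == runs[2]

    def test_no_stochastic_term_means_certainty(self, example_reader):
        results = [
            recognize(example_reader, "wald", 400, 2000, rng_seed=i).correct
            for i in range(10_000)
        ]
        assert all(results)

    def test_lapse_frequency_matches_rate(self, example_reader):
        p = 0.05
        reader = example_reader.with_(lapse_rate=p)
        errors = sum(
            not recognize(reader, "wald", 400, 2000, rng_seed=i).correct
            for i in range(10_000)
        )
        tol = 3 * np.sqrt(p * (1 - p) / 10_000)
        assert abs(errors / 10_000 - p) < tol

    def test_error_positions_uniform_under_capacity_errors(self, example_reader):
        """No positional gradient and no crowding: conditional on a capacity
        error, every letter position is hit equally often."""
        positions = []
        i = 0
        while len(positions) < 10_000:
            out = recognize(example_reader, "abcde", 250, 2000, rng_seed=i)
            i += 1
            assert not out.correct  # 5 letters > capacity 3 at 250 ms
            positions.append(out.error_position)
        counts = np.bincount(positions, minlength=5)
        _, pvalue = stats.chisquare(counts)
        assert pvalue > 0.001
        # the word-final position is no more error prone than interior ones
        assert counts[-1] <= counts[1:4].mean() + 3 * np.sqrt(counts.mean())

    def test_grapheme_confusion_flips_confusable_letters(self):
        reader = ReaderProfile(
            capacity_by_time={t: 8 for t in TIME_GRID_MS},
            required_vrt_ms=1.0,
            grapheme_confusions=frozenset([frozenset("pq"), frozenset("bd")]),
        )
        outcomes = [recognize(reader, "pad", 500, 100, rng_seed=i) for i in range(4000)]
        errs = [o for o in outcomes if not o.correct]
        # two confusable letters at 0.5 each: error rate 1 - 0.25
        assert abs(len(errs) / 4000 - 0.75) < 0.03
        assert all(o.error_position in (0, 2) for o in errs)

    def test_empty_word_rejected(self, example_reader):
        with pytest.raises(ValueError):
            recognize(example_reader, "", 500, 1500, rng_seed=0)


class TestProfileInvariants:
    def test_capacity_clamps_down_to_grid(self, example_reader):
        assert example_reader.capacity(437) == example_reader.capacity(400) == 5

    def test_capacity_below_grid_rejected(self, example_reader):
        with pytest.raises(ValueError):
            example_reader.capacity(200)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"capacity_by_time": {250: 4, 500: 3}},  # non-monotone
            {"capacity_by_time": {250: 3, 500: 9}},  # ceiling above 8
            {"required_vrt_ms": 0.0},
            {"lapse_rate": 0.2},
            {"compliance": 1.5},
        ],
    )
    def test_invalid_profiles_rejected(self, kwargs):
        base = dict(capacity_by_time={250: 3, 500: 6}, required_vrt_ms=1000.0)
        base.update(kwargs)
        with pytest.raises(ConfigurationError):
            ReaderProfile(**base)

    def test_letters_recognized_limited_by_capacity_and_window(self, example_reader):
        assert letters_recognized(example_reader, "blumen", 500) == 6
        assert letters_recognized(example_reader, "blumen", 250) == 3
        hemianopic = example_reader.with_(field_defect=RIGHT_FOVEAL)
        assert letters_recognized(hemianopic, "blumen", 500) == 3  # fixation at index 2

    def test_yaml_json_round_trip(self, example_reader):
        reader = example_reader.with_(
            field_defect=VisualFieldDefect("right", True, "gaze_to_end"),
            grapheme_confusions=frozenset([frozenset("mn")]),
        )
        assert ReaderProfile.from_yaml(reader.to_yaml()) == reader
        assert ReaderProfile.from_json(reader.to_json()) == reader


class TestSampleCohort:
    def test_vrt_mean_matches_truncated_normal(self):
        cohort = sample_cohort(10_000, "low_vrt", rng_seed=1)
        vrts = np.array([r.required_vrt_ms for r in cohort])
        a = (200.0 - 1316.0) / 712.0
        expected = stats.truncnorm.mean(a, np.inf, loc=1316.0, scale=712.0)
        se = stats.truncnorm.std(a, np.inf, loc=1316.0, scale=712.0) / np.sqrt(10_000)
        assert abs(vrts.mean() - expected) < 3 * se
        assert vrts.min() >= 200.0

    def test_max_ceiling_is_six_in_large_cohort(self):
        cohort = sample_cohort(500, "low_vrt", rng_seed=1)
        assert max(r.ceiling for r in cohort) == 6

    def test_single_profile_satisfies_invariants(self):
        (profile,) = sample_cohort(1, "high_vrt", rng_seed=7)
        caps = [profile.capacity_by_time[t] for t in TIME_GRID_MS]
        assert caps == sorted(caps)
        assert profile.ceiling in {3, 4, 5, 6}
        assert profile.compliance == 0.9 and profile.lapse_rate == 0.02

    def test_invalid_preset_and_size_rejected(self):
        with pytest.raises(ValueError):
            sample_cohort(0, "low_vrt", 1)
        with pytest.raises(ValueError):
            sample_cohort(5, "medium", 1)

    def test_jsonl_round_trip(self, tmp_path):
        cohort = sample_cohort(10, "low_vrt", rng_seed=3)
        path = tmp_path / "cohort.jsonl"
        save_cohort_jsonl(cohort, path)
        assert load_cohort_jsonl(path) == cohort
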