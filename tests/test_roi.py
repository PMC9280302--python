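"""Lateralization, normalization, frame averaging, hematoma course, filters."""
import numpy as np
import pandas as pd
import pytest

from lesionet import (
    HematomaSeries,
    InsufficientDataError,
    SchemaError,
    ValidationError,
    apply_inclusion_filters,
    average_frames,
    hematoma_course,
    lateralization_index,
    make_hematoma_series,
    normalize_by_whole_brain,
    percent_change,
    suvw_normalize,
)


class TestLateralization:
    def test_symmetric_brain_gives_unit_indices(self, tiny_atlas, table_builder):
        vals = np.tile([50.0, 50.0, 60.0, 60.0], (4, 1))
        table = table_builder(vals, tiny_atlas)
        lat = lateralization_index(table, tiny_atlas)
        assert np.allclose(lat.to_numpy(), 1.0)
        assert list(lat.columns) == ["striatum", "thalamus"]

    def test_hand_division(self, tiny_atlas, table_builder):
        # lesion side right: ipsi = *_r columns
        vals = np.array([[50.0, 33.0, 60.0, 60.0]])
        table = table_builder(vals, tiny_atlas, groups=["ich"])
        lat = lateralization_index(table, tiny_atlas)
        assert lat["striatum"].iloc[0] == pytest.approx(0.66)

    def test_zero_ipsilateral_allowed_zero_contralateral_not(
        self, tiny_atlas, table_builder
    ):
        table = table_builder([[50.0, 0.0, 60.0, 60.0]], tiny_atlas, groups=["ich"])
        assert lateralization_index(table, tiny_atlas)["striatum"].iloc[0] == 0.0
        bad = table_builder([[0.0, 50.0, 60.0, 60.0]], tiny_atlas, groups=["ich"])
        with pytest.raises(ValidationError, match="striatum"):
            lateralization_index(bad, tiny_atlas)

    def test_reciprocal_under_lesion_side_swap(self, atlas, table_builder):
        rng = np.random.default_rng(3)
        table = table_builder(rng.lognormal(3, 0.3, size=(6, 18)), atlas)
        right = lateralization_index(table, atlas)
        left = lateralization_index(table, atlas.with_lesion_side("left"))
        assert np.allclose(right.to_numpy(), 1.0 / left.to_numpy())


class TestNormalization:
    def test_whole_brain_fraction_arithmetic(self, tiny_atlas, table_builder):
        table = table_builder(
            [[10.0, 10.0, 10.0, 10.0]], tiny_atlas, whole_brain=[2000.0]
        )
        norm = normalize_by_whole_brain(table)
        assert np.allclose(norm.to_numpy(), 0.005)

    def test_scale_invariance(self, atlas, table_builder):
        rng = np.random.default_rng(4)
        vals = rng.lognormal(3, 0.3, size=(5, 18))
        wb = vals.sum(axis=1) * 1.6
        t1 = table_builder(vals, atlas, whole_brain=wb)
        t2 = table_builder(vals * 2, atlas, whole_brain=wb * 2)
        assert np.allclose(
            normalize_by_whole_brain(t1).to_numpy(),
            normalize_by_whole_brain(t2).to_numpy(),
        )

    def test_fractions_bounded_by_overhead(self, atlas, table_builder):
        rng = np.random.default_rng(5)
        vals = rng.lognormal(3, 0.3, size=(8, 18))
        table = table_builder(vals, atlas, whole_brain=vals.sum(axis=1) * 1.6)
        sums = normalize_by_whole_brain(table).sum(axis=1)
        assert np.allclose(sums, 1 / 1.6)

    def test_region_exceeding_whole_brain_rejected(self, tiny_atlas, table_builder):
        table = table_builder([[50.0, 50.0, 60.0, 60.0]], tiny_atlas, whole_brain=[55.0])
        with pytest.raises(ValidationError):
            normalize_by_whole_brain(table)

    def test_suvw_identity_and_scale_invariance(self, tiny_atlas, table_builder):
        vals = np.array([[1.2, 1.2, 1.2, 1.2], [2.4, 1.2, 0.6, 0.6]])
        table = table_builder(
            vals, tiny_atlas, whole_brain=[1.2, 1.2], modality="suv"
        )
        suvw = suvw_normalize(table)
        assert np.allclose(suvw.to_numpy()[0], 1.0)
        assert suvw.iloc[1, 0] == pytest.approx(2.0)
        doubled = table_builder(
            vals * 2, tiny_atlas, whole_brain=[2.4, 2.4], modality="suv"
        )
        assert np.allclose(suvw.to_numpy(), suvw_normalize(doubled).to_numpy())


class TestFrames:
    def test_mean_and_identity(self):
        frames = [np.array([1.0, 2.0]), np.array([3.0, 4.0]), np.array([5.0, 6.0])]
        assert np.array_equal(average_frames(frames), [3.0, 4.0])
        one = pd.Series([1.5, 2.5], index=["a", "b"])
        assert average_frames([one, one, one]).equals(one)
        assert average_frames([one]).equals(one)

    def test_mismatched_regions_rejected(self):
        a = pd.Series([1.0], index=["x"])
        b = pd.Series([1.0], index=["y"])
        with pytest.raises(SchemaError):
            average_frames([a, b])


class TestPercentChange:
    @pytest.mark.parametrize(
        "v0, v1, expected", [(23.35, 13.91, 40.428), (10, 10, 0.0), (10, 0, 100.0)]
    )
    def test_values(self, v0, v1, expected):
        assert percent_change(v0, v1) == pytest.approx(expected, abs=1e-3)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValidationError):
            percent_change(0.0, 5.0)


class TestHematomaCourse:
    def test_constant_series_identity_course(self):
        series = [
            HematomaSeries(f"s{i}", {0: 20.0, 3: 20.0, 7: 20.0}) for i in range(5)
        ]
        course = hematoma_course(series)
        assert np.allclose(course.summary["mean"], 20.0)
        assert (course.comparisons["p"] == 1.0).all()
        assert course.mean_resorption_percent == 0.0

    def test_generator_defaults_match_calibration(self):
        course = hematoma_course(make_hematoma_series(n=1000, seed=11))
        assert course.summary.loc[0, "mean"] == pytest.approx(23.35, abs=1.0)
        assert course.summary.loc[7, "mean"] == pytest.approx(13.91, abs=1.0)
        # day 0 vs day 3 similar; day 0 vs day 7 decisively decreased
        cmp7 = course.comparisons.set_index("day_b").loc[7]
        assert cmp7["p"] < 1e-6 and cmp7["mean_diff"] > 0

    def test_incomplete_series_excluded_with_diagnostic(self):
        series = [
            HematomaSeries(f"s{i}", {0: 20.0, 3: 19.0, 7: 12.0}) for i in range(4)
        ] + [HematomaSeries("partial", {0: 20.0})]
        course = hematoma_course(series)
        assert course.excluded == ["partial"]
        assert (course.summary["n"] == 4).all()

    def test_two_animals_insufficient(self):
        series = [HematomaSeries(f"s{i}", {0: 20.0, 3: 19.0, 7: 12.0}) for i in range(2)]
        with pytest.raises(InsufficientDataError):
            hematoma_course(series)


class TestInclusionFilters:
    def test_study_cohort_arithmetic(self):
        cohort = (
            [(f"d{i}", None, True) for i in range(3)]
            + [(f"small{i}", 6.0, False) for i in range(7)]
            + [(f"ok{i}", 20.0, False) for i in range(104)]
        )
        included, excluded = apply_inclusion_filters(cohort)
        assert len(included) == 104
        reasons = [e.reason for e in excluded]
        assert reasons.count("died_before_mri") == 3
        assert reasons.count("volume_below_threshold") == 7

    def test_threshold_is_strict(self):
        included, excluded = apply_inclusion_filters(
            [("at", 10.0, False), ("below", 9.999, False)]
        )
        assert [d.subject_id for d in included] == ["at"]
        assert excluded[0].reason == "volume_below_threshold"

    def test_death_excluded_before_volume_filter(self):
        _, excluded = apply_inclusion_filters([("both", 5.0, True)])
        assert excluded[0].reason == "died_before_mri"

    def test_sham_bypasses_volume_filter(self):
        included, _ = apply_inclusion_filters([("sh", 0.0, False, "sham")])
        assert included[0].subject_id == "sh"

    def test_empty_cohort(self):
        assert apply_inclusion_filters([]) == ([], [])
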