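"""Exposure distributions: categorization, medians, adherence, CSV round-trip."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dietpaf.errors import ComputationError, DataError
from dietpaf.exposure import (
    DEFAULT_RECOMMENDATIONS,
    CategoryScheme,
    ExposureCategory,
    Recommendation,
    adherence_prevalence,
    build_distribution,
    gx,
    load_exposure_table,
    load_records,
    weighted_median,
    write_exposure_table,
    write_records,
)
from dietpaf.strata import Factor, Race, Sex, StratumKey

from conftest import make_record

RED = DEFAULT_RECOMMENDATIONS[Factor.red_meat]
FIBER = DEFAULT_RECOMMENDATIONS[Factor.fiber]
PROCESSED = DEFAULT_RECOMMENDATIONS[Factor.processed_meat]
STRATUM = StratumKey(age_band="25-34", sex=Sex.men, race=Race.nh_white)


class TestWeightedMedian:
    def test_reduces_to_sample_median_under_unit_weights(self):
        assert weighted_median([10, 50], [1, 1]) == 30  # even count interpolates
        assert weighted_median([10, 50, 80], [1, 1, 1]) == 50
        assert weighted_median([10, 50, 80, 120], [1, 1, 1, 1]) == 65

    def test_weight_pulls_median(self):
        assert weighted_median([40, 80], [3, 1]) == 40

    def test_single_value(self):
        assert weighted_median([120], [2.5]) == 120


class TestBuildDistribution:
    def test_fixed_bins_hand_example(self, four_records):
        """4 records {10,50,80,120} in bins [0,60),[60,100),[100,inf)."""
        d = build_distribution(
            four_records, Factor.red_meat, STRATUM,
            scheme=CategoryScheme(kind="fixed", edges=(0.0, 60.0, 100.0)),
        )
        assert [c.prevalence for c in d.categories] == [0.5, 0.25, 0.25]
        assert [c.median for c in d.categories] == [30.0, 80.0, 120.0]

    def test_weighted_prevalences(self):
        recs = [make_record(0, 40.0, weight=3.0), make_record(1, 80.0, weight=1.0)]
        d = build_distribution(
            recs, Factor.red_meat, STRATUM, scheme=CategoryScheme(kind="fixed", edges=(0.0, 60.0))
        )
        assert [c.prevalence for c in d.categories] == [0.75, 0.25]

    def test_all_compliant_single_category(self):
        recs = [make_record(i, c) for i, c in enumerate([10.0, 20.0, 55.0])]
        d = build_distribution(recs, Factor.red_meat, STRATUM)
        assert len(d.categories) == 1
        assert d.categories[0].prevalence == 1.0
        assert gx(d.categories[0], RED) == 0.0

    def test_empty_stratum_raises(self, four_records):
        other = StratumKey(age_band="60-69", sex=Sex.women, race=Race.hispanic)
        with pytest.raises(ComputationError, match="no records"):
            build_distribution(four_records, Factor.red_meat, other)

    def test_quantile_scheme_reference_is_boundary(self):
        rng = np.random.default_rng(0)
        recs = [make_record(i, float(c)) for i, c in enumerate(rng.lognormal(4.2, 0.7, 200))]
        d = build_distribution(recs, Factor.red_meat, STRATUM)
        uppers = [c.upper for c in d.categories]
        assert 60.0 in uppers or d.categories[0].lower == 60.0
        # compliant category first, with zero departure
        assert gx(d.categories[0], RED) == 0.0
        assert all(gx(c, RED) > 0 for c in d.categories[1:])

    def test_quantile_scheme_protective_side(self):
        rng = np.random.default_rng(1)
        recs = [
            make_record(i, {Factor.fiber: float(c)})
            for i, c in enumerate(rng.lognormal(2.7, 0.5, 200))
        ]
        d = build_distribution(recs, Factor.fiber, STRATUM)
        # non-compliant categories sit below the 28 g/day reference
        assert all(c.upper <= 28.0 for c in d.categories[:-1])
        assert d.categories[-1].lower == 28.0

    def test_pooled_strata_pool_records_not_averages(self):
        recs = [
            make_record(0, 100.0, sex=Sex.men, weight=3.0),
            make_record(1, 10.0, sex=Sex.women, weight=1.0),
        ]
        pooled = StratumKey(age_band="25-34", sex=Sex.persons, race=Race.all)
        d = build_distribution(
            recs, Factor.red_meat, pooled, scheme=CategoryScheme(kind="fixed", edges=(0.0, 60.0))
        )
        # weight-fraction 3/4 above 60, not the 1/2 a sub-stratum average would give
        assert [c.prevalence for c in d.categories] == [0.25, 0.75]

    def test_normalization_invariant(self):
        rng = np.random.default_rng(2)
        recs = [
            make_record(i, float(v), weight=float(w))
            for i, (v, w) in enumerate(zip(rng.lognormal(4, 1, 500), rng.gamma(4, 0.25, 500)))
        ]
        for kind in ("quantile", "per_value"):
            d = build_distribution(recs, Factor.red_meat, STRATUM, scheme=CategoryScheme(kind=kind))
            assert abs(sum(c.prevalence for c in d.categories) - 1.0) < 1e-9


class TestGx:
    @pytest.mark.parametrize(
        "rec,median,expected",
        [
            (RED, 120.0, 60.0),  # excess above the 60 g/day maximum
            (FIBER, 28.0, 0.0),  # exactly at the reference
            (FIBER, 35.0, 0.0),  # over-adherence clamps to zero
            (FIBER, 18.0, 10.0),  # deficit below the 28 g/day minimum
        ],
    )
    def test_departure(self, rec, median, expected):
        c = ExposureCategory(index=1, lower=0.0, upper=math.inf, median=median, prevalence=1.0)
        assert gx(c, rec) == expected


class TestAdherence:
    def test_half_exceed_maximum(self, four_records):
        assert adherence_prevalence(four_records, Factor.red_meat, RED, STRATUM) == 0.5

    def test_zero_reference_counts_any_consumption(self):
        recs = [make_record(i, {Factor.processed_meat: c}) for i, c in enumerate([0.0, 0.0, 25.0])]
        got = adherence_prevalence(recs, Factor.processed_meat, PROCESSED, STRATUM)
        assert got == pytest.approx(1 / 3)

    def test_all_compliant_is_zero(self):
        recs = [make_record(i, c) for i, c in enumerate([10.0, 60.0])]  # 60 is compliant
        assert adherence_prevalence(recs, Factor.red_meat, RED, STRATUM) == 0.0

    def test_boundary_compliance_both_directions(self):
        assert RED.is_compliant(60.0)
        assert FIBER.is_compliant(28.0)
        assert not RED.is_compliant(60.0001)
        assert not FIBER.is_compliant(27.9999)

    def test_matches_category_mass_when_reference_is_boundary(self):
        """Non-adherence equals the summed prevalence of categories with
        positive departure, when the scheme cuts at the reference."""
        rng = np.random.default_rng(3)
        recs = [
            make_record(i, float(v), weight=float(w))
            for i, (v, w) in enumerate(zip(rng.lognormal(4.2, 0.8, 300), rng.gamma(4, 0.25, 300)))
        ]
        d = build_distribution(recs, Factor.red_meat, STRATUM)
        mass = sum(c.prevalence for c in d.categories if gx(c, RED) > 0)
        assert mass == pytest.approx(
            adherence_prevalence(recs, Factor.red_meat, RED, STRATUM), abs=1e-12
        )


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=20, derandomize=True, deadline=None)
def test_distribution_sums_to_one_property(seed):
    """Normalization holds for arbitrary consumption/weight draws."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 60))
    recs = [
        make_record(i, float(v), weight=float(w))
        for i, (v, w) in enumerate(zip(rng.lognormal(4, 1.2, n), rng.gamma(2, 0.5, n) + 0.01))
    ]
    d = build_distribution(recs, Factor.red_meat, STRATUM)
    assert abs(sum(c.prevalence for c in d.categories) - 1.0) < 1e-9


class TestCSVRoundTrip:
    def test_exposure_table_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        recs = [make_record(i, float(v)) for i, v in enumerate(rng.lognormal(4.2, 0.8, 100))]
        d = build_distribution(recs, Factor.red_meat, STRATUM)
        p = tmp_path / "exposure.csv"
        write_exposure_table([d], p)
        (loaded,) = load_exposure_table(p)
        assert loaded == d  # lossless, not just close

    def test_invalid_prevalence_rejected(self, tmp_path):
        p = tmp_path / "exposure.csv"
        p.write_text(
            "factor,age_band,sex,race,category_index,lower,upper,median,prevalence\n"
            "red_meat,25-34,men,nh_white,1,0,inf,30,1.2\n"
        )
        with pytest.raises(DataError, match="1.2"):
            load_exposure_table(p)

    def test_non_normalized_distribution_rejected(self, tmp_path):
        p = tmp_path / "exposure.csv"
        p.write_text(
            "factor,age_band,sex,race,category_index,lower,upper,median,prevalence\n"
            "red_meat,25-34,men,nh_white,1,0,60,30,0.5\n"
            "red_meat,25-34,men,nh_white,2,60,inf,90,0.4\n"
        )
        with pytest.raises(DataError, match="sum"):
            load_exposure_table(p)

    def test_records_round_trip(self, tmp_path, four_records):
        p = tmp_path / "records.csv"
        write_records(four_records, p)
        loaded = load_records(p)
        assert sorted(loaded, key=lambda r: r.person_id) == four_records


def test_record_validation():
    with pytest.raises(ValueError, match="weight"):
        make_record(0, 10.0, weight=0.0)
    with pytest.raises(ValueError, match="concrete"):
        make_record(0, 10.0, sex=Sex.persons)
    with pytest.raises(ValueError):
        make_record(0, -5.0)


def test_recommendation_defaults():
    assert RED.reference_level == 60.0 and RED.comparator == "maximum"
    assert PROCESSED.reference_level == 0.0
    assert FIBER.reference_level == 28.0 and FIBER.comparator == "minimum"
    assert DEFAULT_RECOMMENDATIONS[Factor.calcium].reference_level == 1000.0
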