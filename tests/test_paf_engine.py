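"""PAF formula, latency pairing, excess cases, aggregation and combination."""

import math
import warnings

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dietpaf.errors import ComputationError, ConfigError, DataError
from dietpaf.exposure import (
    DEFAULT_RECOMMENDATIONS,
    ExposureCategory,
    ExposureDistribution,
    Recommendation,
)
from dietpaf.incidence_io import IncidenceTable
from dietpaf.paf_engine import (
    PAFResult,
    aggregate_age_weighted,
    allcancer_scope,
    combine_factors,
    complement_combine,
    err,
    excess_cases,
    paf_single,
    pair_latency,
)
from dietpaf.risk_models import PerUnitRisk
from dietpaf.strata import (
    DEFAULT_INCIDENCE_BANDS,
    DEFAULT_PREVALENCE_BANDS,
    Direction,
    Factor,
    Race,
    Sex,
    StratumKey,
    Unit,
)

RED = DEFAULT_RECOMMENDATIONS[Factor.red_meat]
STRATUM = StratumKey(age_band="all", sex=Sex.men, race=Race.all)


def make_rg(rg, factor=Factor.red_meat, sex=Sex.men):
    return PerUnitRisk(
        factor=factor, sex_stratum=sex, rg=rg, unit=Unit.g_per_day,
        direction=Direction.detrimental,
    )


def make_dist(cats, factor=Factor.red_meat):
    """Distribution from (median, prevalence) pairs; bounds tile around them."""
    medians = [m for m, _ in cats]
    edges = [0.0] + [(a + b) / 2 for a, b in zip(medians, medians[1:])] + [math.inf]
    return ExposureDistribution(
        factor=factor,
        stratum=StratumKey(age_band="25-34", sex=Sex.men, race=Race.nh_white),
        categories=tuple(
            ExposureCategory(index=i + 1, lower=lo, upper=hi, median=m, prevalence=p)
            for i, ((m, p), lo, hi) in enumerate(zip(cats, edges, edges[1:]))
        ),
    )


class TestErr:
    def test_zero_departure(self):
        assert err(make_rg(0.005), 0.0) == 0.0

    def test_exponential_value(self):
        assert err(make_rg(0.0030), 50.0) == pytest.approx(math.exp(0.15) - 1, abs=1e-12)

    def test_full_increment_recovers_rr_minus_one(self):
        rg = make_rg(math.log(1.28) / 100)
        assert err(rg, 100.0) == pytest.approx(0.28, abs=1e-12)

    def test_negative_departure_is_contract_violation(self):
        with pytest.raises(ComputationError, match="clamp"):
            err(make_rg(0.005), -1.0)


class TestPafSingle:
    def test_fully_compliant_population(self):
        d = make_dist([(30.0, 1.0)])
        assert paf_single(d, make_rg(0.0025), RED) == 0.0

    def test_single_category_err_one_gives_half(self):
        # G chosen so exp(rg G) = 2, i.e. ERR = 1 -> PAF = 1/2
        rg = 0.0025
        g = math.log(2) / rg
        d = make_dist([(60.0 + g, 1.0)])
        assert paf_single(d, make_rg(rg), RED) == pytest.approx(0.5, abs=1e-12)

    def test_three_category_hand_value(self):
        """p = (0.5, 0.25, 0.25), departures (0, 20, 60), slope 0.0025/day."""
        d = make_dist([(30.0, 0.5), (80.0, 0.25), (120.0, 0.25)])
        s = 0.25 * (math.exp(0.0025 * 20) - 1) + 0.25 * (math.exp(0.0025 * 60) - 1)
        assert paf_single(d, make_rg(0.0025), RED) == pytest.approx(s / (1 + s), abs=1e-14)

    def test_factor_mismatch_rejected(self):
        d = make_dist([(30.0, 1.0)])
        with pytest.raises(ComputationError, match="mismatch"):
            paf_single(d, make_rg(0.01, factor=Factor.fiber), RED)

    @given(
        rg=st.floats(1e-5, 0.02),
        g1=st.floats(0.0, 200.0),
        p1=st.floats(0.01, 0.99),
    )
    @settings(max_examples=100, derandomize=True)
    def test_bounds_property(self, rg, g1, p1):
        """0 <= PAF < 1 whenever all excess relative risks are non-negative,
        and PAF = 0 iff no mass has positive departure (or the slope is 0)."""
        d = make_dist([(30.0, 1 - p1), (60.0 + g1, p1)])
        paf = paf_single(d, make_rg(rg), RED)
        assert 0.0 <= paf < 1.0
        if g1 == 0.0:
            assert paf == 0.0
        elif g1 > 1e-6:
            assert paf > 0.0

    def test_monotone_in_slope_departure_and_mass(self):
        base = paf_single(make_dist([(30.0, 0.5), (120.0, 0.5)]), make_rg(0.002), RED)
        assert paf_single(make_dist([(30.0, 0.5), (120.0, 0.5)]), make_rg(0.003), RED) > base
        assert paf_single(make_dist([(30.0, 0.5), (150.0, 0.5)]), make_rg(0.002), RED) > base
        assert paf_single(make_dist([(30.0, 0.4), (120.0, 0.6)]), make_rg(0.002), RED) > base


class TestLatencyPairing:
    def test_default_band_pairing(self):
        lm = pair_latency(DEFAULT_PREVALENCE_BANDS, DEFAULT_INCIDENCE_BANDS, offset=10)
        assert dict((inc, prev) for prev, inc in lm.pairs) == {
            "25-34": "18-24",  # youngest incidence band clamps to youngest exposure band
            "35-44": "25-34",
            "45-54": "35-44",
            "55-64": "45-54",
            "65-69": "55-59",
            "70+": "60-69",  # oldest exposure band carries forward
        }

    def test_zero_offset_is_identity(self):
        bands = ["25-34", "35-44", "45-54"]
        lm = pair_latency(bands, bands, offset=0)
        assert all(prev == inc for prev, inc in lm.pairs)

    def test_every_incidence_band_has_exactly_one_source(self):
        lm = pair_latency(DEFAULT_PREVALENCE_BANDS, DEFAULT_INCIDENCE_BANDS)
        sources = [lm.source_for(b) for b in DEFAULT_INCIDENCE_BANDS]
        assert len(sources) == len(DEFAULT_INCIDENCE_BANDS)

    def test_orphan_bands_listed(self):
        with pytest.raises(ConfigError, match="85-94"):
            pair_latency(["18-24", "25-34"], ["28-37", "85-94"], offset=10)

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            pair_latency(["18-24", "20-29"], ["25-34"], offset=10)


def make_incidence(counts_by_band, sex=Sex.men, race=Race.all, site="colorectal"):
    return IncidenceTable(
        {(site, band, sex, race): n for band, n in counts_by_band.items()}
    )


class TestExcessCases:
    def test_paf_times_count(self):
        lm = pair_latency(["18-24"], ["25-34"], offset=10)
        inc = make_incidence({"25-34": 100})
        (res,) = excess_cases({"18-24": 0.10}, inc, lm, "red_meat", Sex.men, Race.all)
        assert res.excess_cases == pytest.approx(10.0)
        assert res.case_count == 100

    def test_two_band_total(self):
        lm = pair_latency(["18-24", "25-34"], ["25-34", "35-44"], offset=10)
        inc = make_incidence({"25-34": 100, "35-44": 50})
        res = excess_cases({"18-24": 0.10, "25-34": 0.20}, inc, lm, "red_meat", Sex.men, Race.all)
        assert sum(r.excess_cases for r in res) == pytest.approx(20.0)

    def test_zero_counts_keep_paf(self):
        lm = pair_latency(["18-24"], ["25-34"], offset=10)
        inc = make_incidence({"25-34": 0})
        (res,) = excess_cases({"18-24": 0.10}, inc, lm, "red_meat", Sex.men, Race.all)
        assert res.excess_cases == 0.0 and res.paf == 0.10

    def test_missing_cell_is_error_not_zero(self):
        lm = pair_latency(["18-24", "25-34"], ["25-34", "35-44"], offset=10)
        inc = make_incidence({"25-34": 100})  # 35-44 missing
        with pytest.raises(DataError, match="missing incidence cell"):
            excess_cases({"18-24": 0.1, "25-34": 0.2}, inc, lm, "red_meat", Sex.men, Race.all)


def make_result(paf, cases, factor="red_meat", band="all", sex=Sex.men, race=Race.all,
                scope="colorectal"):
    return PAFResult(
        factor=factor, site_scope=scope,
        stratum=StratumKey(age_band=band, sex=sex, race=race),
        paf=paf, case_count=cases,
    )


class TestAggregation:
    def test_case_weighted_mean(self):
        r = aggregate_age_weighted(
            [make_result(0.10, 100, band="25-34"), make_result(0.20, 100, band="35-44")]
        )
        assert r.paf == pytest.approx(0.15)
        assert r.excess_cases == pytest.approx(30.0)  # identity preserved

    def test_single_band_unchanged(self):
        r = aggregate_age_weighted([make_result(0.123, 77, band="25-34")])
        assert r.paf == pytest.approx(0.123) and r.case_count == 77

    def test_constant_paf_any_weights(self):
        r = aggregate_age_weighted(
            [make_result(0.3, 10, band="25-34"), make_result(0.3, 990, band="35-44")]
        )
        assert r.paf == pytest.approx(0.3)

    def test_degenerate_zero_cases(self):
        r = aggregate_age_weighted([make_result(0.4, 0, band="25-34")])
        assert r.paf == 0.0 and r.excess_cases == 0.0

    def test_mixed_factors_rejected(self):
        with pytest.raises(ComputationError):
            aggregate_age_weighted(
                [make_result(0.1, 10, factor="red_meat"), make_result(0.1, 10, factor="fiber")]
            )


class TestCombineFactors:
    def test_published_persons_row_sums(self):
        """Colorectal PAFs 3.8 + 9.9 + 12.3 + 8.0 combine to 34.0%."""
        parts = [
            make_result(p / 100, 10000, factor=f, sex=Sex.persons)
            for f, p in [("red_meat", 3.8), ("processed_meat", 9.9), ("fiber", 12.3), ("calcium", 8.0)]
        ]
        combined = combine_factors(parts)
        assert combined.factor == "all_factors"
        assert combined.paf_percent == 34.0

    def test_single_factor_unchanged(self):
        r = combine_factors([make_result(0.1, 50)])
        assert r.paf == pytest.approx(0.1) and r.factor == "all_factors"

    def test_overflow_warns(self):
        parts = [make_result(0.3, 100, factor=f) for f in ("a", "b", "c", "d")]
        with pytest.warns(UserWarning, match=">= 1"):
            r = combine_factors(parts)
        assert r.paf == pytest.approx(1.2)

    def test_mismatched_strata_rejected(self):
        with pytest.raises(ComputationError):
            combine_factors([make_result(0.1, 10), make_result(0.1, 10, sex=Sex.women)])

    def test_mismatched_denominator_rejected(self):
        with pytest.raises(ComputationError, match="denominator"):
            combine_factors([make_result(0.1, 10), make_result(0.1, 20, factor="fiber")])

    def test_complement_mode_is_smaller(self):
        parts = [make_result(0.2, 100, factor=f) for f in ("a", "b")]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            add = combine_factors(parts).paf
            comp = complement_combine(parts).paf
        assert comp == pytest.approx(1 - 0.8 * 0.8)
        assert comp < add


class TestAllCancerScope:
    @pytest.mark.parametrize(
        "excess,total,expected_pct",
        [(3428.0, 103408, 3.3), (531.0, 12020, 4.4), (0.0, 103408, 0.0)],
    )
    def test_denominator_swap(self, excess, total, expected_pct):
        site_cases = 10000
        r = make_result(excess / site_cases, site_cases)
        out = allcancer_scope(r, total)
        assert out.site_scope == "all_cancers"
        assert out.excess_cases == pytest.approx(excess)  # numerator unchanged
        assert out.paf_percent == expected_pct

    def test_total_below_site_count_rejected(self):
        with pytest.raises(ComputationError):
            allcancer_scope(make_result(0.1, 10000), 500)
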