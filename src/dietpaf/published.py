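"""Published inputs and results for the Texas 2015 dietary cancer-burden study.

Four printed tables drive the reproduction and the acceptance checks:

* relative risks per dose increment for colorectal cancer, by sex, from the
  WCRF/AICR Third Expert Report, with their published per-unit slopes;
* NHANES-based prevalence (%) of adults not meeting the dietary
  recommendations, by sex and race/ethnicity;
* the study's age-weighted PAF / excess-case grid by factor, sex and
  race/ethnicity, for colorectal cancer and for all cancers;
* Texas Cancer Registry 2015 case-count marginals (all invasive cancers
  excluding BCC/SCC of the skin, adults aged >= 25).

Only printed values appear here; anything the source did not print (age- and
race-specific colorectal counts, category boundaries and medians) is covered
by the synthetic-data generator instead.
"""

from __future__ import annotations

from .risk_models import RiskEstimate, RiskTable
from .strata import Direction, Factor, Race, Sex, Unit

# -- published relative risks (per increment) --------------------------------
# (factor, sex): rr, increment, direction, CI-includes-null flag
_RR_ROWS: list[tuple[Factor, Sex, float, float, Direction, bool]] = [
    (Factor.red_meat, Sex.men, 1.28, 100.0, Direction.detrimental, True),
    (Factor.red_meat, Sex.women, 1.02, 100.0, Direction.detrimental, True),
    (Factor.red_meat, Sex.persons, 1.12, 100.0, Direction.detrimental, True),
    (Factor.processed_meat, Sex.men, 1.11, 50.0, Direction.detrimental, True),
    (Factor.processed_meat, Sex.women, 1.18, 50.0, Direction.detrimental, True),
    (Factor.processed_meat, Sex.persons, 1.16, 50.0, Direction.detrimental, False),
    (Factor.fiber, Sex.men, 0.89, 10.0, Direction.protective, False),
    (Factor.fiber, Sex.women, 0.91, 10.0, Direction.protective, False),
    (Factor.fiber, Sex.persons, 0.93, 10.0, Direction.protective, True),
    (Factor.calcium, Sex.men, 0.93, 200.0, Direction.protective, False),
    (Factor.calcium, Sex.women, 0.93, 200.0, Direction.protective, False),
    (Factor.calcium, Sex.persons, 0.94, 200.0, Direction.protective, False),
]

#: Published per-unit slopes (4 dp) for the same cells, for verification.
PUBLISHED_RG: dict[tuple[Factor, Sex], float] = {
    (Factor.red_meat, Sex.men): 0.0025,
    (Factor.red_meat, Sex.women): 0.0002,
    (Factor.red_meat, Sex.persons): 0.0011,
    (Factor.processed_meat, Sex.men): 0.0021,
    (Factor.processed_meat, Sex.women): 0.0033,
    (Factor.processed_meat, Sex.persons): 0.0030,
    (Factor.fiber, Sex.men): 0.0117,
    (Factor.fiber, Sex.women): 0.0094,
    (Factor.fiber, Sex.persons): 0.0073,
    (Factor.calcium, Sex.men): 0.0004,
    (Factor.calcium, Sex.women): 0.0004,
    (Factor.calcium, Sex.persons): 0.0003,
}


def published_risk_table() -> RiskTable:
    return RiskTable(
        [
            RiskEstimate(
                factor=f,
                sex_stratum=s,
                site="colorectal",
                rr=rr,
                increment=inc,
                unit=Unit.mg_per_day if f is Factor.calcium else Unit.g_per_day,
                direction=d,
                ci_includes_null=flag,
            )
            for (f, s, rr, inc, d, flag) in _RR_ROWS
        ]
    )


# -- published non-adherence prevalence (%) ----------------------------------
# race -> sex -> factor -> % not meeting the recommendation (adults >= 18)
PUBLISHED_NONADHERENCE_PCT: dict[Race, dict[Sex, dict[Factor, float]]] = {
    Race.all: {
        Sex.men: {Factor.red_meat: 59.9, Factor.processed_meat: 88.1, Factor.fiber: 88.0, Factor.calcium: 53.4},
        Sex.women: {Factor.red_meat: 45.4, Factor.processed_meat: 83.9, Factor.fiber: 95.6, Factor.calcium: 71.7},
        Sex.persons: {Factor.red_meat: 52.7, Factor.processed_meat: 86.0, Factor.fiber: 92.0, Factor.calcium: 63.0},
    },
    Race.nh_white: {
        Sex.men: {Factor.red_meat: 63.9, Factor.processed_meat: 91.6, Factor.fiber: 87.8, Factor.calcium: 49.5},
        Sex.women: {Factor.red_meat: 48.7, Factor.processed_meat: 85.9, Factor.fiber: 95.6, Factor.calcium: 69.3},
        Sex.persons: {Factor.red_meat: 56.4, Factor.processed_meat: 88.8, Factor.fiber: 91.9, Factor.calcium: 59.9},
    },
    Race.nh_black: {
        Sex.men: {Factor.red_meat: 49.0, Factor.processed_meat: 86.6, Factor.fiber: 96.4, Factor.calcium: 67.4},
        Sex.women: {Factor.red_meat: 37.6, Factor.processed_meat: 86.7, Factor.fiber: 98.3, Factor.calcium: 86.6},
        Sex.persons: {Factor.red_meat: 42.9, Factor.processed_meat: 86.6, Factor.fiber: 97.5, Factor.calcium: 78.2},
    },
    Race.hispanic: {
        Sex.men: {Factor.red_meat: 52.8, Factor.processed_meat: 84.9, Factor.fiber: 79.9, Factor.calcium: 63.6},
        Sex.women: {Factor.red_meat: 40.8, Factor.processed_meat: 79.8, Factor.fiber: 92.9, Factor.calcium: 69.0},
        Sex.persons: {Factor.red_meat: 47.3, Factor.processed_meat: 82.5, Factor.fiber: 86.6, Factor.calcium: 66.4},
    },
    Race.other: {
        Sex.men: {Factor.red_meat: 53.8, Factor.processed_meat: 62.5, Factor.fiber: 89.3, Factor.calcium: 57.2},
        Sex.women: {Factor.red_meat: 36.6, Factor.processed_meat: 67.9, Factor.fiber: 94.0, Factor.calcium: 74.6},
        Sex.persons: {Factor.red_meat: 44.9, Factor.processed_meat: 65.3, Factor.fiber: 91.7, Factor.calcium: 66.2},
    },
}


# -- published burden grid ---------------------------------------------------
# race -> sex -> factor-or-"all_factors" ->
#   (colorectal PAF %, all-cancer PAF %, all-cancer excess cases)
Grid = dict[Race, dict[Sex, dict[str, tuple[float, float, int]]]]

PUBLISHED_BURDEN: Grid = {
    Race.all: {
        Sex.men: {
            "red_meat": (6.5, 0.7, 365), "processed_meat": (9.0, 1.0, 505),
            "fiber": (12.3, 1.3, 695), "calcium": (6.6, 0.7, 370),
            "all_factors": (34.4, 3.8, 1935),
        },
        Sex.women: {
            "red_meat": (0.3, 0.0, 14), "processed_meat": (11.1, 1.0, 497),
            "fiber": (12.1, 1.0, 541), "calcium": (9.9, 0.8, 441),
            "all_factors": (33.5, 2.9, 1493),
        },
        Sex.persons: {
            "red_meat": (3.8, 0.4, 379), "processed_meat": (9.9, 1.0, 1002),
            "fiber": (12.3, 1.2, 1236), "calcium": (8.0, 0.8, 811),
            "all_factors": (34.0, 3.3, 3428),
        },
    },
    Race.nh_white: {
        Sex.men: {
            "red_meat": (6.8, 0.7, 223), "processed_meat": (9.4, 0.9, 308),
            "fiber": (12.1, 1.2, 393), "calcium": (5.8, 0.6, 190),
            "all_factors": (34.2, 3.4, 1114),
        },
        Sex.women: {
            "red_meat": (0.3, 0.0, 9), "processed_meat": (11.3, 0.9, 300),
            "fiber": (12.0, 1.0, 317), "calcium": (9.3, 0.8, 248),
            "all_factors": (32.9, 2.7, 874),
        },
        Sex.persons: {
            "red_meat": (3.9, 0.4, 232), "processed_meat": (10.3, 0.9, 608),
            "fiber": (12.0, 1.1, 711), "calcium": (7.4, 0.7, 438),
            "all_factors": (33.6, 3.1, 1989),
        },
    },
    Race.nh_black: {
        Sex.men: {
            "red_meat": (5.8, 0.7, 41), "processed_meat": (9.5, 1.1, 68),
            "fiber": (14.9, 1.8, 106), "calcium": (9.5, 1.1, 68),
            "all_factors": (39.7, 4.7, 283),
        },
        Sex.women: {
            "red_meat": (0.2, 0.0, 1), "processed_meat": (12.7, 1.3, 79),
            "fiber": (13.8, 1.4, 86), "calcium": (12.9, 1.3, 81),
            "all_factors": (39.6, 4.1, 248),
        },
        Sex.persons: {
            "red_meat": (3.2, 0.4, 43), "processed_meat": (11.0, 1.2, 147),
            "fiber": (14.3, 1.6, 192), "calcium": (11.1, 1.2, 149),
            "all_factors": (39.6, 4.4, 531),
        },
    },
    Race.hispanic: {
        Sex.men: {
            "red_meat": (5.2, 0.7, 78), "processed_meat": (7.4, 1.0, 112),
            "fiber": (11.5, 1.6, 173), "calcium": (9.8, 1.4, 148),
            "all_factors": (34.0, 4.8, 511),
        },
        Sex.women: {
            "red_meat": (0.3, 0.0, 3), "processed_meat": (10.4, 0.9, 107),
            "fiber": (11.6, 1.0, 119), "calcium": (10.2, 0.9, 105),
            "all_factors": (32.5, 2.8, 334),
        },
        Sex.persons: {
            "red_meat": (3.2, 0.4, 81), "processed_meat": (8.7, 1.0, 219),
            "fiber": (11.6, 1.2, 292), "calcium": (10.0, 1.1, 253),
            "all_factors": (33.4, 3.7, 845),
        },
    },
    Race.other: {
        Sex.men: {
            "red_meat": (5.3, 0.5, 8), "processed_meat": (4.0, 0.4, 6),
            "fiber": (12.4, 1.1, 18), "calcium": (7.2, 0.6, 11),
            "all_factors": (28.9, 2.5, 43),
        },
        Sex.women: {
            "red_meat": (0.1, 0.0, 0), "processed_meat": (6.6, 0.5, 10),
            "fiber": (11.4, 1.0, 17), "calcium": (10.9, 0.9, 17),
            "all_factors": (28.9, 2.4, 44),
        },
        Sex.persons: {
            "red_meat": (2.6, 0.2, 8), "processed_meat": (5.3, 0.5, 16),
            "fiber": (11.9, 1.0, 36), "calcium": (9.1, 0.8, 27),
            "all_factors": (28.9, 2.5, 87),
        },
    },
}

# -- registry case-count marginals (all cancers excl. BCC/SCC, age >= 25) ----
TEXAS_2015_ALL_CANCERS: dict[tuple[Sex, Race], int] = {
    (Sex.persons, Race.all): 103408,
    (Sex.men, Race.all): 51472,
    (Sex.women, Race.all): 51936,
    (Sex.persons, Race.nh_white): 65214,
    (Sex.persons, Race.hispanic): 22642,
    (Sex.persons, Race.nh_black): 12020,
    (Sex.persons, Race.other): 3532,
}
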