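"""Population attributable fractions, latency-paired excess cases, aggregation.

The Levin-style categorical PAF with a continuous dose-response is

    PAF = S / (1 + S),    S = sum_x p_x * ERR_x,    ERR_x = exp(Rg * G_x) - 1

where p_x is the prevalence of exposure category x, G_x its average departure
from the guideline reference, and Rg the per-unit log-risk slope.  PAFs are
computed per exposure-side age band, paired with the incidence age band one
latency offset (default ten years) older, multiplied by that band's case
count to give excess cases, and aggregated case-weighted over age bands.
Multi-factor burden is additive in excess cases.
"""

from __future__ import annotations

import math
import warnings
from typing import Literal, Mapping, Sequence

from pydantic import BaseModel, Field

from .errors import ComputationError, ConfigError
from .exposure import ExposureDistribution, Recommendation, gx
from .incidence_io import IncidenceTable
from .risk_models import PerUnitRisk, round_half_up
from .strata import AgeBand, Race, Sex, StratumKey, check_bands

SiteScope = Literal["colorectal", "all_cancers"]


class PAFResult(BaseModel, frozen=True):
    """PAF and excess cases for one factor (or all factors) in one stratum."""

    factor: str  # Factor value or "all_factors"
    site_scope: SiteScope = "colorectal"
    stratum: StratumKey
    paf: float
    case_count: int = Field(ge=0)

    @property
    def excess_cases(self) -> float:
        """Unrounded excess = PAF x case count."""
        return self.paf * self.case_count

    @property
    def excess_rounded(self) -> int:
        return int(round_half_up(self.excess_cases, 0))

    @property
    def paf_percent(self) -> float:
        """Report-facing PAF in percent, 1 decimal place, half-up."""
        return round_half_up(100.0 * self.paf, 1)


class LatencyMap(BaseModel, frozen=True):
    """Exposure-band -> incidence-band pairing under a latency offset."""

    offset_years: int = Field(ge=0)
    pairs: tuple[tuple[str, str], ...]  # (prevalence band, incidence band)

    def source_for(self, incidence_band: str) -> str:
        for prev, inc in self.pairs:
            if AgeBand(inc) == AgeBand(incidence_band):
                return prev
        raise ComputationError(f"incidence band {incidence_band!r} has no exposure source band")


def err(rg: PerUnitRisk | float, g: float) -> float:
    """Excess relative risk exp(Rg x G) - 1 at departure G from the guideline."""
    if g < 0:
        raise ComputationError(f"negative departure G = {g}; clamp upstream")
    slope = rg.rg if isinstance(rg, PerUnitRisk) else float(rg)
    return math.exp(slope * g) - 1.0


def paf_single(
    dist: ExposureDistribution,
    rg: PerUnitRisk,
    rec: Recommendation,
) -> float:
    """Single-factor PAF = S/(1+S) with S = sum_x p_x ERR_x, at full precision."""
    if dist.factor is not rg.factor or dist.factor is not rec.factor:
        raise ComputationError(
            f"factor mismatch: distribution {dist.factor.value}, slope {rg.factor.value}, "
            f"recommendation {rec.factor.value}"
        )
    s = sum(c.prevalence * err(rg, gx(c, rec)) for c in dist.categories)
    return s / (1.0 + s)


def pair_latency(
    prev_bands: Sequence[str],
    inc_bands: Sequence[str],
    offset: int = 10,
) -> LatencyMap:
    """Pair each incidence age band with the exposure band ``offset`` years younger.

    The youngest incidence band clamps to the youngest exposure band when the
    shifted lower edge falls below it; an open-ended oldest incidence band
    carries the oldest exposure band forward.  Every incidence band must
    resolve to exactly one source, otherwise the orphans are listed.
    """
    pb = check_bands(list(prev_bands))
    ib = check_bands(list(inc_bands))
    pairs: list[tuple[str, str]] = []
    orphans: list[str] = []
    for band in ib:
        if band.open_ended and band.lo - offset > pb[-1].lo:
            pairs.append((pb[-1].label, band.label))  # carry oldest band forward
            continue
        target = band.lo - offset
        src = next((p for p in pb if target in p), None)
        if src is None and band == ib[0] and target < pb[0].lo:
            src = pb[0]  # clamp the youngest band
        if src is None:
            orphans.append(band.label)
        else:
            pairs.append((src.label, band.label))
    if orphans:
        raise ConfigError(
            f"incidence bands with no exposure band {offset} years younger: {orphans}"
        )
    return LatencyMap(offset_years=offset, pairs=tuple(pairs))


def excess_cases(
    paf_by_ageband: Mapping[str, float],
    incidence: IncidenceTable,
    latency: LatencyMap,
    factor: str,
    sex: Sex,
    race: Race,
    site_group: str = "colorectal",
) -> list[PAFResult]:
    """Apply age-band PAFs to latency-paired incidence counts.

    One result per incidence band: excess = PAF(source band) x count(band).
    A missing count cell raises; it is never an implicit zero.
    """
    results = []
    for prev_band, inc_band in latency.pairs:
        if prev_band not in paf_by_ageband:
            raise ComputationError(
                f"no PAF for exposure band {prev_band!r} (needed by incidence band {inc_band!r})"
            )
        count = incidence.get(site_group, inc_band, sex, race)
        results.append(
            PAFResult(
                factor=factor,
                site_scope="colorectal",
                stratum=StratumKey(age_band=inc_band, sex=sex, race=race),
                paf=paf_by_ageband[prev_band],
                case_count=count,
            )
        )
    return results


def aggregate_age_weighted(results: Sequence[PAFResult]) -> PAFResult:
    """Case-weighted aggregate over age bands: PAF = sum(excess) / sum(cases).

    Preserves the identity excess = PAF x cases through aggregation.  With
    zero cases in every band the PAF is 0 (degenerate stratum, not an error).
    """
    if not results:
        raise ComputationError("cannot aggregate an empty result set")
    first = results[0]
    for r in results[1:]:
        if (r.factor, r.site_scope, r.stratum.sex, r.stratum.race) != (
            first.factor, first.site_scope, first.stratum.sex, first.stratum.race,
        ):
            raise ComputationError("age aggregation requires a common factor/sex/race/site scope")
    total_cases = sum(r.case_count for r in results)
    total_excess = sum(r.excess_cases for r in results)
    return PAFResult(
        factor=first.factor,
        site_scope=first.site_scope,
        stratum=StratumKey(age_band="all", sex=first.stratum.sex, race=first.stratum.race),
        paf=total_excess / total_cases if total_cases else 0.0,
        case_count=total_cases,
    )


def combine_factors(results: Sequence[PAFResult]) -> PAFResult:
    """Additive multi-factor burden: excess cases sum over factors.

    All inputs must share stratum, site scope and denominator; the combined
    PAF is the sum of single-factor PAFs and may exceed 1, in which case a
    warning is attached (additivity ignores joint exposure).
    """
    if not results:
        raise ComputationError("cannot combine an empty result set")
    first = results[0]
    for r in results[1:]:
        if r.stratum != first.stratum or r.site_scope != first.site_scope:
            raise ComputationError("combine_factors requires a common stratum and site scope")
        if r.case_count != first.case_count:
            raise ComputationError(
                f"combine_factors requires a common denominator "
                f"({r.case_count} != {first.case_count})"
            )
    paf_all = sum(r.paf for r in results)
    if paf_all >= 1.0:
        warnings.warn(
            f"combined PAF {paf_all:.3f} >= 1 in stratum {first.stratum}: additive "
            "combination overflows; single-factor PAFs are not mutually exclusive",
            stacklevel=2,
        )
    return PAFResult(
        factor="all_factors",
        site_scope=first.site_scope,
        stratum=first.stratum,
        paf=paf_all,
        case_count=first.case_count,
    )


def complement_combine(results: Sequence[PAFResult]) -> PAFResult:
    """Alternative multi-factor combination 1 - prod(1 - PAF_f).

    Offered for sensitivity analysis only; assumes independent exposures and
    multiplicative joint risks, which the additive convention does not.
    """
    if not results:
        raise ComputationError("cannot combine an empty result set")
    base = combine_factors(results)  # reuse the consistency checks
    paf_all = 1.0 - math.prod(1.0 - r.paf for r in results)
    return base.model_copy(update={"paf": paf_all})


def allcancer_scope(result: PAFResult, total_cancers: int) -> PAFResult:
    """Re-express colorectal excess cases against the all-cancer denominator.

    The excess numerator is unchanged; only the denominator widens to all
    incident cancers (excluding BCC/SCC of the skin).
    """
    if total_cancers < result.case_count:
        raise ComputationError(
            f"all-cancer count {total_cancers} below site count {result.case_count}"
        )
    return PAFResult(
        factor=result.factor,
        site_scope="all_cancers",
        stratum=result.stratum,
        paf=result.excess_cases / total_cancers if total_cancers else 0.0,
        case_count=total_cancers,
    )
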