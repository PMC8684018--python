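"""Dose-response relative risks and their per-unit log-risk slopes.

Published RRs for diet-cancer associations are reported per consumption
increment (e.g. colorectal-cancer RR per 100 g/day of red meat).  The burden
model needs a slope per *single* unit of daily consumption, on the log-risk
scale:

    detrimental factor:  Rg = ln(RR) / x
    protective factor:   Rg = ln(1/RR) / x

where x is the reported increment.  A protective RR below 1 therefore maps to
a positive Rg per unit of daily *deficit*, so downstream code can treat both
directions as "risk per unit of departure from the guideline".
"""

from __future__ import annotations

import csv
import math
import warnings
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

from pydantic import BaseModel, field_validator

from .errors import DataError
from .strata import FACTOR_UNITS, Direction, Factor, Sex, Unit


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up, the convention used for all report-facing values."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


class RiskEstimate(BaseModel, frozen=True):
    """A published RR per dose increment for one factor and sex stratum.

    ``ci_includes_null`` records that the source CI crossed 1; the point
    estimate is used unchanged and the flag travels as metadata only.
    """

    factor: Factor
    sex_stratum: Sex
    site: str = "colorectal"
    rr: float
    increment: float
    unit: Unit
    direction: Direction
    ci_includes_null: bool = False

    @field_validator("rr", "increment")
    @classmethod
    def _positive(cls, v: float, info) -> float:
        if not (v > 0 and math.isfinite(v)):
            raise ValueError(f"{info.field_name} must be a positive finite number, got {v}")
        return v

    def model_post_init(self, __context) -> None:
        if self.direction is Direction.detrimental and self.rr < 1:
            warnings.warn(
                f"detrimental factor {self.factor.value}/{self.sex_stratum.value} has RR "
                f"{self.rr} < 1; accepted as-is",
                stacklevel=2,
            )

    @property
    def key(self) -> tuple[Factor, Sex, str]:
        return (self.factor, self.sex_stratum, self.site)


class PerUnitRisk(BaseModel, frozen=True):
    """Log-risk slope per unit of daily consumption (or deficit)."""

    factor: Factor
    sex_stratum: Sex
    rg: float
    unit: Unit
    direction: Direction

    @property
    def rg_report(self) -> float:
        """Report-facing slope, rounded half-up to 4 decimal places."""
        return round_half_up(self.rg, 4)


def rg_from_rr(estimate: RiskEstimate) -> PerUnitRisk:
    """Convert a per-increment RR to a per-unit log-risk slope.

    Full precision is retained internally; rounding happens only at report
    time (:attr:`PerUnitRisk.rg_report`).
    """
    if estimate.direction is Direction.detrimental:
        rg = math.log(estimate.rr) / estimate.increment
    else:
        rg = math.log(1.0 / estimate.rr) / estimate.increment
    return PerUnitRisk(
        factor=estimate.factor,
        sex_stratum=estimate.sex_stratum,
        rg=rg,
        unit=estimate.unit,
        direction=estimate.direction,
    )


def rr_from_rg(risk: PerUnitRisk, increment: float) -> float:
    """Inverse of :func:`rg_from_rr`: reconstruct the RR at a given increment."""
    if risk.direction is Direction.detrimental:
        return math.exp(risk.rg * increment)
    return math.exp(-risk.rg * increment)


RISK_CSV_COLUMNS = [
    "factor",
    "sex_stratum",
    "site",
    "rr",
    "increment",
    "unit",
    "direction",
    "ci_includes_null",
]


class RiskTable:
    """The full set of risk estimates, unique per (factor, sex stratum, site)."""

    def __init__(self, estimates: list[RiskEstimate]):
        self._by_key: dict[tuple[Factor, Sex, str], RiskEstimate] = {}
        for est in estimates:
            if est.key in self._by_key:
                raise DataError(
                    f"duplicate risk estimate for "
                    f"({est.factor.value}, {est.sex_stratum.value}, {est.site})"
                )
            self._by_key[est.key] = est

    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self):
        return iter(self._by_key.values())

    def get(self, factor: Factor, sex: Sex, site: str = "colorectal") -> RiskEstimate:
        try:
            return self._by_key[(Factor(factor), Sex(sex), site)]
        except KeyError:
            raise DataError(f"no risk estimate for ({factor}, {sex}, {site})") from None

    def per_unit(self, factor: Factor, sex: Sex, site: str = "colorectal") -> PerUnitRisk:
        return rg_from_rr(self.get(factor, sex, site))


def load_risk_table(path: str | Path) -> RiskTable:
    """Read a risk-estimate CSV (schema ``RISK_CSV_COLUMNS``) into a RiskTable.

    Schema problems are reported with the offending row number; duplicated
    (factor, sex stratum, site) keys are rejected.
    """
    path = Path(path)
    estimates: list[RiskEstimate] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(RISK_CSV_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise DataError(f"{path.name}: missing columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                est = RiskEstimate(
                    factor=row["factor"],
                    sex_stratum=row["sex_stratum"],
                    site=row["site"],
                    rr=float(row["rr"]),
                    increment=float(row["increment"]),
                    unit=row["unit"],
                    direction=row["direction"],
                    ci_includes_null=row["ci_includes_null"].strip().lower()
                    in ("1", "true", "yes"),
                )
            except (ValueError, KeyError) as exc:
                raise DataError(f"{path.name} row {i}: {exc}") from exc
            if est.unit is not FACTOR_UNITS[est.factor]:
                raise DataError(
                    f"{path.name} row {i}: factor {est.factor.value} must be in "
                    f"{FACTOR_UNITS[est.factor].value}, got {est.unit.value}"
                )
            estimates.append(est)
    return RiskTable(estimates)


def write_risk_table(table: RiskTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(RISK_CSV_COLUMNS)
        for est in sorted(table, key=lambda e: (e.factor.value, e.sex_stratum.value, e.site)):
            w.writerow(
                [
                    est.factor.value,
                    est.sex_stratum.value,
                    est.site,
                    repr(est.rr),
                    repr(est.increment),
                    est.unit.value,
                    est.direction.value,
                    str(est.ci_includes_null).lower(),
                ]
            )
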