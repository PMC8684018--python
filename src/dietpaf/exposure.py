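"""Consumption records -> per-stratum exposure-category distributions.

Individual daily-consumption values (24-hour-recall style, optionally survey
weighted) are summarized per stratum into K ordered categories, each with a
prevalence p_x, consumption bounds, and a median.  Categories are always cut
so the guideline reference level is a boundary: category 1 holds the
compliant population (excess/deficit G_x = 0) and the remaining categories
partition the non-compliant side.

G_x, the average departure from the guideline inside category x, is

    detrimental factor:  G_x = max(0, median_x - reference)
    protective factor:   G_x = max(0, reference - median_x)

so over-adherence never confers modeled negative risk.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .errors import ComputationError, DataError
from .strata import FACTOR_UNITS, Factor, Race, Sex, StratumKey, Unit


# -- recommendations ---------------------------------------------------------

class Recommendation(BaseModel, frozen=True):
    """Guideline reference level for one factor.

    ``comparator='maximum'``: consumption above the reference is harmful
    (meats).  ``comparator='minimum'``: intake below the reference is
    insufficient (fiber, calcium).
    """

    factor: Factor
    reference_level: float = Field(ge=0)
    comparator: Literal["maximum", "minimum"]

    @property
    def unit(self) -> Unit:
        return FACTOR_UNITS[self.factor]

    def is_compliant(self, consumption: float) -> bool:
        """Consumption exactly at the reference counts as compliant."""
        if self.comparator == "maximum":
            return consumption <= self.reference_level
        return consumption >= self.reference_level

    def departure(self, consumption: float) -> float:
        """Excess (maximum-type) or deficit (minimum-type), clamped at 0."""
        if self.comparator == "maximum":
            return max(0.0, consumption - self.reference_level)
        return max(0.0, self.reference_level - consumption)


#: Guideline defaults: <=60 g/day red meat, 0 g/day processed meat,
#: >=28 g/day fiber, >=1000 mg/day calcium.
DEFAULT_RECOMMENDATIONS: dict[Factor, Recommendation] = {
    Factor.red_meat: Recommendation(factor=Factor.red_meat, reference_level=60.0, comparator="maximum"),
    Factor.processed_meat: Recommendation(factor=Factor.processed_meat, reference_level=0.0, comparator="maximum"),
    Factor.fiber: Recommendation(factor=Factor.fiber, reference_level=28.0, comparator="minimum"),
    Factor.calcium: Recommendation(factor=Factor.calcium, reference_level=1000.0, comparator="minimum"),
}


# -- records -----------------------------------------------------------------

class DietRecord(BaseModel, frozen=True):
    """One person's daily consumption of each factor, with a survey weight."""

    person_id: str
    age_band: str
    sex: Sex
    race: Race
    weight: float = 1.0
    consumption: dict[Factor, float]

    @model_validator(mode="after")
    def _check(self):
        if not (self.weight > 0 and math.isfinite(self.weight)):
            raise ValueError(f"record {self.person_id}: weight must be positive and finite")
        if self.sex is Sex.persons or self.race is Race.all:
            raise ValueError(f"record {self.person_id}: records need concrete sex and race")
        for f, v in self.consumption.items():
            if not (v >= 0 and math.isfinite(v)):
                raise ValueError(f"record {self.person_id}: {f} consumption {v} invalid")
        return self


# -- categories and distributions -------------------------------------------

class ExposureCategory(BaseModel, frozen=True):
    """One consumption level: half-open bounds [lower, upper), prevalence, median."""

    index: int = Field(ge=1)
    lower: float
    upper: float  # may be +inf
    median: float
    prevalence: float = Field(ge=0)

    @model_validator(mode="after")
    def _check(self):
        if not self.lower <= self.median <= self.upper:
            raise ValueError(
                f"category {self.index}: median {self.median} outside "
                f"[{self.lower}, {self.upper})"
            )
        return self


class ExposureDistribution(BaseModel, frozen=True):
    """Ordered category set for one factor in one stratum; prevalences sum to 1."""

    factor: Factor
    stratum: StratumKey
    categories: tuple[ExposureCategory, ...]

    @model_validator(mode="after")
    def _check(self):
        total = sum(c.prevalence for c in self.categories)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"{self.factor.value} {self.stratum}: prevalences sum to {total!r}, not 1"
            )
        if self.categories[0].lower != 0.0:
            raise ValueError("categories must start at consumption 0")
        if math.isfinite(self.categories[-1].upper):
            raise ValueError("last category must be open-ended (upper = inf)")
        for a, b in zip(self.categories, self.categories[1:]):
            if a.upper != b.lower:
                raise ValueError(
                    f"categories {a.index} and {b.index} do not tile: "
                    f"{a.upper} != {b.lower}"
                )
        return self


def gx(category: ExposureCategory, rec: Recommendation) -> float:
    """Average departure from the guideline within a category (clamped at 0)."""
    return rec.departure(category.median)


# -- weighted statistics -----------------------------------------------------

def weighted_median(values: Sequence[float], weights: Sequence[float]) -> float:
    """Weighted median of consumption values.

    The smallest value whose cumulative weight fraction reaches one half; when
    the half-weight point falls exactly on a value's boundary the median
    interpolates to the midpoint with the next value, so with unit weights
    this reduces to the ordinary sample median.
    """
    if len(values) == 0:
        raise ComputationError("weighted median of an empty set")
    order = np.argsort(values, kind="stable")
    v = np.asarray(values, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    cum = np.cumsum(w)
    half = cum[-1] / 2.0
    k = int(np.searchsorted(cum, half, side="left"))
    if math.isclose(cum[k], half, rel_tol=1e-12) and k + 1 < len(v):
        return float((v[k] + v[k + 1]) / 2.0)
    return float(v[k])


# -- category schemes --------------------------------------------------------

class CategoryScheme(BaseModel, frozen=True):
    """How to cut a stratum's consumption values into exposure categories.

    * ``quantile`` (default): category 1 = compliant side of the reference;
      the non-compliant side is split into ``n_noncompliant`` weighted
      quantile groups (quartiles by default).
    * ``fixed``: explicit bin edges (ascending, starting at 0; an implicit
      +inf closes the last bin); membership is half-open [lower, upper).
    * ``per_value``: one category per distinct consumption value — the full
      refinement used to check the categorical PAF against individual-level
      enumeration.
    """

    kind: Literal["quantile", "fixed", "per_value"] = "quantile"
    n_noncompliant: int = Field(default=4, ge=1)
    edges: tuple[float, ...] | None = None

    @model_validator(mode="after")
    def _check(self):
        if self.kind == "fixed":
            if not self.edges or len(self.edges) < 2:
                raise ValueError("fixed scheme needs at least two bin edges")
            if self.edges[0] != 0.0 or any(a >= b for a, b in zip(self.edges, self.edges[1:])):
                raise ValueError("fixed edges must be ascending and start at 0")
        return self


def _match(records: Iterable[DietRecord], factor: Factor, stratum: StratumKey):
    vals, wts = [], []
    for r in records:
        if factor in r.consumption and stratum.matches_record(r.age_band, r.sex, r.race):
            vals.append(r.consumption[factor])
            wts.append(r.weight)
    return np.asarray(vals, dtype=float), np.asarray(wts, dtype=float)


def _categories_from_groups(groups, total_w: float) -> list[ExposureCategory]:
    cats = []
    for idx, (lo, hi, v, w) in enumerate(groups, start=1):
        cats.append(
            ExposureCategory(
                index=idx,
                lower=lo,
                upper=hi,
                median=weighted_median(v, w) if len(v) else (lo if math.isfinite(lo) else 0.0),
                prevalence=float(np.sum(w)) / total_w,
            )
        )
    return cats


def build_distribution(
    records: Iterable[DietRecord],
    factor: Factor,
    stratum: StratumKey,
    scheme: CategoryScheme | None = None,
    rec: Recommendation | None = None,
) -> ExposureDistribution:
    """Summarize matching records into an ExposureDistribution.

    ``sex=persons`` pools both sexes and ``race=all`` pools all races at the
    record level.  Prevalences are weight fractions; medians are weighted
    medians of within-category consumption.  A stratum with no matching
    records raises, never returns silent zeros.
    """
    scheme = scheme or CategoryScheme()
    rec = rec or DEFAULT_RECOMMENDATIONS[factor]
    v, w = _match(records, factor, stratum)
    if len(v) == 0:
        raise ComputationError(f"no records for factor {factor.value} in stratum {stratum}")
    total_w = float(np.sum(w))

    if scheme.kind == "fixed":
        edges = list(scheme.edges) + [math.inf]
        groups = []
        for lo, hi in zip(edges, edges[1:]):
            m = (v >= lo) & (v < hi)
            if m.any():
                groups.append((lo, hi, v[m], w[m]))
        # re-tile after dropping empty bins so bounds stay contiguous
        groups = _retile(groups)
        return ExposureDistribution(
            factor=factor, stratum=stratum, categories=tuple(_categories_from_groups(groups, total_w))
        )

    if scheme.kind == "per_value":
        uniq = np.unique(v)
        edges = [0.0] + [float((a + b) / 2) for a, b in zip(uniq, uniq[1:])] + [math.inf]
        groups = []
        for u, lo, hi in zip(uniq, edges, edges[1:]):
            m = v == u
            groups.append((lo, hi, v[m], w[m]))
        return ExposureDistribution(
            factor=factor, stratum=stratum, categories=tuple(_categories_from_groups(groups, total_w))
        )

    # quantile scheme: compliant category + weighted quantile cut of the rest
    compliant = np.array([rec.is_compliant(x) for x in v])
    ref = rec.reference_level
    groups: list[tuple[float, float, np.ndarray, np.ndarray]] = []
    vn, wn = v[~compliant], w[~compliant]
    if rec.comparator == "maximum":
        cut_edges = _weighted_quantile_edges(vn, wn, scheme.n_noncompliant) if len(vn) else []
        inner = [ref] + cut_edges + [math.inf]
        if compliant.any() or len(vn) == 0:
            groups.append((0.0, inner[0] if len(vn) else math.inf, v[compliant], w[compliant]))
        for lo, hi in zip(inner, inner[1:]):
            m = (~compliant) & (v > lo) & (v <= hi if math.isfinite(hi) else np.ones_like(v, bool))
            if m.any():
                groups.append((lo, hi, v[m], w[m]))
    else:
        # minimum-type: non-compliant side is below the reference
        cut_edges = _weighted_quantile_edges(vn, wn, scheme.n_noncompliant) if len(vn) else []
        inner = [0.0] + cut_edges + [ref]
        for lo, hi in zip(inner, inner[1:]):
            m = (~compliant) & (v >= lo) & (v < hi)
            if m.any():
                groups.append((lo, hi, v[m], w[m]))
        if compliant.any() or len(vn) == 0:
            groups.append((ref if len(groups) else 0.0, math.inf, v[compliant], w[compliant]))
    groups = _retile(groups)
    return ExposureDistribution(
        factor=factor, stratum=stratum, categories=tuple(_categories_from_groups(groups, total_w))
    )


def _weighted_quantile_edges(v: np.ndarray, w: np.ndarray, k: int) -> list[float]:
    """Interior cut points splitting (v, w) into k roughly equal-weight groups."""
    if len(v) == 0 or k <= 1:
        return []
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cum = np.cumsum(w) / np.sum(w)
    edges = []
    for j in range(1, k):
        i = int(np.searchsorted(cum, j / k, side="left"))
        edges.append(float(v[min(i, len(v) - 1)]))
    # dedupe while preserving order; duplicate quantiles collapse categories
    out: list[float] = []
    for e in edges:
        if not out or e > out[-1]:
            out.append(e)
    return out


def _retile(groups):
    """Force contiguous [0, inf) coverage after empty bins were dropped."""
    if not groups:
        return groups
    tiled = []
    lo = 0.0
    for i, (_, hi, v, w) in enumerate(groups):
        hi_eff = math.inf if i == len(groups) - 1 else hi
        # keep medians inside bounds even after extending the bin downward
        tiled.append((lo, hi_eff, v, w))
        lo = hi_eff
    return tiled


# -- adherence ---------------------------------------------------------------

def adherence_prevalence(
    records: Iterable[DietRecord],
    factor: Factor,
    rec: Recommendation,
    stratum: StratumKey,
) -> float:
    """Weight fraction of a stratum NOT meeting the recommendation.

    (The published adherence tables report "prevalence not meeting
    recommendations", so this is the number they print.)  Strictly above a
    maximum-type reference, or strictly below a minimum-type one.
    """
    v, w = _match(records, factor, stratum)
    if len(v) == 0:
        raise ComputationError(f"no records for factor {factor.value} in stratum {stratum}")
    noncompliant = np.array([not rec.is_compliant(x) for x in v])
    return float(np.sum(w[noncompliant]) / np.sum(w))


# -- CSV i/o -----------------------------------------------------------------

EXPOSURE_CSV_COLUMNS = [
    "factor", "age_band", "sex", "race", "category_index",
    "lower", "upper", "median", "prevalence",
]

RECORDS_CSV_COLUMNS = ["person_id", "age_band", "sex", "race", "weight", "factor", "consumption"]


def write_exposure_table(dists: Iterable[ExposureDistribution], path: str | Path) -> None:
    """Write distributions to CSV; values keep full precision (lossless round-trip)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(EXPOSURE_CSV_COLUMNS)
        for d in dists:
            for c in d.categories:
                w.writerow(
                    [
                        d.factor.value, d.stratum.age_band, d.stratum.sex.value,
                        d.stratum.race.value, c.index,
                        repr(c.lower), "inf" if math.isinf(c.upper) else repr(c.upper),
                        repr(c.median), repr(c.prevalence),
                    ]
                )


def load_exposure_table(path: str | Path) -> list[ExposureDistribution]:
    """Read an exposure CSV back into distributions, validating normalization."""
    path = Path(path)
    rows: dict[tuple, list] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(EXPOSURE_CSV_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise DataError(f"{path.name}: missing columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                key = (row["factor"], row["age_band"], row["sex"], row["race"])
                cat = ExposureCategory(
                    index=int(row["category_index"]),
                    lower=float(row["lower"]),
                    upper=float(row["upper"]),
                    median=float(row["median"]),
                    prevalence=float(row["prevalence"]),
                )
            except ValueError as exc:
                raise DataError(f"{path.name} row {i}: {exc}") from exc
            if cat.prevalence > 1:
                raise DataError(f"{path.name} row {i}: prevalence {cat.prevalence} > 1")
            rows.setdefault(key, []).append(cat)
    dists = []
    for (factor, band, sex, race), cats in rows.items():
        cats.sort(key=lambda c: c.index)
        try:
            dists.append(
                ExposureDistribution(
                    factor=Factor(factor),
                    stratum=StratumKey(age_band=band, sex=Sex(sex), race=Race(race)),
                    categories=tuple(cats),
                )
            )
        except ValueError as exc:
            raise DataError(f"{path.name}: ({factor}, {band}, {sex}, {race}): {exc}") from exc
    return dists


def write_records(records: Iterable[DietRecord], path: str | Path) -> None:
    """Long-format records CSV: one row per (person, factor)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(RECORDS_CSV_COLUMNS)
        for r in records:
            for f in sorted(r.consumption, key=lambda f: f.value):
                w.writerow(
                    [r.person_id, r.age_band, r.sex.value, r.race.value,
                     repr(r.weight), f.value, repr(r.consumption[f])]
                )


def load_records(path: str | Path) -> list[DietRecord]:
    path = Path(path)
    by_person: dict[str, dict] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(RECORDS_CSV_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise DataError(f"{path.name}: missing columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                p = by_person.setdefault(
                    row["person_id"],
                    dict(
                        person_id=row["person_id"], age_band=row["age_band"],
                        sex=Sex(row["sex"]), race=Race(row["race"]),
                        weight=float(row["weight"]), consumption={},
                    ),
                )
                p["consumption"][Factor(row["factor"])] = float(row["consumption"])
            except ValueError as exc:
                raise DataError(f"{path.name} row {i}: {exc}") from exc
    return [DietRecord(**p) for p in by_person.values()]
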