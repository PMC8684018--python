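"""Cancer-registry count tables: loading, validation, colorectal site selection.

Counts are integers keyed by (site group, age band, sex, race).  Two site
groups are recognised: ``colorectal`` (ICD-O-3 topography C18-C20: colon,
rectosigmoid junction, rectum) and ``all_excl_bcc_scc`` (all invasive cancers
excluding basal and squamous cell carcinoma of the skin).  Colorectal counts
may be supplied directly or derived from a per-topography-code table.
"""

from __future__ import annotations

import csv
import re
from pathlib import Path
from typing import Iterable

from .errors import DataError
from .strata import Race, Sex

SITE_GROUPS = ("colorectal", "all_excl_bcc_scc")

_CODE_RE = re.compile(r"^C(\d{2})(?:\.(\d))?$")


def is_colorectal(site_code: str) -> bool:
    """True iff an ICD-O-3 topography code falls in C18-C20 (sub-sites included)."""
    m = _CODE_RE.match(site_code.strip().upper())
    if not m:
        raise DataError(f"malformed ICD-O-3 topography code {site_code!r}")
    return int(m.group(1)) in (18, 19, 20)


INCIDENCE_CSV_COLUMNS = ["site_group", "age_band", "sex", "race", "count"]
SITE_CODE_CSV_COLUMNS = ["site_code", "age_band", "sex", "race", "count"]

Cell = tuple[str, str, Sex, Race]


class IncidenceTable:
    """Map (site_group, age_band, sex, race) -> non-negative integer count."""

    def __init__(self, cells: dict[Cell, int]):
        self.cells: dict[Cell, int] = {}
        for (site, band, sex, race), n in cells.items():
            if int(n) != n or n < 0:
                raise DataError(f"count for ({site}, {band}, {sex}, {race}) is {n!r}; "
                                "counts must be non-negative integers")
            self.cells[(site, band, Sex(sex), Race(race))] = int(n)

    def __len__(self) -> int:
        return len(self.cells)

    def get(self, site_group: str, age_band: str, sex: Sex, race: Race) -> int:
        key = (site_group, age_band, Sex(sex), Race(race))
        if key not in self.cells:
            raise DataError(
                f"missing incidence cell ({site_group}, {age_band}, "
                f"{Sex(sex).value}, {Race(race).value})"
            )
        return self.cells[key]

    def has(self, site_group: str, age_band: str, sex: Sex, race: Race) -> bool:
        return (site_group, age_band, Sex(sex), Race(race)) in self.cells

    def age_bands(self, site_group: str) -> list[str]:
        return sorted(
            {b for (s, b, _, _) in self.cells if s == site_group and b != "all"}
        )


def validate_marginals(table: IncidenceTable, strict: bool = False) -> list[str]:
    """Check supplied pooled cells against their component sums.

    Wherever a ``persons`` cell coexists with both sex cells, or an ``all``
    race cell with all four race cells, the pooled count must equal the sum.
    Returns the list of inconsistency messages; raises instead when strict.
    """
    report: list[str] = []
    for (site, band, sex, race), n in table.cells.items():
        if sex is Sex.persons:
            if table.has(site, band, Sex.men, race) and table.has(site, band, Sex.women, race):
                s = table.get(site, band, Sex.men, race) + table.get(site, band, Sex.women, race)
                if s != n:
                    report.append(
                        f"({site}, {band}, persons, {race.value}): {n} != men+women = {s}"
                    )
        if race is Race.all:
            parts = [Race.nh_white, Race.nh_black, Race.hispanic, Race.other]
            if all(table.has(site, band, sex, r) for r in parts):
                s = sum(table.get(site, band, sex, r) for r in parts)
                if s != n:
                    report.append(
                        f"({site}, {band}, {sex.value}, all): {n} != race sum = {s}"
                    )
    if strict and report:
        raise DataError("inconsistent marginals:\n  " + "\n  ".join(report))
    return report


def load_incidence(path: str | Path, strict: bool = False) -> IncidenceTable:
    """Read an incidence CSV; validates marginals (warnings unless strict)."""
    path = Path(path)
    cells: dict[Cell, int] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(INCIDENCE_CSV_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise DataError(f"{path.name}: missing columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            if row["site_group"] not in SITE_GROUPS:
                raise DataError(f"{path.name} row {i}: unknown site group {row['site_group']!r}")
            try:
                raw = float(row["count"])
                if raw != int(raw) or raw < 0:
                    raise ValueError(f"count {row['count']!r} not a non-negative integer")
                key = (row["site_group"], row["age_band"], Sex(row["sex"]), Race(row["race"]))
                if key in cells:
                    raise ValueError(f"duplicate cell {key}")
                cells[key] = int(raw)
            except ValueError as exc:
                raise DataError(f"{path.name} row {i}: {exc}") from exc
    table = IncidenceTable(cells)
    validate_marginals(table, strict=strict)
    return table


def write_incidence(table: IncidenceTable, path: str | Path) -> None:
    """Write with a canonical row sort so load/write round-trips byte-identically."""
    rows = sorted(
        ((s, b, sex.value, race.value, n) for (s, b, sex, race), n in table.cells.items()),
    )
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(INCIDENCE_CSV_COLUMNS)
        w.writerows(rows)


def colorectal_from_site_codes(path: str | Path) -> IncidenceTable:
    """Aggregate a per-topography-code count CSV into colorectal counts."""
    path = Path(path)
    cells: dict[Cell, int] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(SITE_CODE_CSV_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise DataError(f"{path.name}: missing columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                if not is_colorectal(row["site_code"]):
                    continue
                key = ("colorectal", row["age_band"], Sex(row["sex"]), Race(row["race"]))
                cells[key] = cells.get(key, 0) + int(row["count"])
            except (ValueError, DataError) as exc:
                raise DataError(f"{path.name} row {i}: {exc}") from exc
    return IncidenceTable(cells)


def merge_tables(tables: Iterable[IncidenceTable]) -> IncidenceTable:
    cells: dict[Cell, int] = {}
    for t in tables:
        for k, n in t.cells.items():
            if k in cells:
                raise DataError(f"duplicate cell {k} while merging incidence tables")
            cells[k] = n
    return IncidenceTable(cells)
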