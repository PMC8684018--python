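"""End-to-end orchestration: records + risks + counts -> burden tables.

For every factor and (sex, race/ethnicity) cell the pipeline builds
per-age-band exposure distributions, computes PAFs, pairs them with the
incidence band one latency offset older, multiplies by case counts,
aggregates case-weighted over age, combines factors additively, and
re-expresses colorectal excess against the all-cancer denominator.  Outputs
are deterministic files (no timestamps), so identical inputs give
byte-identical results.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, Field

from . import __version__
from .errors import ComputationError, ConfigError
from .exposure import (
    DEFAULT_RECOMMENDATIONS,
    CategoryScheme,
    build_distribution,
    load_records,
)
from .incidence_io import IncidenceTable, load_incidence
from .paf_engine import (
    PAFResult,
    aggregate_age_weighted,
    allcancer_scope,
    combine_factors,
    complement_combine,
    excess_cases,
    paf_single,
    pair_latency,
)
from .risk_models import RiskTable, load_risk_table
from .strata import DEFAULT_PREVALENCE_BANDS, Factor, Race, Sex, StratumKey

REPORT_SEXES = (Sex.men, Sex.women, Sex.persons)
REPORT_RACES = (Race.all, Race.nh_white, Race.nh_black, Race.hispanic, Race.other)
FACTOR_ORDER = (Factor.red_meat, Factor.processed_meat, Factor.fiber, Factor.calcium)


class RunConfig(BaseModel, frozen=True):
    """Everything a pipeline run needs; file paths must exist."""

    risk_path: Path
    records_path: Path
    incidence_path: Path
    out_dir: Path
    prevalence_bands: tuple[str, ...] = tuple(DEFAULT_PREVALENCE_BANDS)
    scheme: CategoryScheme = CategoryScheme()
    latency_offset: int = Field(default=10, ge=0)
    rr_policy: Literal["sex_specific", "persons_everywhere"] = "sex_specific"
    combination: Literal["additive", "complement"] = "additive"
    strict_marginals: bool = False

    def validate_paths(self) -> None:
        for p in (self.risk_path, self.records_path, self.incidence_path):
            if not Path(p).is_file():
                raise ConfigError(f"input file not found: {p}")


def _rg_sex(policy: str, sex: Sex) -> Sex:
    """Which published RR row to use for a report row: sex rows take the
    sex-specific RR; pooled rows take the persons RR (pooled prevalence)."""
    return Sex.persons if policy == "persons_everywhere" else sex


def compute_results(
    records,
    risk_table: RiskTable,
    incidence: IncidenceTable,
    cfg: RunConfig,
) -> list[PAFResult]:
    """The full result set: per factor and all-factors, both site scopes,
    every (sex, race) report cell present in the incidence table."""
    inc_bands = incidence.age_bands("colorectal")
    if not inc_bands:
        raise ComputationError("incidence table has no colorectal age-band cells")
    latency = pair_latency(list(cfg.prevalence_bands), inc_bands, cfg.latency_offset)
    combine = combine_factors if cfg.combination == "additive" else complement_combine

    results: list[PAFResult] = []
    for sex in REPORT_SEXES:
        for race in REPORT_RACES:
            if not all(incidence.has("colorectal", b, sex, race) for b in inc_bands):
                continue
            per_factor: list[PAFResult] = []
            total_allcancer = sum(
                incidence.get("all_excl_bcc_scc", b, sex, race) for b in inc_bands
            )
            for factor in FACTOR_ORDER:
                rg = risk_table.per_unit(factor, _rg_sex(cfg.rr_policy, sex))
                rec = DEFAULT_RECOMMENDATIONS[factor]
                paf_by_band = {}
                for band in cfg.prevalence_bands:
                    dist = build_distribution(
                        records, factor, StratumKey(age_band=band, sex=sex, race=race),
                        scheme=cfg.scheme, rec=rec,
                    )
                    paf_by_band[band] = paf_single(dist, rg, rec)
                per_band = excess_cases(
                    paf_by_band, incidence, latency, factor.value, sex, race
                )
                agg = aggregate_age_weighted(per_band)
                per_factor.append(agg)
                results.append(agg)
                results.append(allcancer_scope(agg, total_allcancer))
            combined = combine(per_factor)
            results.append(combined)
            results.append(allcancer_scope(combined, total_allcancer))
    return results


RESULTS_CSV_COLUMNS = [
    "factor", "site_scope", "sex", "race",
    "paf_percent", "excess_cases", "case_count", "paf_full", "excess_full",
]


def write_results_csv(results: list[PAFResult], path: Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(RESULTS_CSV_COLUMNS)
        for r in results:
            w.writerow(
                [
                    r.factor, r.site_scope, r.stratum.sex.value, r.stratum.race.value,
                    f"{r.paf_percent:.1f}", r.excess_rounded, r.case_count,
                    repr(r.paf), repr(r.excess_cases),
                ]
            )


def render_table3(results: list[PAFResult]) -> str:
    """Text grid in the published layout: race blocks x (men/women/persons)
    rows, one column pair per factor plus all factors, each cell
    'colorectal-PAF% | all-cancer-PAF% (excess cases)'.  Missing cells render
    as '-', never as zeros."""
    cols = [f.value for f in FACTOR_ORDER] + ["all_factors"]
    index: dict[tuple[str, str, Sex, Race], PAFResult] = {
        (r.factor, r.site_scope, r.stratum.sex, r.stratum.race): r for r in results
    }
    lines = []
    header = ["race", "sex"] + [f"{c} crc%|all% (excess)" for c in cols]
    widths = [16, 8] + [max(len(h), 22) for h in header[2:]]
    lines.append("  ".join(h.ljust(w) for h, w in zip(header, widths)))
    for race in REPORT_RACES:
        for sex in REPORT_SEXES:
            row = [race.value.ljust(widths[0]), sex.value.ljust(widths[1])]
            any_cell = False
            for i, c in enumerate(cols):
                crc = index.get((c, "colorectal", sex, race))
                allc = index.get((c, "all_cancers", sex, race))
                if crc is None and allc is None:
                    cell = "-"
                else:
                    any_cell = True
                    crc_s = f"{crc.paf_percent:.1f}" if crc else "-"
                    all_s = (
                        f"{allc.paf_percent:.1f} ({allc.excess_rounded})" if allc else "-"
                    )
                    cell = f"{crc_s} | {all_s}"
                row.append(cell.ljust(widths[2 + i]))
            if any_cell:
                lines.append("  ".join(row).rstrip())
    return "\n".join(lines) + "\n"


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> list[PAFResult]:
    """Run end to end and write results, a table grid, a JSON summary and a
    provenance log under ``cfg.out_dir``.  Returns the result list."""
    cfg.validate_paths()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    risk_table = load_risk_table(cfg.risk_path)
    records = load_records(cfg.records_path)
    incidence = load_incidence(cfg.incidence_path, strict=cfg.strict_marginals)
    results = compute_results(records, risk_table, incidence, cfg)

    write_results_csv(results, out / "results.csv")
    (out / "table3.txt").write_text(render_table3(results))

    summary = {
        "n_results": len(results),
        "cells": {
            f"{r.factor}/{r.site_scope}/{r.stratum.sex.value}/{r.stratum.race.value}": {
                "paf_percent": r.paf_percent,
                "excess_cases": r.excess_rounded,
                "case_count": r.case_count,
            }
            for r in results
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")

    provenance = {
        "dietpaf_version": __version__,
        "inputs": {
            "risk": {"path": str(cfg.risk_path), "sha256": _sha256(cfg.risk_path)},
            "records": {"path": str(cfg.records_path), "sha256": _sha256(cfg.records_path)},
            "incidence": {"path": str(cfg.incidence_path), "sha256": _sha256(cfg.incidence_path)},
        },
        "config": json.loads(cfg.model_dump_json()),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True) + "\n")
    return results
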