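"""Configuration-driven grid runner: every exposure-outcome pair goes
through selection, harmonization and the sensitivity battery, and the
results land as a report-shaped TSV plus a full-precision JSON bundle.
"""
from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .errors import ConfigurationError, TsmrError
from .sensitivity import SensitivityConfig, SensitivityReport, run_sensitivity
from .summary_io import (
    DEFAULT_COLUMN_MAP,
    LdMap,
    apply_pleiotropy_tags,
    harmonize,
    ld_prune,
    read_pleiotropy_tags,
    read_summary_table,
    significance_filter,
)
from .types import GwasAssociation, InstrumentSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TableSpec:
    id: str
    path: Path
    column_map: dict = field(default_factory=lambda: dict(DEFAULT_COLUMN_MAP))
    binary: bool = True
    rescale: float = 1.0  # multiplies exposure beta/se, e.g. per-SD -> per-100%


@dataclass
class AnalysisConfig:
    exposures: list[TableSpec]
    outcomes: list[TableSpec]
    tags_path: Path | None = None
    ld_path: Path | None = None
    p_threshold: float = 5e-8
    r2_threshold: float = 0.8
    n_boot: int = 1000
    seed: int = 0
    egger_residual_variance: str = "none"
    out_dir: Path = Path("results")

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold <= 1):
            raise ConfigurationError("p_threshold must be in (0, 1]")
        if not (0 < self.r2_threshold <= 1):
            raise ConfigurationError("r2_threshold must be in (0, 1]")
        for spec in list(self.exposures) + list(self.outcomes):
            if not Path(spec.path).exists():
                raise ConfigurationError(f"input table not found: {spec.path}")
        for path in (self.tags_path, self.ld_path):
            if path is not None and not Path(path).exists():
                raise ConfigurationError(f"input file not found: {path}")

    def canonical_hash(self) -> str:
        payload = {
            "exposures": [
                [s.id, str(s.path), s.column_map, s.binary, s.rescale]
                for s in self.exposures
            ],
            "outcomes": [
                [s.id, str(s.path), s.column_map, s.binary] for s in self.outcomes
            ],
            "tags_path": str(self.tags_path),
            "ld_path": str(self.ld_path),
            "p_threshold": self.p_threshold,
            "r2_threshold": self.r2_threshold,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "egger_residual_variance": self.egger_residual_variance,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from YAML; relative paths resolve
    against the config file's directory."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    base = path.parent

    def _resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    def _table(entry, binary_default=True):
        return TableSpec(
            id=entry["id"],
            path=_resolve(entry["path"]),
            column_map=dict(entry.get("column_map") or DEFAULT_COLUMN_MAP),
            binary=bool(entry.get("binary", binary_default)),
            rescale=float(entry.get("rescale", 1.0)),
        )

    try:
        exposures = [_table(e) for e in raw["exposures"]]
        outcomes = [_table(o) for o in raw["outcomes"]]
    except KeyError as exc:
        raise ConfigurationError(f"config missing key {exc}") from None
    return AnalysisConfig(
        exposures=exposures,
        outcomes=outcomes,
        tags_path=_resolve(raw["tags_path"]) if raw.get("tags_path") else None,
        ld_path=_resolve(raw["ld_path"]) if raw.get("ld_path") else None,
        p_threshold=float(raw.get("p_threshold", 5e-8)),
        r2_threshold=float(raw.get("r2_threshold", 0.8)),
        n_boot=int(raw.get("n_boot", 1000)),
        seed=int(raw.get("seed", 0)),
        egger_residual_variance=str(raw.get("egger_residual_variance", "none")),
        out_dir=_resolve(raw.get("out_dir", "results")),
    )


def build_instrument_set(
    exposure: list[GwasAssociation],
    outcome: list[GwasAssociation],
    exposure_id: str,
    outcome_id: str,
    p_threshold: float = 5e-8,
    r2: LdMap | None = None,
    r2_threshold: float = 0.8,
    tags: dict | None = None,
) -> InstrumentSet:
    """Select, prune and harmonize one exposure-outcome pair into an
    :class:`InstrumentSet` with a complete exclusion log."""
    log: list[tuple[str, str]] = []
    selected = significance_filter(exposure, p_threshold)
    for rec in exposure:
        if rec not in selected:
            log.append((rec.snp_id, f"p>={p_threshold:g}"))
    pruned = ld_prune(selected, r2 or LdMap(), r2_threshold, exclusion_log=log)
    instruments = harmonize(pruned, outcome, report=log)
    if tags:
        instruments = apply_pleiotropy_tags(instruments, tags)
    return InstrumentSet(
        exposure_id=exposure_id,
        outcome_id=outcome_id,
        instruments=instruments,
        exclusion_log=log,
    )


@dataclass
class GridResult:
    reports: list[SensitivityReport]
    instrument_sets: list[InstrumentSet]
    failures: list[tuple[str, str, str]]  # (exposure_id, outcome_id, error)

    @property
    def ok(self) -> bool:
        return not self.failures


def run_grid(config: AnalysisConfig, write: bool = True) -> GridResult:
    """Run the full exposure x outcome grid.

    Pairs that fail validation are reported in ``failures`` and skipped;
    the rest of the grid still runs. When ``write`` is true the report
    table, JSON bundle, per-pair instrument logs and a run log are written
    under ``config.out_dir``.
    """
    tags = read_pleiotropy_tags(config.tags_path) if config.tags_path else {}
    ld = LdMap.from_csv(config.ld_path) if config.ld_path else LdMap()

    exposure_cache = {
        spec.id: _read_rescaled(spec) for spec in config.exposures
    }
    outcome_cache = {
        spec.id: read_summary_table(spec.path, spec.column_map, spec.id)
        for spec in config.outcomes
    }

    reports, sets, failures = [], [], []
    for exp_spec in config.exposures:
        for out_spec in config.outcomes:
            try:
                iset = build_instrument_set(
                    exposure_cache[exp_spec.id],
                    outcome_cache[out_spec.id],
                    exp_spec.id,
                    out_spec.id,
                    p_threshold=config.p_threshold,
                    r2=ld,
                    r2_threshold=config.r2_threshold,
                    tags=tags,
                )
                report = run_sensitivity(
                    iset,
                    config=SensitivityConfig(
                        binary_outcome=out_spec.binary,
                        n_boot=config.n_boot,
                        seed=config.seed,
                        egger_residual_variance=config.egger_residual_variance,
                    ),
                )
            except TsmrError as exc:
                logger.error("%s -> %s failed: %s", exp_spec.id, out_spec.id, exc)
                failures.append((exp_spec.id, out_spec.id, str(exc)))
                continue
            reports.append(report)
            sets.append(iset)

    result = GridResult(reports=reports, instrument_sets=sets, failures=failures)
    if write:
        write_grid_outputs(result, config)
    return result


def _read_rescaled(spec: TableSpec) -> list[GwasAssociation]:
    records = read_summary_table(spec.path, spec.column_map, spec.id)
    if spec.rescale == 1.0:
        return records
    from dataclasses import replace

    return [
        replace(r, beta=r.beta * spec.rescale, se=r.se * spec.rescale)
        for r in records
    ]


# --------------------------------------------------------------------------
# Report writing
# --------------------------------------------------------------------------


def _fmt_est(value: float | None) -> str:
    return "" if value is None else f"{value:.2f}"


def _fmt_int(value: float | None) -> str:
    return "" if value is None else f"{value:.2g}"


def report_rows(report: SensitivityReport, binary: bool) -> list[list[str]]:
    """Flatten one sensitivity report into report-table rows."""

    def est_cells(est):
        if est is None:
            return ["", "", "", ""]
        if binary:
            return [est.method, _fmt_est(est.or_point), _fmt_est(est.or_low), _fmt_est(est.or_high)]
        return [est.method, _fmt_est(est.beta), _fmt_est(est.ci_low), _fmt_est(est.ci_high)]

    def intercept_cells(egger):
        if egger is None:
            return ["", ""]
        return [_fmt_int(egger.egger_intercept), _fmt_int(egger.egger_intercept_p)]

    rows = []
    for subset, primary, secondary, egger in (
        ("all", report.primary, report.secondary, report.egger_all),
        ("excl_pleiotropic", report.primary_excl, report.secondary_excl, report.egger_excl),
    ):
        if primary is None:
            continue
        base = [report.outcome_id, report.exposure_id, subset, str(primary.n_snps)]
        rows.append(base + est_cells(primary) + intercept_cells(egger))
        if secondary is not None and secondary.method != "IVW":
            rows.append(base + est_cells(secondary) + ["", ""])
    return rows


HEADER = [
    "outcome",
    "exposure",
    "snp_subset",
    "n_snps",
    "method",
    "estimate",
    "ci_low",
    "ci_high",
    "egger_intercept",
    "egger_intercept_p",
]


def write_grid_outputs(result: GridResult, config: AnalysisConfig) -> dict[str, Path]:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    binary_by_outcome = {spec.id: spec.binary for spec in config.outcomes}

    table_path = out_dir / "mr_report.tsv"
    with table_path.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(HEADER)
        for report in result.reports:
            for row in report_rows(report, binary_by_outcome[report.outcome_id]):
                writer.writerow(row)

    json_path = out_dir / "mr_report.json"
    json_path.write_text(
        json.dumps([r.to_dict() for r in result.reports], indent=2) + "\n"
    )

    sets_path = out_dir / "instrument_sets.json"
    sets_path.write_text(
        json.dumps(
            [
                {
                    "exposure_id": s.exposure_id,
                    "outcome_id": s.outcome_id,
                    "snp_ids": s.snp_ids,
                    "instruments": [
                        {
                            "snp_id": i.snp_id,
                            "effect_allele": i.effect_allele,
                            "gamma_hat": i.gamma_hat,
                            "se_gamma": i.se_gamma,
                            "big_gamma_hat": i.big_gamma_hat,
                            "se_big_gamma": i.se_big_gamma,
                            "pleiotropy_tags": sorted(i.pleiotropy_tags),
                            "gene_label": i.gene_label,
                        }
                        for i in s.instruments
                    ],
                    "exclusion_log": [
                        {"snp_id": snp, "reason": reason}
                        for snp, reason in s.exclusion_log
                    ],
                }
                for s in result.instrument_sets
            ],
            indent=2,
        )
        + "\n"
    )

    log_path = out_dir / "run_log.json"
    log_path.write_text(
        json.dumps(
            {
                "package_version": __version__,
                "config_hash": config.canonical_hash(),
                "seed": config.seed,
                "n_boot": config.n_boot,
                "failures": [
                    {"exposure_id": e, "outcome_id": o, "error": msg}
                    for e, o, msg in result.failures
                ],
            },
            indent=2,
        )
        + "\n"
    )
    return {
        "table": table_path,
        "json": json_path,
        "sets": sets_path,
        "log": log_path,
    }
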