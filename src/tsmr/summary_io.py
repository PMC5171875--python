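"""Reading, validation, harmonization and selection of GWAS summary statistics.

Instrument selection follows the conventional two-sample MR workflow:
genome-wide-significance filtering, greedy LD pruning by ascending p-value,
allele harmonization onto a common effect allele, and removal of instruments
annotated as directly associated with the outcome (pleiotropy tags supplied
as input data, never looked up live).
"""
from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import replace
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError, HarmonizationError, RowValidationError
from .types import GwasAssociation, HarmonizedInstrument, InstrumentSet

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = ("snp_id", "effect_allele", "beta", "se", "p_value")
OPTIONAL_COLUMNS = ("other_allele", "eaf", "n")

#: Default column map for tables written by this package.
DEFAULT_COLUMN_MAP = {
    "snp_id": "snp_id",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "beta": "beta",
    "se": "se",
    "p_value": "p_value",
    "eaf": "eaf",
    "n": "n",
}


def read_summary_table(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    trait_id: str = "",
    sep: str | None = None,
) -> list[GwasAssociation]:
    """Read a delimited GWAS summary table into validated records.

    Parameters
    ----------
    path
        CSV or TSV file. Delimiter is sniffed from the extension unless
        ``sep`` is given.
    column_map
        Maps field names (``snp_id``, ``effect_allele``, ``other_allele``,
        ``beta``, ``se``, ``p_value``, ``eaf``, ``n``) to column headers in
        the file. Optional fields may be omitted.
    trait_id
        Trait label stamped on every record.

    Raises
    ------
    ConfigurationError
        If a mandatory column is missing from the map or the file.
    RowValidationError
        Listing every offending row (1-based, header excluded) and reason.
    """
    column_map = dict(column_map or DEFAULT_COLUMN_MAP)
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    for key in MANDATORY_COLUMNS:
        if key not in column_map:
            raise ConfigurationError(f"column map is missing mandatory field {key!r}")
        if column_map[key] not in frame.columns:
            raise ConfigurationError(
                f"column {column_map[key]!r} (field {key!r}) not found in {path}"
            )
    present_optional = {
        key: column_map[key]
        for key in OPTIONAL_COLUMNS
        if key in column_map and column_map[key] in frame.columns
    }

    records: list[GwasAssociation] = []
    offenders: list[tuple[int, str]] = []
    for idx, row in enumerate(frame.itertuples(index=False), start=1):
        rowmap = dict(zip(frame.columns, row))
        try:
            records.append(_row_to_association(rowmap, column_map, present_optional, trait_id))
        except (ValueError, KeyError) as exc:
            offenders.append((idx, str(exc)))
    if offenders:
        raise RowValidationError(offenders)
    return records


def _parse_float(raw: str, name: str) -> float:
    try:
        return float(raw)
    except ValueError:
        raise ValueError(f"non-numeric {name}: {raw!r}") from None


def _row_to_association(rowmap, column_map, present_optional, trait_id) -> GwasAssociation:
    snp_id = rowmap[column_map["snp_id"]].strip()
    other = None
    if "other_allele" in present_optional:
        raw = rowmap[present_optional["other_allele"]].strip().upper()
        other = raw or None
    eaf = n = None
    if "eaf" in present_optional:
        raw = rowmap[present_optional["eaf"]].strip()
        eaf = _parse_float(raw, "eaf") if raw else None
    if "n" in present_optional:
        raw = rowmap[present_optional["n"]].strip()
        n = _parse_float(raw, "n") if raw else None
    return GwasAssociation(
        snp_id=snp_id,
        effect_allele=rowmap[column_map["effect_allele"]].strip().upper(),
        other_allele=other,
        beta=_parse_float(rowmap[column_map["beta"]], "beta"),
        se=_parse_float(rowmap[column_map["se"]], "se"),
        p_value=_parse_float(rowmap[column_map["p_value"]], "p-value"),
        eaf=eaf,
        n=n,
        trait_id=trait_id,
    )


def write_summary_table(records: list[GwasAssociation], path: str | Path) -> None:
    """Write records as a TSV readable back with the default column map."""
    path = Path(path)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(
            ["snp_id", "effect_allele", "other_allele", "beta", "se", "p_value", "eaf", "n"]
        )
        for rec in records:
            writer.writerow(
                [
                    rec.snp_id,
                    rec.effect_allele,
                    rec.other_allele or "",
                    repr(rec.beta),
                    repr(rec.se),
                    repr(rec.p_value),
                    "" if rec.eaf is None else repr(rec.eaf),
                    "" if rec.n is None else repr(rec.n),
                ]
            )


def significance_filter(
    assocs: list[GwasAssociation], threshold: float = 5e-8
) -> list[GwasAssociation]:
    """Keep records with ``p_value < threshold``, preserving input order."""
    if not (0 < threshold <= 1):
        raise ConfigurationError(f"significance threshold {threshold} not in (0, 1]")
    kept = [a for a in assocs if a.p_value < threshold]
    if assocs and not kept:
        logger.warning(
            "significance filter at %g removed all %d records", threshold, len(assocs)
        )
    return kept


class LdMap:
    """Symmetric pairwise r-squared lookup; absent pairs mean r2 = 0."""

    def __init__(self, pairs: dict[tuple[str, str], float] | None = None):
        self._r2: dict[frozenset, float] = {}
        for (a, b), value in (pairs or {}).items():
            self.set(a, b, value)

    def set(self, snp_a: str, snp_b: str, r2: float) -> None:
        if not (0 <= r2 <= 1):
            raise ValueError(f"r2 for ({snp_a}, {snp_b}) is {r2}, outside [0, 1]")
        if snp_a != snp_b:
            self._r2[frozenset((snp_a, snp_b))] = r2

    def get(self, snp_a: str, snp_b: str) -> float:
        if snp_a == snp_b:
            return 1.0
        return self._r2.get(frozenset((snp_a, snp_b)), 0.0)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LdMap":
        frame = pd.read_csv(path)
        ld = cls()
        for row in frame.itertuples(index=False):
            ld.set(str(row.snp_a), str(row.snp_b), float(row.r2))
        return ld


def ld_prune(
    assocs: list[GwasAssociation],
    r2: LdMap | dict[tuple[str, str], float],
    r2_threshold: float = 0.8,
    exclusion_log: list[tuple[str, str]] | None = None,
) -> list[GwasAssociation]:
    """Greedy LD pruning keeping the strongest SNP of each correlated group.

    SNPs are processed in ascending p-value order (ties broken by descending
    |beta|, then snp_id); a SNP is kept iff its r2 with every already-kept
    SNP is below ``r2_threshold``. The returned list is in processing order,
    so the result does not depend on input row order.
    """
    if not (0 < r2_threshold <= 1):
        raise ConfigurationError(f"r2 threshold {r2_threshold} not in (0, 1]")
    if not isinstance(r2, LdMap):
        r2 = LdMap(r2)
    ranked = sorted(assocs, key=lambda a: (a.p_value, -abs(a.beta), a.snp_id))
    kept: list[GwasAssociation] = []
    for cand in ranked:
        clash = next(
            (k for k in kept if r2.get(cand.snp_id, k.snp_id) >= r2_threshold), None
        )
        if clash is None:
            kept.append(cand)
        elif exclusion_log is not None:
            exclusion_log.append(
                (
                    cand.snp_id,
                    f"ld:r2={r2.get(cand.snp_id, clash.snp_id):g} with kept SNP {clash.snp_id}",
                )
            )
    return kept


def harmonize(
    exposure: list[GwasAssociation],
    outcome: list[GwasAssociation],
    report: list[tuple[str, str]] | None = None,
) -> list[HarmonizedInstrument]:
    """Align exposure and outcome associations onto a common effect allele.

    For each exposure SNP found in the outcome table: if the outcome effect
    allele matches the exposure effect allele the betas are copied; if it
    matches the exposure other allele the outcome beta is sign-flipped.
    Palindromic SNPs (A/T, C/G) are harmonized by allele letters alone with
    a warning — no frequency inference is attempted. SNPs absent from the
    outcome table are appended to ``report`` as ``(snp_id,
    "missing_in_outcome")``, never silently dropped.

    Raises
    ------
    HarmonizationError
        If the outcome allele pair is neither a match nor a swap.
    """
    by_id: dict[str, GwasAssociation] = {}
    for rec in outcome:
        by_id.setdefault(rec.snp_id, rec)

    out: list[HarmonizedInstrument] = []
    for exp in exposure:
        oc = by_id.get(exp.snp_id)
        if oc is None:
            if report is not None:
                report.append((exp.snp_id, "missing_in_outcome"))
            logger.warning("%s absent from outcome data", exp.snp_id)
            continue
        beta_out = _orient_outcome_beta(exp, oc)
        if exp.is_palindromic:
            warnings.warn(
                f"{exp.snp_id} is palindromic ({exp.effect_allele}/{exp.other_allele}); "
                "harmonized by allele letters alone",
                stacklevel=2,
            )
        out.append(
            HarmonizedInstrument(
                snp_id=exp.snp_id,
                gamma_hat=exp.beta,
                se_gamma=exp.se,
                big_gamma_hat=beta_out,
                se_big_gamma=oc.se,
                effect_allele=exp.effect_allele,
            )
        )
    return out


def _orient_outcome_beta(exp: GwasAssociation, oc: GwasAssociation) -> float:
    if oc.effect_allele == exp.effect_allele:
        if (
            oc.other_allele is not None
            and exp.other_allele is not None
            and oc.other_allele != exp.other_allele
        ):
            raise HarmonizationError(
                f"{exp.snp_id}: other alleles disagree "
                f"({exp.other_allele} vs {oc.other_allele})"
            )
        return oc.beta
    if exp.other_allele is not None and oc.effect_allele == exp.other_allele:
        if oc.other_allele is not None and oc.other_allele != exp.effect_allele:
            raise HarmonizationError(
                f"{exp.snp_id}: alleles {oc.effect_allele}/{oc.other_allele} are not a "
                f"swap of {exp.effect_allele}/{exp.other_allele}"
            )
        return -oc.beta
    raise HarmonizationError(
        f"{exp.snp_id}: outcome alleles {oc.effect_allele}/{oc.other_allele} match "
        f"neither orientation of {exp.effect_allele}/{exp.other_allele}"
    )


def read_pleiotropy_tags(path: str | Path) -> dict[str, dict]:
    """Read a pleiotropy-tag CSV (snp_id, outcome_id, gene_label, source).

    Returns a map snp_id -> {"outcomes": set of outcome ids, "gene_label": str}.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"snp_id", "outcome_id"}
    if not required.issubset(frame.columns):
        raise ConfigurationError(
            f"tag file {path} must contain columns {sorted(required)}"
        )
    tags: dict[str, dict] = {}
    for row in frame.itertuples(index=False):
        entry = tags.setdefault(row.snp_id, {"outcomes": set(), "gene_label": ""})
        entry["outcomes"].add(row.outcome_id)
        gene = getattr(row, "gene_label", "")
        if gene:
            entry["gene_label"] = gene
    return tags


def apply_pleiotropy_tags(
    instruments: list[HarmonizedInstrument], tags: dict[str, dict]
) -> list[HarmonizedInstrument]:
    """Attach tag annotations to matching instruments (others untouched)."""
    out = []
    for inst in instruments:
        entry = tags.get(inst.snp_id)
        if entry is None:
            out.append(inst)
        else:
            out.append(inst.with_tags(entry["outcomes"], entry["gene_label"] or None))
    return out


def exclude_pleiotropic(instrument_set: InstrumentSet, outcome_id: str) -> InstrumentSet:
    """Remove instruments tagged as directly associated with ``outcome_id``.

    Removals are appended to the exclusion log with reason
    ``pleiotropy:<outcome_id>``; the input set is not mutated.
    """
    kept, removed = [], []
    for inst in instrument_set.instruments:
        if outcome_id in inst.pleiotropy_tags:
            removed.append((inst.snp_id, f"pleiotropy:{outcome_id}"))
        else:
            kept.append(inst)
    if not kept:
        logger.warning(
            "pleiotropy exclusion for %s emptied the %s instrument set",
            outcome_id,
            instrument_set.exposure_id,
        )
    return InstrumentSet(
        exposure_id=instrument_set.exposure_id,
        outcome_id=instrument_set.outcome_id,
        instruments=kept,
        exclusion_log=list(instrument_set.exclusion_log) + removed,
    )


def write_instrument_set(instrument_set: InstrumentSet, path: str | Path) -> None:
    """Serialize an instrument set as TSV (exclusion log goes to JSON alongside)."""
    import json

    path = Path(path)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(
            [
                "snp_id",
                "effect_allele",
                "gamma_hat",
                "se_gamma",
                "big_gamma_hat",
                "se_big_gamma",
                "pleiotropy_tags",
                "gene_label",
            ]
        )
        for inst in instrument_set.instruments:
            writer.writerow(
                [
                    inst.snp_id,
                    inst.effect_allele,
                    repr(inst.gamma_hat),
                    repr(inst.se_gamma),
                    repr(inst.big_gamma_hat),
                    repr(inst.se_big_gamma),
                    ";".join(sorted(inst.pleiotropy_tags)),
                    inst.gene_label,
                ]
            )
    log_path = path.with_suffix(path.suffix + ".exclusions.json")
    log_path.write_text(
        json.dumps(
            {
                "exposure_id": instrument_set.exposure_id,
                "outcome_id": instrument_set.outcome_id,
                "exclusions": [
                    {"snp_id": s, "reason": r} for s, r in instrument_set.exclusion_log
                ],
            },
            indent=2,
        )
        + "\n"
    )
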