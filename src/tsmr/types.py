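"""Core domain records shared across the package.

All records are plain dataclasses validated at construction time so that
invalid summary statistics are rejected at the boundary, not deep inside an
estimator.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

NUCLEOTIDES = frozenset("ACGT")
#: Allele pairs whose strand cannot be resolved from letters alone.
PALINDROMIC_PAIRS = frozenset({frozenset("AT"), frozenset("CG")})


def _check_allele(allele: str | None, name: str, snp_id: str) -> None:
    if allele is None:
        return
    if allele not in NUCLEOTIDES:
        raise ValueError(
            f"{snp_id}: {name} must be a single upper-case nucleotide "
            f"(A/C/G/T), got {allele!r}"
        )


@dataclass(frozen=True)
class GwasAssociation:
    """One SNP's association with one trait from a GWAS summary table."""

    snp_id: str
    effect_allele: str
    beta: float
    se: float
    p_value: float
    trait_id: str
    other_allele: str | None = None
    eaf: float | None = None
    n: float | None = None

    def __post_init__(self) -> None:
        _check_allele(self.effect_allele, "effect_allele", self.snp_id)
        _check_allele(self.other_allele, "other_allele", self.snp_id)
        if self.other_allele is not None and self.other_allele == self.effect_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")
        if not (self.se > 0):
            raise ValueError(f"{self.snp_id}: non-positive SE")
        if not (0 < self.p_value <= 1):
            raise ValueError(f"{self.snp_id}: p-value {self.p_value} not in (0, 1]")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValueError(f"{self.snp_id}: EAF {self.eaf} not in [0, 1]")
        if not math.isfinite(self.beta):
            raise ValueError(f"{self.snp_id}: non-finite beta")

    @property
    def is_palindromic(self) -> bool:
        if self.other_allele is None:
            return False
        return frozenset((self.effect_allele, self.other_allele)) in PALINDROMIC_PAIRS


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Exposure and outcome associations for one SNP on a common effect allele.

    ``gamma_hat``/``se_gamma`` are the SNP-exposure association and its SE;
    ``big_gamma_hat``/``se_big_gamma`` are the SNP-outcome association and
    its SE, sign-aligned to the same ``effect_allele``.
    """

    snp_id: str
    gamma_hat: float
    se_gamma: float
    big_gamma_hat: float
    se_big_gamma: float
    effect_allele: str
    pleiotropy_tags: frozenset[str] = frozenset()
    gene_label: str = ""

    def __post_init__(self) -> None:
        if not (self.se_gamma > 0):
            raise ValueError(f"{self.snp_id}: non-positive exposure SE")
        if not (self.se_big_gamma > 0):
            raise ValueError(f"{self.snp_id}: non-positive outcome SE")

    def with_tags(self, tags, gene_label: str | None = None) -> "HarmonizedInstrument":
        return replace(
            self,
            pleiotropy_tags=frozenset(tags),
            gene_label=self.gene_label if gene_label is None else gene_label,
        )


@dataclass
class InstrumentSet:
    """Harmonized instruments for one exposure-outcome pair plus an audit log.

    ``exclusion_log`` records every SNP removed at any stage as
    ``(snp_id, reason)`` so that nothing is silently dropped.
    """

    exposure_id: str
    outcome_id: str
    instruments: list[HarmonizedInstrument] = field(default_factory=list)
    exclusion_log: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [inst.snp_id for inst in self.instruments]
        if len(ids) != len(set(ids)):
            dupes = sorted({s for s in ids if ids.count(s) > 1})
            raise ValueError(f"duplicate snp_ids in instrument set: {dupes}")

    def __len__(self) -> int:
        return len(self.instruments)

    @property
    def snp_ids(self) -> list[str]:
        return [inst.snp_id for inst in self.instruments]


@dataclass(frozen=True)
class WaldRatio:
    """Single-SNP causal estimate with Fieller confidence limits."""

    snp_id: str
    theta_hat: float
    se_theta: float
    fieller_low: float
    fieller_high: float
    fieller_case: str  # bounded | unbounded | exclusive

    def __post_init__(self) -> None:
        if not (self.se_theta > 0):
            raise ValueError(f"{self.snp_id}: non-positive Wald SE")
        if self.fieller_case == "bounded" and not (
            self.fieller_low <= self.theta_hat <= self.fieller_high
        ):
            raise ValueError(f"{self.snp_id}: bounded Fieller limits exclude estimate")


@dataclass(frozen=True)
class MrEstimate:
    """A pooled causal-effect estimate on the exposure's per-unit scale.

    ``beta`` is per 1.0-unit change in the exposure (1.0 = 100% change in
    concentration when exposure betas are in proportional-change units).
    Odds-ratio fields are populated only for binary outcomes.
    """

    method: str  # IVW | MR-Egger | WeightedMedian
    beta: float
    se: float
    ci_low: float
    ci_high: float
    n_snps: int
    max_weight_share: float
    or_point: float | None = None
    or_low: float | None = None
    or_high: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValueError("confidence limits exclude the point estimate")
        if not (0 < self.max_weight_share <= 1):
            raise ValueError("max_weight_share must be in (0, 1]")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_snps": self.n_snps,
            "max_weight_share": self.max_weight_share,
            "or_point": self.or_point,
            "or_low": self.or_low,
            "or_high": self.or_high,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_se": self.egger_intercept_se,
            "egger_intercept_p": self.egger_intercept_p,
        }
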