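"""Sensitivity battery: pleiotropy-exclusion reruns and the weight-share
rule choosing between the weighted median and MR-Egger.

The secondary estimator is the weighted median when every instrument
carries less than half of the IVW weight, and MR-Egger when a single
instrument carries more than half. Exactly half routes to MR-Egger
(conservative). The MR-Egger intercept and its p-value are reported for
every configuration with at least three instruments, whichever secondary
method is chosen; an intercept p-value below 0.05 flags directional
pleiotropy but never changes the analysis automatically.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import InsufficientInstrumentsError
from .estimators import ivw_fixed, max_weight_share, mr_egger, to_odds_ratio, weighted_median
from .summary_io import apply_pleiotropy_tags, exclude_pleiotropic
from .types import InstrumentSet, MrEstimate

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SensitivityConfig:
    binary_outcome: bool = True
    n_boot: int = 1000
    seed: int = 0
    egger_residual_variance: str = "none"


@dataclass
class SensitivityReport:
    """One exposure-outcome analysis block: primary IVW and chosen secondary,
    each with and without pleiotropy-tagged SNPs."""

    exposure_id: str
    outcome_id: str
    primary: MrEstimate
    primary_excl: MrEstimate | None
    secondary: MrEstimate | None
    secondary_excl: MrEstimate | None
    secondary_method_reason: str
    secondary_excl_method_reason: str = ""
    egger_all: MrEstimate | None = None
    egger_excl: MrEstimate | None = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def conv(est):
            return None if est is None else est.to_dict()

        return {
            "exposure_id": self.exposure_id,
            "outcome_id": self.outcome_id,
            "primary": conv(self.primary),
            "primary_excl": conv(self.primary_excl),
            "secondary": conv(self.secondary),
            "secondary_excl": conv(self.secondary_excl),
            "secondary_method_reason": self.secondary_method_reason,
            "secondary_excl_method_reason": self.secondary_excl_method_reason,
            "egger_all": conv(self.egger_all),
            "egger_excl": conv(self.egger_excl),
            "notes": self.notes,
        }


def choose_secondary(instrument_set: InstrumentSet) -> tuple[str, str]:
    """Pick the secondary estimator from IVW weight shares.

    Returns ``(method, reason)`` where method is ``"WeightedMedian"`` when
    the maximum single-SNP weight share is below 0.5 and ``"MR-Egger"``
    otherwise (including exactly 0.5, the conservative choice).

    Raises
    ------
    InsufficientInstrumentsError
        With fewer than three instruments neither secondary method is
        available.
    """
    if len(instrument_set) < 3:
        raise InsufficientInstrumentsError(
            f"{len(instrument_set)} instrument(s): no secondary method available, "
            "report IVW only"
        )
    share = max_weight_share(instrument_set.instruments)
    if share < 0.5:
        return "WeightedMedian", f"max weight share {share:.2f} < 0.5 → WeightedMedian"
    if share == 0.5:
        return "MR-Egger", "max weight share exactly 0.50 → MR-Egger (conservative)"
    return "MR-Egger", f"max weight share {share:.2f} > 0.5 → MR-Egger"


def _estimate_block(
    instrument_set: InstrumentSet, config: SensitivityConfig
) -> tuple[MrEstimate, MrEstimate | None, str, MrEstimate | None]:
    """(ivw, secondary, reason, egger-for-intercept) for one instrument set."""
    ivw = ivw_fixed(instrument_set.instruments)
    egger = None
    if len(instrument_set) >= 3:
        egger = mr_egger(
            instrument_set.instruments,
            residual_variance=config.egger_residual_variance,
        )
    try:
        method, reason = choose_secondary(instrument_set)
    except InsufficientInstrumentsError as exc:
        secondary, reason = None, str(exc)
    else:
        if method == "WeightedMedian":
            secondary = weighted_median(
                instrument_set.instruments, n_boot=config.n_boot, seed=config.seed
            )
        else:
            secondary = egger
    if config.binary_outcome:
        ivw = to_odds_ratio(ivw)
        secondary = to_odds_ratio(secondary) if secondary is not None else None
        egger = to_odds_ratio(egger) if egger is not None else None
    return ivw, secondary, reason, egger


def run_sensitivity(
    instrument_set: InstrumentSet,
    tags: dict[str, dict] | None = None,
    config: SensitivityConfig | None = None,
) -> SensitivityReport:
    """Run IVW plus the chosen secondary on the full instrument set and on
    the set with pleiotropy-tagged SNPs excluded.

    ``tags`` (as returned by :func:`tsmr.summary_io.read_pleiotropy_tags`)
    is applied to the instruments first when given; otherwise instruments
    must already carry their tags. Tagging for the set's own ``outcome_id``
    triggers exclusion in the second pass.
    """
    config = config or SensitivityConfig()
    if tags is not None:
        instrument_set = InstrumentSet(
            exposure_id=instrument_set.exposure_id,
            outcome_id=instrument_set.outcome_id,
            instruments=apply_pleiotropy_tags(instrument_set.instruments, tags),
            exclusion_log=list(instrument_set.exclusion_log),
        )
    if len(instrument_set) == 0:
        raise InsufficientInstrumentsError(
            f"empty instrument set for {instrument_set.exposure_id} → "
            f"{instrument_set.outcome_id}"
        )
    primary, secondary, reason, egger_all = _estimate_block(instrument_set, config)

    excl_set = exclude_pleiotropic(instrument_set, instrument_set.outcome_id)
    notes: list[str] = []
    if len(excl_set) == 0:
        notes.append(
            "pleiotropy exclusion removed every instrument; excluded-set "
            "estimates unavailable"
        )
        primary_excl = secondary_excl = egger_excl = None
        reason_excl = ""
    elif len(excl_set) == len(instrument_set):
        primary_excl, secondary_excl = primary, secondary
        reason_excl, egger_excl = reason, egger_all
    else:
        primary_excl, secondary_excl, reason_excl, egger_excl = _estimate_block(
            excl_set, config
        )

    return SensitivityReport(
        exposure_id=instrument_set.exposure_id,
        outcome_id=instrument_set.outcome_id,
        primary=primary,
        primary_excl=primary_excl,
        secondary=secondary,
        secondary_excl=secondary_excl,
        secondary_method_reason=reason,
        secondary_excl_method_reason=reason_excl,
        egger_all=egger_all,
        egger_excl=egger_excl,
        notes=notes,
    )
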