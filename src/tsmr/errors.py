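"""Exception hierarchy for tsmr."""


class TsmrError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TsmrError):
    """Invalid configuration: missing columns, bad thresholds, bad paths."""


class RowValidationError(TsmrError):
    """One or more input rows failed validation.

    Carries ``offenders``: a list of ``(row_number, reason)`` pairs using
    1-based data-row numbers (header excluded).
    """

    def __init__(self, offenders):
        self.offenders = list(offenders)
        lines = ", ".join(f"row {i}: {r}" for i, r in self.offenders)
        super().__init__(f"{len(self.offenders)} invalid row(s): {lines}")


class HarmonizationError(TsmrError):
    """Allele pair on the outcome side is neither a match nor a swap."""


class WeakInstrumentError(TsmrError):
    """SNP-exposure association is exactly zero; Wald ratio undefined."""


class InsufficientInstrumentsError(TsmrError):
    """Too few instruments for the requested estimator."""


class WeightShareError(TsmrError):
    """A single instrument dominates the IVW weight (share > 50%)."""

    def __init__(self, snp_id, share):
        self.snp_id = snp_id
        self.share = share
        super().__init__(
            f"instrument {snp_id} carries {share:.1%} of the IVW weight "
            f"(> 50%); use MR-Egger for this set"
        )
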