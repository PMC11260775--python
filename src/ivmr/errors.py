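"""Exception hierarchy shared across the package."""


class IVMRError(Exception):
    """Base class for all package errors."""


class ConfigurationError(IVMRError):
    """A run configuration or file layout problem (missing column, unknown
    category label, invalid threshold)."""


class RowValidationError(IVMRError):
    """One or more summary-statistic rows violate record invariants.

    Attributes
    ----------
    rsids : list of str
        Identifiers of the offending rows.
    reasons : list of str
        One human-readable reason per offending row.
    """

    def __init__(self, rsids, reasons):
        self.rsids = list(rsids)
        self.reasons = list(reasons)
        detail = "; ".join(f"{r}: {why}" for r, why in zip(self.rsids, self.reasons))
        super().__init__(f"{len(self.rsids)} invalid row(s): {detail}")


class UndefinedLDError(IVMRError):
    """LD is undefined (monomorphic SNP or SNP absent from the panel)."""


class EmptyInstrumentError(IVMRError):
    """An estimator was invoked on an empty instrument set."""


class MRMethodUnavailable(IVMRError):
    """A method's minimum-SNP precondition is not met; reported per method,
    never fatal to the pipeline."""
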