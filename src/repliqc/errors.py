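"""Exception hierarchy shared across the package."""


class RepliqcError(Exception):
    """Base class for all repliqc errors."""


class InvalidRecordError(RepliqcError, ValueError):
    """A VCF record (or record fragment) violates a format contract."""


class ContractError(RepliqcError, ValueError):
    """An operation was called outside its stated precondition."""


class DegenerateInputError(RepliqcError, ValueError):
    """Input too small or variance-free for a density-based operation."""


class ConstraintInfeasibleError(RepliqcError):
    """No candidate threshold satisfies the discordant-removal constraint.

    Carries ``max_achievable``, the largest discordant-removed fraction any
    candidate reaches, so callers can relax ``d_min`` knowingly.
    """

    def __init__(self, message: str, max_achievable: float):
        super().__init__(message)
        self.max_achievable = max_achievable


class NotBimodalError(RepliqcError):
    """A valley threshold was requested but the density has < 2 modes."""


class NoInformativePairsError(RepliqcError):
    """Concordance was requested on a set with zero evaluated replicate pairs."""


class AmbiguousClinVarError(RepliqcError):
    """Duplicate CPRA identifiers in a ClinVar table; carries the offenders."""

    def __init__(self, offenders):
        self.offenders = list(offenders)
        super().__init__(
            "duplicate CPRA identifiers in ClinVar table: "
            + ", ".join(self.offenders[:10])
        )


class UnsupportedSubtypeError(RepliqcError):
    """Triallelic subtype outside the supported taxonomy (e.g. two symbolic alts)."""
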