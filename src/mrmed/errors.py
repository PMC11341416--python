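"""Exception hierarchy for mrmed.

Every error raised on purpose by the package derives from :class:`MrmedError`
so callers (and the CLI) can distinguish analysis failures from bugs.
"""


class MrmedError(Exception):
    """Base class for all mrmed errors."""


class FormatError(MrmedError):
    """A summary-statistic file violates the expected table layout."""


class EmptyInputError(MrmedError):
    """No valid rows survived validation."""


class ConfigError(MrmedError):
    """A simulation or selection configuration is infeasible."""


class InsufficientInstrumentsError(MrmedError):
    """Too few instruments remain for the requested estimator.

    Parameters
    ----------
    n_available
        Instruments actually available.
    n_required
        Minimum the operation needs.
    context
        Optional label (e.g. which mediation leg failed).
    """

    def __init__(self, n_available: int, n_required: int, context: str = ""):
        self.n_available = n_available
        self.n_required = n_required
        self.context = context
        where = f" in {context}" if context else ""
        super().__init__(
            f"{n_available} instrument(s) available{where}, "
            f"but at least {n_required} required"
        )


class MediationLegError(MrmedError):
    """One leg of the two-step mediation pipeline could not be fitted."""

    def __init__(self, leg: str, cause: Exception):
        self.leg = leg
        self.cause = cause
        super().__init__(f"mediation leg '{leg}' failed: {cause}")
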