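"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: :class:`SchemaError` -> 2,
:class:`SimulationError` -> 3, :class:`StatisticsError` -> 4.
"""


class CipasimError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CipasimError):
    """Invalid configuration: unknown model id, bad protocol, bad run config."""


class SchemaError(CipasimError):
    """Malformed input table: unknown/missing column, bad value, duplicate key."""


class SimulationError(CipasimError):
    """Numerical failure while integrating the cell model.

    Carries the drug/concentration context so a failing sample inside a
    large uncertainty-quantification run can be reported precisely.
    """

    def __init__(self, message, drug=None, concentration_nM=None):
        ctx = []
        if drug is not None:
            ctx.append(f"drug={drug!r}")
        if concentration_nM is not None:
            ctx.append(f"concentration={concentration_nM:g} nM")
        if ctx:
            message = f"{message} [{', '.join(ctx)}]"
        super().__init__(message)
        self.drug = drug
        self.concentration_nM = concentration_nM


class StatisticsError(CipasimError):
    """Failure in a statistical procedure (fit non-convergence, undefined measure)."""


class FitError(StatisticsError):
    """A least-squares or maximum-likelihood fit failed or is underdetermined."""


class UndefinedMeasureError(StatisticsError):
    """A performance measure is undefined for the given panel (e.g. one class only)."""
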