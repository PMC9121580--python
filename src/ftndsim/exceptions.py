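"""Exception and warning types used across the package."""


class FtndsimError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(FtndsimError):
    """An invalid generator, missingness or grid configuration."""


class InvalidDataError(FtndsimError):
    """A dataset violates the FTND schema or an operation's preconditions."""


class CalibrationError(FtndsimError):
    """The generator could not be calibrated to the requested targets."""


class SolverError(FtndsimError):
    """A root-finding step (e.g. the eligibility intercept) failed to converge."""


class UnimputableDatasetError(FtndsimError):
    """Item-mean imputation needs a column mean that no observed value provides."""


class DonorPoolError(FtndsimError):
    """Hot-deck imputation could not assemble a donor pool."""


class UndefinedEstimateError(FtndsimError):
    """Too few usable totals to form an estimate in one replication.

    The simulation driver records these replications instead of aborting.
    """


class DonorPoolWarning(UserWarning):
    """Fewer than k candidate donors were available; all candidates were used."""
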