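"""Exception hierarchy for fssim.

Every error raised deliberately by the package derives from :class:`FsSimError`
so that callers (and the CLI) can distinguish simulation errors from bugs.
"""


class FsSimError(Exception):
    """Base class for all fssim errors."""


class InvalidParameterError(FsSimError, ValueError):
    """A physical parameter is outside its admissible range."""


class OutOfDomainError(FsSimError, ValueError):
    """A position (or a sphere around it) lies outside the cavity."""


class IntegrationInstabilityError(FsSimError, RuntimeError):
    """The requested time step cannot be stabilised by sub-stepping."""


class InsufficientDataError(FsSimError, ValueError):
    """A statistic was requested on too few samples."""


class ConfigError(FsSimError):
    """Configuration file could not be loaded."""


class UnknownKeyError(ConfigError):
    """Configuration contains a key the schema does not define."""


class UnitError(ConfigError):
    """A physical quantity is missing a unit suffix or uses an unknown one."""
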