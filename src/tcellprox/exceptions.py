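"""Exception hierarchy shared across the package."""


class TCellProxError(Exception):
    """Base class for all package-specific errors."""


class FormatError(TCellProxError, ValueError):
    """An input file does not conform to the declared dialect."""


class ValidationError(TCellProxError, ValueError):
    """Input values violate a documented contract (bad labels, non-finite numbers...)."""


class EmptyInputError(TCellProxError, ValueError):
    """A file or table that must contain data is empty."""


class GeometryError(TCellProxError, ValueError):
    """An observation window cannot be built or does not contain the cells."""


class ParameterError(TCellProxError, ValueError):
    """A numeric parameter is outside its legal range."""


class EmptyCohortError(TCellProxError, ValueError):
    """Quality filtering removed every patient from the cohort."""


class ConsistencyError(TCellProxError, RuntimeError):
    """Internal pipeline invariant violated (e.g. missing component after QC)."""


class FitError(TCellProxError, RuntimeError):
    """A survival model failed to converge or could not be specified."""


class ConfigError(TCellProxError, ValueError):
    """A configuration value is unknown or inconsistent."""
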