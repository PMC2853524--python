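"""Exception hierarchy shared across the package.

Exit codes used by the CLI: 2 configuration, 3 data, 4 solver.
"""


class SwitchFBAError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(SwitchFBAError):
    """Invalid configuration: bad parameter values, missing reaction ids, ..."""

    exit_code = 2


class DataError(SwitchFBAError):
    """Invalid input data: malformed files, duplicate ids, negative rates, ..."""

    exit_code = 3


class SBMLParseError(DataError):
    """SBML document failed to parse; message names the offending line."""


class ValidationError(DataError):
    """A model or matrix violates a structural invariant."""


class SolverError(SwitchFBAError):
    """LP solve failed in a way that is not plain infeasibility reporting."""

    exit_code = 4
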