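"""Exception hierarchy.

The CLI maps these onto exit codes: input problems (unreadable or malformed
files, empty networks, bad tables) exit 2, parameter problems (infeasible FDR,
malformed grids) exit 3, solver problems exit 4.
"""


class ActivemodError(Exception):
    """Base class for all package errors."""


class FormatError(ActivemodError):
    """A file could not be parsed in the expected format."""


class EmptyNetworkError(ActivemodError):
    """No interactions survived reading/filtering."""


class ValidationError(ActivemodError):
    """Input data violates a documented precondition."""


class ParameterError(ActivemodError):
    """A tuning parameter is outside its feasible range."""


class NoSignalError(ActivemodError):
    """The p-value distribution shows no enrichment near zero."""


class SolverError(ActivemodError):
    """The optimisation backend failed or the instance exceeds its size bound."""
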