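"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ValidationError/FormatError -> 1,
InfeasibleModelError -> 2, anything else -> 3.
"""


class CometabError(Exception):
    """Base class for all package errors."""


class ValidationError(CometabError):
    """An input violates a structural invariant (bad bounds, dangling ids...)."""


class FormatError(CometabError):
    """A file could not be parsed in the declared format."""


class InfeasibleModelError(CometabError):
    """An LP required to be feasible is infeasible under the current constraints."""


class UnboundedModelError(CometabError):
    """An optimisation is unbounded where a finite optimum was required."""
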