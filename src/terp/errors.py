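"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: configuration problems -> 2,
black-box adapter contract violations -> 3, degenerate inputs
(constant predictions, one-class neighborhoods) -> 4.
"""


class TerpError(Exception):
    """Base class for all package-specific errors."""

    exit_code = 1


class ConfigError(TerpError):
    """Invalid or inconsistent run configuration."""

    exit_code = 2


class AdapterContractError(TerpError):
    """A black-box adapter broke its contract (bad shape, values outside [0, 1])."""

    exit_code = 3


class DegenerateInputError(TerpError):
    """Input admits no meaningful explanation (constant g, one-class neighborhood)."""

    exit_code = 4


class DegenerateNeighborhoodError(DegenerateInputError):
    """All neighborhood samples fall in a single predicted class.

    The supervised 1-d projection needs both in-class and not-in-class
    samples.  Remedies: enlarge the neighborhood, raise ``mask_prob``,
    or use the standardized-Euclidean similarity fallback.
    """


class SelectionError(TerpError):
    """Model selection could not identify an optimal explanation."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace
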