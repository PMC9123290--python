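"""Exception hierarchy.

Three failure families map onto distinct CLI exit codes: configuration
problems (bad probability tables, unknown columns), validation problems
(out-of-range or missing data handed to an operation), and estimation
problems (degenerate likelihoods, non-convergence, separation).
"""


class GenderPathsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GenderPathsError):
    """Invalid generator or pipeline configuration."""


class ValidationError(GenderPathsError):
    """Input data violate an operation's preconditions."""


class EstimationError(GenderPathsError):
    """A model fit is impossible or degenerate for the given data."""
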