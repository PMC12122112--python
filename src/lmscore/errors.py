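"""Exception hierarchy.

Validation errors (bad input data) are kept distinct from runtime errors
(e.g. an infeasible reconstruction) so the CLI can map them to exit codes
1 and 2 respectively.
"""


class LmscoreError(Exception):
    """Base class for all package errors."""


class ValidationError(LmscoreError, ValueError):
    """Invalid input: out-of-range point, missing item, malformed file."""


class InfeasibleError(LmscoreError, RuntimeError):
    """No assignment satisfying marginals and score bands was found."""
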