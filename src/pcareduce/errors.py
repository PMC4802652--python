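"""Exception hierarchy.

Separate classes exist so the CLI can map them to distinct exit codes:
usage/parameter problems, malformed data, and numerical degeneracy are
different failure modes for a pipeline user.
"""


class PcaReduceError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(PcaReduceError, ValueError):
    """A parameter is outside its legal range (e.g. q > min(n-1, d))."""


class InvalidInputError(PcaReduceError, ValueError):
    """Input data violates a contract (non-finite values, shape mismatch,
    duplicate identifiers, unparsable file)."""


class CannotReduceError(PcaReduceError):
    """Requested a dimension drop on a one-dimensional score matrix."""


class NumericalDegeneracyError(PcaReduceError):
    """A pooled covariance failed to be positive definite even after
    ridge regularisation; the message names the offending cluster pair."""


class StaleCandidateError(PcaReduceError):
    """A merge candidate refers to a cluster configuration that no longer
    exists (the state has been merged since the candidate was scored)."""
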