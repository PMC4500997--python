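"""Exception hierarchy for riccinet.

Every error raised by the library derives from :class:`RiccinetError`, so
callers (and the CLI) can distinguish input/validation problems from
numerical failures with a single ``except`` clause.
"""


class RiccinetError(Exception):
    """Base class for all riccinet errors."""


class ValidationError(RiccinetError):
    """Input data violates a structural invariant (weights, symmetry, ...)."""


class UnknownNodeError(RiccinetError, KeyError):
    """A node identifier is not present in the network."""

    def __str__(self) -> str:  # KeyError quotes its args; keep the message readable
        return Exception.__str__(self)


class IsolatedNodeError(RiccinetError):
    """A random-walk measure was requested at a node with zero strength."""


class DisconnectedPairError(RiccinetError):
    """Curvature is undefined for a pair with infinite hop distance."""


class DisconnectedSupportError(RiccinetError):
    """Transport was requested between supports at infinite ground distance."""


class MassBalanceError(RiccinetError):
    """The two measures handed to the transport solver differ in total mass."""


class SupportSizeError(RiccinetError):
    """Brute-force transport enumeration refused: combined support too large."""


class ParameterError(RiccinetError, ValueError):
    """A numeric parameter is outside its admissible range."""


class SampleSizeError(RiccinetError):
    """Too few samples in a phenotype for a variance-stabilized correlation."""


class AlignmentError(RiccinetError):
    """Two tables that must share keys do not."""


class ConnectivityError(RiccinetError):
    """An operation requiring a connected graph received a disconnected one."""


class PipelineError(RiccinetError):
    """A pipeline stage failed; the message is prefixed with the stage name."""
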