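"""Exception hierarchy for fedgnn.

All package-specific failures derive from :class:`FedGNNError` so callers can
catch one base class at pipeline boundaries (CLI, federation driver).
"""


class FedGNNError(Exception):
    """Base class for all fedgnn errors."""


class InputError(FedGNNError):
    """A user-supplied file or table is unreadable or malformed."""


class EmptyNetworkError(InputError):
    """A PPI edge list contained no usable (non-self-loop) edges."""


class IncompatibleInputsError(InputError):
    """Expression table and PPI network share fewer than two genes."""


class ParameterError(FedGNNError, ValueError):
    """A configuration value is out of its valid range."""


class DegenerateDataError(FedGNNError):
    """A training set cannot support fitting (e.g. a single class)."""


class TopologyMismatchError(FedGNNError):
    """A graph's node set does not match the model that scores it."""


class WeightShapeError(FedGNNError):
    """A weight vector's length does not match the ensemble it targets."""


class ProtocolError(FedGNNError):
    """The federated protocol was violated (missing payload, bad round)."""


class IllegalTransitionError(ProtocolError):
    """A (state, role, event) triple has no defined transition."""


class DeadlockError(ProtocolError):
    """Scripted actions left an active client without a next action.

    Carries the simulation transcript for post-mortem inspection.
    """

    def __init__(self, message: str, transcript=None):
        super().__init__(message)
        self.transcript = transcript if transcript is not None else []
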