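"""Exception hierarchy for the mindmodes package."""


class MindmodesError(Exception):
    """Base class for all package-specific errors."""


class NormalizationError(MindmodesError):
    """A zero vector cannot be normalized, or a state required to be
    normalized is not."""


class BasisMismatchError(MindmodesError):
    """Two objects that must share a basis do not."""


class UnknownLabelError(MindmodesError, KeyError):
    """A label is not present in the basis."""


class EmptySubspaceError(MindmodesError):
    """A projector or context was requested over an empty label set."""


class AnnihilationError(MindmodesError):
    """An operator mapped the state to the zero vector: the state has no
    support in the operator's range."""


class HermitianityError(MindmodesError):
    """An operator required to be Hermitian (or a projector) is not."""


class NumericalError(MindmodesError):
    """A numerically impossible quantity appeared (e.g. negative variance
    beyond round-off), signalling a broken operator."""


class FixtureError(MindmodesError):
    """A packaged fixture file is malformed or internally inconsistent."""
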