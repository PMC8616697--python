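"""Exception and warning hierarchy."""


class FlicmsegError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(FlicmsegError, ValueError):
    """A parameter object (phantom/noise/config) violates its invariants."""


class DegenerateInputError(FlicmsegError, ValueError):
    """Input is structurally unusable (e.g. fewer distinct intensities than clusters)."""


class ContractError(FlicmsegError, ValueError):
    """Arguments are mutually inconsistent (shape/class-count mismatch)."""


class EmptyRegionError(FlicmsegError, ValueError):
    """A requested label class has no pixels."""


class SkullStripError(FlicmsegError, RuntimeError):
    """Skull stripping could not find a closed outer head boundary.

    Carries the diagnostic edge map that was produced.
    """

    def __init__(self, message, edge_map=None):
        super().__init__(message)
        self.edge_map = edge_map


class EmptyClusterWarning(UserWarning):
    """A cluster received (numerically) zero total membership weight."""


class ConvergenceWarning(UserWarning):
    """Iteration hit max_iter without meeting the center-shift tolerance."""
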