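"""Exception types shared across the package."""


class VoxevoError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(VoxevoError, ValueError):
    """A configuration object violates one of its invariants."""


class InvalidDesignError(VoxevoError, ValueError):
    """A voxel design violates a structural invariant (e.g. no tissue)."""


class MutationFailureError(VoxevoError, RuntimeError):
    """Mutation retry budget exhausted without a phenotypic change."""


class SimulationUnstableError(VoxevoError, RuntimeError):
    """A simulated coordinate became non-finite (numerical divergence)."""


class ContractViolationError(VoxevoError, ValueError):
    """An operation was called with arguments outside its contract."""


class DesignParseError(VoxevoError, ValueError):
    """A design or genome file is malformed; the message names the line."""
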