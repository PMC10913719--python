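"""Exception types shared across the workbench."""


class WorkbenchError(Exception):
    """Base class for workbench errors."""


class ParameterError(WorkbenchError, ValueError):
    """An argument violates a documented precondition."""


class EmptyLibraryError(WorkbenchError):
    """A simulated library would contain no reads (no active template)."""


class PoolExhaustionError(WorkbenchError):
    """A read pool is too small to sample the requested count without replacement."""

    def __init__(self, pool_name: str, requested: int, available: int):
        self.pool_name = pool_name
        self.requested = requested
        self.available = available
        super().__init__(
            f"pool '{pool_name}' holds {available} reads; {requested} requested "
            "for sampling without replacement"
        )


class MarkerUniquenessError(WorkbenchError):
    """A species genome lacks enough unique windows for the marker database."""
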