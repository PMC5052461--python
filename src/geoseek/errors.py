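"""Typed exceptions shared across the pipeline stages."""


class GeoseekError(Exception):
    """Base class for all package-specific failures."""


class ConfigError(GeoseekError, ValueError):
    """A configuration object violates one of its invariants."""


class InsufficientHistoryError(GeoseekError):
    """A user does not have enough qualifying search days for a window."""

    def __init__(self, user_id: str, n_days: int, required: int):
        self.user_id = user_id
        self.n_days = n_days
        self.required = required
        super().__init__(
            f"user {user_id!r} has {n_days} qualifying search days "
            f"before the endpoint; {required} are required"
        )


class ControlPoolError(GeoseekError):
    """The candidate control pool is smaller than the number requested."""

    def __init__(self, available: int, requested: int):
        self.available = available
        self.requested = requested
        super().__init__(
            f"control pool has {available} users but {requested} were requested "
            f"(shortfall {requested - available})"
        )


class StageError(GeoseekError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
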