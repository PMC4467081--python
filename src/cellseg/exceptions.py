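"""Exception types shared across the package."""


class CellsegError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CellsegError, ValueError):
    """An on-disk input does not have the expected layout (e.g. multi-channel)."""


class ParameterError(CellsegError, ValueError):
    """A parameter violates its documented domain."""


class GeometryError(CellsegError, ValueError):
    """A polygon operation received degenerate or self-intersecting geometry."""


class DegenerateContourError(CellsegError, RuntimeError):
    """A snake collapsed below the minimum vertex count or enclosed area."""

    def __init__(self, message: str, cell_id: int | None = None):
        super().__init__(message)
        self.cell_id = cell_id


class CapacityError(CellsegError, RuntimeError):
    """An output format cannot represent the result (e.g. >65535 labels)."""


class GenerationError(CellsegError, RuntimeError):
    """The synthetic scene generator could not satisfy its placement constraints."""


class StageError(CellsegError, RuntimeError):
    """A pipeline stage failed; carries the stage name and offending cell id."""

    def __init__(self, stage: str, cell_id: int | None, cause: Exception):
        super().__init__(f"stage '{stage}' failed"
                         + (f" for cell {cell_id}" if cell_id is not None else "")
                         + f": {cause}")
        self.stage = stage
        self.cell_id = cell_id
        self.cause = cause
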