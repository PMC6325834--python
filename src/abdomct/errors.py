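"""Exception types shared across the pipeline.

All inherit :class:`ValueError` so callers that only care about "bad input"
can catch one base class.
"""


class FormatError(ValueError):
    """A medical-imaging file or series violates the expected format."""


class GeometryError(ValueError):
    """Voxel grids / VOIs with incompatible shapes or metadata."""


class BoundaryError(ValueError):
    """Slice indices outside, or inconsistent with, the volume extent."""


class DegenerateInputError(ValueError):
    """Statistically or geometrically degenerate input (constant data,
    empty all-tissue volume, zero pairwise mean...)."""


class SimulationError(RuntimeError):
    """The synthetic-cohort generator could not satisfy its constraints."""
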