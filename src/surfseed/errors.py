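"""Exception hierarchy for surfseed.

All domain errors derive from :class:`SurfSeedError` so callers (and the CLI)
can catch one base class and map it to a nonzero exit status.
"""


class SurfSeedError(Exception):
    """Base class for all surfseed domain errors."""


class MeshFormatError(SurfSeedError):
    """A mesh file could not be read or written in the requested format."""


class InvalidInputError(SurfSeedError):
    """An input violates a documented precondition (empty mesh, empty sample set...)."""


class InvalidSeedError(SurfSeedError):
    """Seed points are inconsistent (e.g. two labels snapping to one vertex)."""


class InvalidSpecError(SurfSeedError):
    """A synthetic fixture specification is geometrically unrealisable."""


class UnsegmentableVertexError(SurfSeedError):
    """An operation touched a vertex with no incident faces (zero normal)."""
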