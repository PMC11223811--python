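"""Exception hierarchy.

Every stage of the design pipeline raises a subclass of :class:`WireweaverError`
so callers (and the CLI) can report which stage failed without string matching.
"""


class WireweaverError(Exception):
    """Base class for all errors raised by wireweaver."""


class FormatError(WireweaverError):
    """Malformed input file (OBJ, route list, oxDNA, NUPACK, ...)."""


class GeometryError(WireweaverError):
    """Degenerate geometry: zero-length edges, singular transforms, ..."""


class RoutingError(WireweaverError):
    """A routing method's preconditions are violated (disconnected graph,
    non-manifold mesh for A-trails, ...)."""


class RouteImportError(WireweaverError):
    """An imported edge sequence is not a valid closed covering walk."""


class SizeError(WireweaverError):
    """Exact-mode search budget exceeded; the heuristic mode is advised."""


class ParameterError(WireweaverError):
    """Design parameters incompatible with the input (scale too small, ...)."""


class RelaxationError(WireweaverError):
    """Rigid-body relaxation diverged (non-finite state)."""


class ConstraintError(WireweaverError):
    """Sequence constraints are unsatisfiable."""


class SequenceError(WireweaverError):
    """Sequence-level problem: wrong alphabet, scaffold too short,
    unassigned bases at export time."""


class CapacityError(WireweaverError):
    """More kissing loops than table entries."""


class BoxError(WireweaverError):
    """A nucleotide lies outside the requested simulation box."""


class StageError(WireweaverError):
    """Wraps an error with the pipeline stage it occurred in."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause
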