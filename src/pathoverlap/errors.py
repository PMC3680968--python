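"""Exception hierarchy for pathoverlap."""


class PathOverlapError(Exception):
    """Base class for all pathoverlap errors."""


class SBMLFormatError(PathOverlapError):
    """The document is not well-formed XML or violates the SBML subset we read."""


class ConsistencyError(PathOverlapError):
    """A document is internally inconsistent (e.g. a reaction references an
    undeclared species id, or an id is declared twice)."""


class DegenerateGraphError(PathOverlapError):
    """An operation is undefined on this input (e.g. an overlap score on a
    graph with zero retained reactions)."""


class ParameterError(PathOverlapError):
    """Invalid user parameters (limits, equivalence lists, fixture settings)."""
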