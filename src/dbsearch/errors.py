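"""Exception hierarchy shared across the package."""


class DBSearchError(Exception):
    """Base class for all package-specific errors."""


class NetworkDefinitionError(DBSearchError):
    """A network or node is structurally invalid (bad CPT, cycle, dangling parent)."""


class EvidenceError(DBSearchError):
    """Evidence refers to an unknown node or state, or is otherwise malformed."""


class IncompleteAssignmentError(EvidenceError):
    """A full joint assignment was required but some nodes are unassigned."""


class ImpossibleEvidenceError(DBSearchError):
    """The declared evidence has probability zero under the model.

    Carries the conflicting assignments so callers can report which
    instantiations are jointly incompatible instead of silently
    renormalizing a zero vector.
    """

    def __init__(self, assignments):
        self.assignments = dict(assignments)
        detail = ", ".join(f"{k}={v}" for k, v in self.assignments.items())
        super().__init__(f"evidence has probability zero: {{{detail}}}")


class ScenarioError(DBSearchError):
    """Scenario parameters violate their constraints (n > N, bad priors, ...)."""


class WrongBuilderError(DBSearchError):
    """A specialised network builder was called outside its domain."""


class IdempotencyError(DBSearchError):
    """An add-once network transformation was applied twice."""


class SizeCapError(DBSearchError):
    """The exact-enumeration oracle was asked for a table beyond its cap."""


class ConsistencyError(DBSearchError):
    """Formula and network computation paths disagree beyond tolerance."""
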