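"""Exception hierarchy shared across the package.

Validation failures (bad configs, malformed inputs) and computation
failures (degenerate evidence, unreachable poses) are kept distinct so the
command-line layer can map them to stable exit codes (2 and 3).
"""


class BigRehabError(Exception):
    """Base class for all package errors."""


class ValidationError(BigRehabError, ValueError):
    """Invalid configuration, specification, or input data."""


class StructureError(ValidationError):
    """Graph structure problem (cycle, CPT/edge mismatch)."""


class ParseError(ValidationError):
    """Malformed file; carries a locator when one is known."""


class ComputationError(BigRehabError, RuntimeError):
    """A well-formed problem with no admissible answer."""


class DegenerateEvidenceError(ComputationError):
    """Evidence assigns zero probability mass to every joint configuration."""


class UnreachablePoseError(ComputationError):
    """No real stroke solves the kinematic loop at the requested pose."""


class StrokeLimitError(ComputationError):
    """Both kinematic-loop roots fall outside the actuator stroke limits."""


class SingularityError(ComputationError):
    """Force-transmission degeneracy: a rod is orthogonal to its drive axis."""
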