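"""Exception hierarchy for the anchored MAIC pipeline."""


class MAICError(Exception):
    """Base class for all package errors."""


class SchemaError(MAICError):
    """A file or configuration does not match the documented schema."""


class SimulationError(MAICError):
    """Trial simulation cannot satisfy its constraints (e.g. truncation)."""


class InfeasibleTargetError(MAICError):
    """Aggregate targets lie outside what the IPD can be reweighted to."""
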