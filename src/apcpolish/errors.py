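"""Exception hierarchy.

All validation failures raise subclasses of :class:`ApcError`, which is a
``ValueError`` so callers can catch either.
"""


class ApcError(ValueError):
    """Base class for all apcpolish validation and estimation errors."""


class TableError(ApcError):
    """Invalid or inconsistent age-period table input."""


class EstimationError(ApcError):
    """Regression or weighting input makes an estimate undefined."""


class SimulationError(ApcError):
    """Synthetic-data specification or generation failure."""
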