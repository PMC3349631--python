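"""Exception hierarchy for cutcalib.

All data-quality problems raise :class:`ValidationError` (a ``ValueError``)
so callers and the CLI can distinguish bad input (exit code 2) from bugs.
"""


class ValidationError(ValueError):
    """Input data violates a structural invariant."""


class AlignmentError(ValidationError):
    """Epoch and observation streams cannot be joined (clock fault)."""


class DegenerateDataError(ValidationError):
    """A computation requires both classes but only one is present."""


class OrderingError(ValidationError):
    """Derived cut-points are not strictly ordered sedentary < moderate < vigorous."""
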