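"""Exception hierarchy for the ecoplate pipeline.

Exit-code mapping used by the CLI: ValidationError -> 2,
DegenerateDataError -> 3, anything else -> 1.
"""


class EcoplateError(Exception):
    """Base class for all ecoplate errors."""


class ValidationError(EcoplateError):
    """Structurally invalid input (layout, plate file, config)."""


class LayoutError(ValidationError):
    """Plate layout violates the EcoPlate structural model."""


class DegenerateDataError(EcoplateError):
    """Data too degenerate for the requested statistic (e.g. zero variance)."""
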