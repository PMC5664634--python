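"""Exception hierarchy for the storechoice pipeline."""


class StoreChoiceError(Exception):
    """Base class for all storechoice errors."""


class ConfigurationError(StoreChoiceError):
    """A configuration value is missing, out of range, or inconsistent."""


class DataError(StoreChoiceError):
    """An input table violates a contract (missing columns, ids, coordinates)."""


class IntegrityError(DataError):
    """A cross-table invariant is violated (e.g. chosen store not in choice set)."""


class SpecificationError(StoreChoiceError):
    """A model specification references unknown attributes."""


class EstimationError(StoreChoiceError):
    """The likelihood cannot be maximised (rank deficiency, cancellation)."""


class NumericalError(StoreChoiceError):
    """A non-finite quantity appeared during numerical evaluation."""
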