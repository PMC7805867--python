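"""Exception hierarchy for loading and validation failures."""


class SelfOptError(ValueError):
    """Base class for all package-specific errors."""


class FormatError(SelfOptError):
    """An input table is missing required columns or has malformed values."""


class ConsistencyError(SelfOptError):
    """Logically inconsistent input (e.g. a gap junction without its reciprocal)."""


class CapacityError(SelfOptError):
    """A request exceeds what the structure can accommodate."""


class CoverageError(SelfOptError):
    """A cluster partition does not cover every neuron it is applied to."""
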