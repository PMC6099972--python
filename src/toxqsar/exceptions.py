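"""Exception hierarchy for toxqsar."""


class ToxQSARError(Exception):
    """Base class for all toxqsar errors."""


class SchemaError(ToxQSARError, ValueError):
    """A required column is missing or a table violates the column contract."""


class ParseError(ToxQSARError, ValueError):
    """A cell could not be parsed; the message names the offending row."""


class SingularDesignError(ToxQSARError, ValueError):
    """The design matrix is rank deficient."""


class UnderdeterminedError(ToxQSARError, ValueError):
    """Fewer observations than parameters + 1."""


class UndefinedStatisticError(ToxQSARError, ValueError):
    """A statistic's denominator is zero (e.g. constant response)."""


class InvalidWidthError(ToxQSARError, ValueError):
    """RBF width must be strictly positive."""


class DegenerateGeometryError(ToxQSARError, ValueError):
    """Two bonded atoms coincide (zero interatomic distance)."""


class NotApplicableError(ToxQSARError, LookupError):
    """A descriptor is undefined for the molecule (e.g. no matching bond)."""


class InvalidPartitionError(ToxQSARError, ValueError):
    """A rotation-validation subset is empty or mislabelled."""
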