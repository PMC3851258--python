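"""Exception hierarchy for the dntox pipeline."""


class DntoxError(ValueError):
    """Base class for all pipeline errors."""


class FormatError(DntoxError):
    """An input file does not conform to the expected tabular layout."""


class ValidationError(DntoxError):
    """Parsed data violate a structural invariant (ragged series, bad roles...)."""


class ConfigurationError(DntoxError):
    """The experiment lacks a component a stage requires (e.g. promoterless wells)."""


class ParameterError(DntoxError):
    """A user-supplied parameter is outside its valid range."""


class NumericalError(DntoxError):
    """A numerical routine produced non-finite values."""
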