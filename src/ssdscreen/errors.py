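"""Exception hierarchy for ssdscreen."""


class SSDScreenError(Exception):
    """Base class for all ssdscreen errors."""


class NewickParseError(SSDScreenError):
    """Malformed Newick input."""


class SchemaError(SSDScreenError):
    """A table is missing required columns or has the wrong layout."""


class ValidationError(SSDScreenError):
    """A table parses but contains invalid values (negative counts, bad masses...)."""


class ConfigError(SSDScreenError):
    """An AnalysisConfig violates its invariants."""


class DegenerateInputError(SSDScreenError):
    """An input is structurally valid but statistically degenerate (zero variance...)."""
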