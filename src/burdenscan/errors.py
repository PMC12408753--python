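"""Exception types shared across the pipeline."""


class BurdenScanError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(BurdenScanError):
    """A configuration field is missing or outside its valid range."""


class DataError(BurdenScanError):
    """Input data violate a structural precondition (negative depth, assay before birth, ...)."""
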