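"""Exception hierarchy.

Exit-code mapping used by the CLI: ValidationError/ConfigError -> 2,
I/O and format problems -> 3.
"""


class YstrError(Exception):
    """Base class for all ystrkit errors."""


class FormatError(YstrError):
    """Malformed input file: missing columns, unparseable values, empty file."""


class ValidationError(YstrError):
    """Data violates a model invariant (duplicate IDs, bad allele, ...)."""


class DiversityError(YstrError):
    """A diversity estimator was asked for an undefined quantity (n < 2)."""


class ConfigError(YstrError):
    """Invalid analysis or simulation configuration."""
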