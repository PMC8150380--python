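"""Exception hierarchy.

``CrossessError`` covers everything the package raises deliberately (bad
input files, invalid configuration, degenerate data); anything else escaping
is an internal bug.
"""


class CrossessError(Exception):
    """Base class for user-facing errors."""


class FormatError(CrossessError):
    """A standard-format file could not be parsed; message names file and line."""


class ConfigError(CrossessError):
    """Invalid configuration or parameter value."""
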