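"""Exception hierarchy.

CLI exit-code mapping: FormatError -> 2 (bad input file),
ConfigError -> 3 (configuration invariant violation).
"""


class EpitrackError(Exception):
    """Base class for all package errors."""


class ConfigError(EpitrackError):
    """A configuration value violates an invariant."""


class FormatError(EpitrackError):
    """A genome/config/target file is malformed."""


class MocOverflowError(ConfigError):
    """The driver-state counter exceeded the code space A**L.

    Signals that the grid (and stage count) can create more driver cells
    than the configured code alphabet can name; enlarge moc_length or
    alphabet_size, or shrink the grid.
    """
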