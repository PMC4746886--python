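"""Exception hierarchy for the ylinkage pipeline."""


class YlinkageError(Exception):
    """Base class for all package errors."""


class CatalogError(YlinkageError):
    """Invalid library catalog (empty/nested prefixes, missing sex)."""


class UnknownLibraryError(YlinkageError):
    """A read name matches no library prefix in the catalog."""


class ReadMapFormatError(YlinkageError):
    """Malformed row in a read-to-scaffold assignment table."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        super().__init__(message)


class HitTableFormatError(YlinkageError):
    """Malformed row in a 12-column tabular homology file."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        super().__init__(message)


class UndefinedStatisticsError(YlinkageError):
    """A statistic is requested from an empty read set."""


class MetadataError(YlinkageError):
    """A required annotation (e.g. conservation label) is missing."""


class AlignmentError(YlinkageError):
    """Calls and truth tables disagree on the scaffold set."""


class ConfigError(YlinkageError):
    """Invalid or incomplete pipeline configuration."""
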