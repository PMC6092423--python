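"""Exception hierarchy.

Exit-code mapping for the CLI: ConfigError -> 2, FormatError/IO -> 3,
any other StageError -> 4.
"""


class SortScreenError(Exception):
    """Base class for all package errors."""


class ConfigError(SortScreenError):
    """Invalid configuration value or combination."""


class FormatError(SortScreenError):
    """Malformed input file (library table, FASTQ, sample sheet, ...)."""


class PairingError(SortScreenError):
    """A replicate lacks its paired input/high fraction."""


class SimulationError(SortScreenError):
    """Simulation produced a degenerate state (e.g. empty sorted fraction)."""


class DegenerateTableError(SortScreenError):
    """A contingency table with an expected cell of zero."""


class StageError(SortScreenError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
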