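"""Exception hierarchy.

``InputError`` marks malformed user input (CLI exit code 2);
``AnalysisError`` marks violated analysis preconditions such as an empty
cohort (CLI exit code 3).
"""


class CdrlightError(Exception):
    """Base class for all package errors."""


class InputError(CdrlightError):
    """Malformed or unreadable input data."""


class AnalysisError(CdrlightError):
    """An analysis precondition is not met (e.g. empty cohort)."""


class InsufficientReplicatesError(AnalysisError):
    """Fewer than two usable qPCR replicates."""
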