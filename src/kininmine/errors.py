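"""Exception hierarchy shared across the package."""


class KininmineError(Exception):
    """Base class for all package errors."""


class InputError(KininmineError):
    """Malformed user input (bad alphabet, unreadable file, schema violation)."""


class ContractError(KininmineError):
    """A documented precondition was violated by the caller."""


class AlignmentError(KininmineError):
    """Spliced alignment could not produce a model covering the cDNA."""


class AnalysisError(KininmineError):
    """A statistical analysis cannot be run on the data provided."""
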