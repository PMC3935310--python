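"""Exception hierarchy shared across the pipeline."""


class SubcellError(Exception):
    """Base class for all package errors."""


class InputError(SubcellError):
    """An input file is missing, unreadable or malformed."""


class ValidationError(SubcellError):
    """Input violates a documented precondition or invariant."""


class TermLookupError(SubcellError, KeyError):
    """A compartment term id is not present in the ontology."""


class CalibrationError(SubcellError):
    """The score distribution is too degenerate for z-calibration."""
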