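"""Exception hierarchy for the pipeline."""


class IsmlError(Exception):
    """Base class for all pipeline errors."""


class FormatError(IsmlError):
    """A tabular input file violates the expected dialect."""


class ValidationError(IsmlError):
    """Input data violates a contract (unknown labels, duplicates, shapes)."""


class DesignError(IsmlError):
    """A simulation design is internally inconsistent or infeasible."""
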