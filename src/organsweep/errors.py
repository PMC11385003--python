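"""Exception hierarchy shared across the package."""


class OrganSweepError(Exception):
    """Base class for all package errors."""


class FormatError(OrganSweepError):
    """A file does not conform to its declared format (FASTA/PAF/SAM/TSV)."""


class ContractError(OrganSweepError):
    """An operation was called with inputs violating its stated preconditions."""


class DepthReferenceError(OrganSweepError):
    """The organelle depth reference is unusable (zero or negative average depth)."""
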