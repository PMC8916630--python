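"""Exception hierarchy shared by all crsim modules."""


class CrsimError(ValueError):
    """Base class for all crsim errors."""


class FormatError(CrsimError):
    """An input file does not have the expected layout (missing columns etc.)."""


class IntegrityError(CrsimError):
    """Input values violate a structural invariant (bounds, duplicates, rank)."""


class DomainError(CrsimError):
    """A parameter lies outside its mathematical domain."""
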