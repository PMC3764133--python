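"""Exception hierarchy for varldkit."""


class VarldkitError(Exception):
    """Base class for all varldkit errors."""


class PanelError(VarldkitError):
    """A genotype panel violates its invariants or is empty."""


class ParseError(VarldkitError):
    """An input file could not be parsed."""


class HarmonizationError(VarldkitError):
    """Two panels share no usable variants after harmonization."""


class UndefinedLDError(VarldkitError):
    """LD is undefined (monomorphic locus or too few complete observations)."""


class LookupError_(VarldkitError):
    """An identifier was not found in a panel or matrix."""
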