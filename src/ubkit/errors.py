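"""Exception hierarchy shared across the toolkit."""


class UbkitError(Exception):
    """Base class for all toolkit errors."""


class PeakFormatError(UbkitError):
    """A peak-list file could not be parsed (names the offending line)."""


class ValidationError(UbkitError):
    """Input violates a stated invariant (duplicate residues, negative volumes, ...)."""


class EmptyProfileError(UbkitError):
    """Two peak lists share no pairable residues."""


class UndefinedStatisticError(UbkitError):
    """A statistic (SD, Pearson r) is undefined for the given data."""


class EmptySelectionError(UbkitError):
    """The residue-selection rule returned no residues; a fit cannot proceed."""


class FitError(UbkitError):
    """Global fit could not be set up (unidentifiable) or failed outright."""


class TopologyError(UbkitError):
    """Structure ensemble frames disagree on atom/residue topology."""
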