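"""Exception hierarchy for the coremum pipeline."""


class CoremumError(Exception):
    """Base class for all coremum errors."""


class InputFormatError(CoremumError):
    """An input file could not be parsed or violates an input invariant."""


class NoIndexableSequenceError(CoremumError):
    """The reference contains no indexable (non-N) sequence."""


class NoGenomesRecruitedError(CoremumError):
    """MUMi recruitment excluded every candidate genome."""


class NoCoreAlignmentError(CoremumError):
    """No locally collinear block survived weight filtering."""


class InternalConsistencyError(CoremumError):
    """A reconstruction self-check failed; always indicates a bug."""


class SaturationError(CoremumError):
    """Pairwise SNP distance is saturated (p >= 0.75); the Jukes-Cantor
    correction is undefined.  Cannot happen for intraspecific input."""


class NewickParseError(CoremumError):
    """Malformed Newick input."""


class ArchiveError(CoremumError):
    """The binary archive is invalid, truncated or corrupt."""
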