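"""Exception hierarchy shared across the package."""


class CodonBiasError(Exception):
    """Base class for all package-specific errors."""


class FastaError(CodonBiasError):
    """Malformed FASTA input."""


class FrameError(CodonBiasError):
    """Coding sequence length is not a positive multiple of three."""


class AmbiguityError(CodonBiasError):
    """Sequence contains non-ACGT characters under a strict policy."""


class PrematureStopError(CodonBiasError):
    """Internal stop codon encountered during translation."""


class TableFormatError(CodonBiasError):
    """Codon usage table fails to parse or is incomplete."""


class ProfileError(CodonBiasError):
    """A codon profile is missing a required amino-acid family."""
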