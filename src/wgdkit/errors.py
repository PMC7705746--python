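"""Exception types shared across the toolkit."""


class WgdkitError(Exception):
    """Base class for all toolkit errors."""


class FastaFormatError(WgdkitError):
    """Malformed or empty FASTA/GFF3 input."""


class SaturationError(WgdkitError):
    """A distance correction left its domain (too many multiple hits).

    Raised when the observed substitution proportions make the
    logarithmic correction undefined, i.e. the sequences are so
    diverged that the distance is incalculable.
    """


class PartitionAmbiguityError(WgdkitError):
    """Subgenome partition requested on chromosomes that do not separate."""
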