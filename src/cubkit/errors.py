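"""Exception hierarchy for cubkit."""


class CubkitError(Exception):
    """Base class for all cubkit errors."""


class FastaParseError(CubkitError):
    """Malformed FASTA input (e.g. sequence data before any header)."""


class FrameError(CubkitError):
    """CDS length is not an exact multiple of three."""

    def __init__(self, seq_id: str, length: int):
        self.seq_id = seq_id
        self.length = length
        super().__init__(
            f"sequence {seq_id!r} has length {length}, not a multiple of 3"
        )


class InternalStopError(CubkitError):
    """A stop codon occurs before the final codon under strict validation."""


class UndefinedProfileError(CubkitError):
    """A per-sequence statistic is undefined (e.g. zero counted codons)."""


class ENCUndefinedError(CubkitError):
    """ENC cannot be computed because a required degeneracy class is empty."""


class ReferenceTableError(CubkitError):
    """Host reference codon-usage table is missing or incomplete."""


class ConfigurationError(CubkitError):
    """Invalid analysis configuration (thresholds, ranges, policies)."""
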