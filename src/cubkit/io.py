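"""FASTA input, CDS validation and codon counting.

Validation enforces the frame rule (length an exact multiple of three),
handles stop codons (a terminal stop is dropped by default; internal stops
are an error under the strict policy) and leaves ambiguity codes (N, R, Y,
…) untouched — the codon containing one is simply excluded from counts and
never guessed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FastaParseError, FrameError, InternalStopError
from .genetics import ALL_CODONS, GeneticCode, STANDARD_CODE

logger = logging.getLogger(__name__)

_UNAMBIGUOUS = set("ACGT")


@dataclass(frozen=True)
class CodingSequence:
    """A coding sequence: accession-like id plus uppercase DNA text."""

    id: str
    nucleotides: str
    flags: tuple[str, ...] = ()

    @property
    def length(self) -> int:
        return len(self.nucleotides)

    @property
    def n_codons(self) -> int:
        return self.length // 3

    def codons(self) -> list[str]:
        s = self.nucleotides
        return [s[i : i + 3] for i in range(0, len(s) - len(s) % 3, 3)]


@dataclass(frozen=True)
class ValidationPolicy:
    """How strictly a CDS must conform before counting.

    strict
        Frame violations and internal stop codons raise; otherwise the
        sequence is trimmed to frame / flagged and analysis proceeds
        (internal stops are excluded from counts downstream).
    drop_terminal_stop
        Remove a final stop codon before codon-level statistics (default).
    """

    strict: bool = True
    drop_terminal_stop: bool = True


@dataclass
class CodonCountTable:
    """Per-codon occurrence counts for one CDS or a pooled set."""

    counts: dict[str, int]
    n_codons: int
    n_excluded: int = 0

    def __post_init__(self):
        for c in ALL_CODONS:
            self.counts.setdefault(c, 0)

    def __getitem__(self, codon: str) -> int:
        return self.counts[codon]

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        merged = {c: self.counts[c] + other.counts[c] for c in ALL_CODONS}
        return CodonCountTable(
            counts=merged,
            n_codons=self.n_codons + other.n_codons,
            n_excluded=self.n_excluded + other.n_excluded,
        )


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_cds_fasta(path: str | Path) -> list[CodingSequence]:
    """Read a multi-record FASTA into :class:`CodingSequence` records.

    Ids are taken from the header up to the first whitespace; U is
    normalized to T and case is folded to uppercase. Record order is
    preserved.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: sequence data before any "
                    f"'>' header"
                )
            break
    records = [
        CodingSequence(id=rec.id, nucleotides=_normalize(str(rec.seq)))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        logger.warning("no FASTA records found in %s", path)
    return records


def write_cds_fasta(seqs: list[CodingSequence], path: str | Path) -> None:
    """Write sequences back to FASTA (unwrapped lines)."""
    recs = [
        SeqRecord(Seq(s.nucleotides), id=s.id, description="") for s in seqs
    ]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta-2line")


def validate_cds(
    seq: CodingSequence,
    code: GeneticCode = STANDARD_CODE,
    policy: ValidationPolicy = ValidationPolicy(),
) -> CodingSequence:
    """Validate (and normalise) a CDS against the frame and stop rules.

    Returns a new :class:`CodingSequence`; under the permissive policy
    problems are recorded in ``flags`` instead of raising.
    """
    if seq.length == 0:
        raise FrameError(seq.id, 0)
    nt = _normalize(seq.nucleotides)
    flags: list[str] = list(seq.flags)

    if len(nt) % 3 != 0:
        if policy.strict:
            raise FrameError(seq.id, len(nt))
        nt = nt[: len(nt) - len(nt) % 3]
        flags.append("trimmed_to_frame")
    codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
    if policy.drop_terminal_stop and codons and code.is_stop(codons[-1]):
        codons = codons[:-1]
        flags.append("terminal_stop_removed")

    internal_stops = [i for i, c in enumerate(codons) if code.is_stop(c)]
    if internal_stops:
        if policy.strict:
            raise InternalStopError(
                f"sequence {seq.id!r}: internal stop codon at codon "
                f"{internal_stops[0] + 1}"
            )
        flags.append("internal_stop")

    return replace(seq, nucleotides="".join(codons), flags=tuple(flags))


def count_codons(
    seqs: CodingSequence | list[CodingSequence],
    code: GeneticCode = STANDARD_CODE,
    include_stop: bool = False,
) -> CodonCountTable:
    """Count every in-frame codon; pooling over sequences sums counts.

    Codons containing non-ACGT symbols are excluded and tallied in
    ``n_excluded``, as are stop codons unless ``include_stop`` is set.
    """
    if isinstance(seqs, CodingSequence):
        seqs = [seqs]
    counts = {c: 0 for c in ALL_CODONS}
    n_excluded = 0
    for seq in seqs:
        for codon in seq.codons():
            if not set(codon) <= _UNAMBIGUOUS:
                n_excluded += 1
                continue
            if not include_stop and code.is_stop(codon):
                n_excluded += 1
                continue
            counts[codon] += 1
    return CodonCountTable(
        counts=counts, n_codons=sum(counts.values()), n_excluded=n_excluded
    )


def counted_codons(
    seq: CodingSequence,
    code: GeneticCode = STANDARD_CODE,
    include_stop: bool = False,
) -> list[str]:
    """The codons of ``seq`` that enter codon-level statistics."""
    out = []
    for codon in seq.codons():
        if not set(codon) <= _UNAMBIGUOUS:
            continue
        if not include_stop and code.is_stop(codon):
            continue
        out.append(codon)
    return out
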