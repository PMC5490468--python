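"""Reading, validating and writing protein sequences in FASTA (Pearson) format.

The package aligns exactly one *pattern* against one *subject*; helpers here
parse FASTA text or files into :class:`ProteinSequence` records and enforce
the amino-acid alphabet.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, List, Union

from .errors import (
    FastaParseError,
    IdenticalSequencesError,
    MissingSequenceError,
    ResidueValidationError,
)

logger = logging.getLogger(__name__)

#: The 20 standard one-letter amino-acid codes.
STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Extended codes accepted only in lenient mode (ambiguity codes and the
#: rare residues selenocysteine/pyrrolysine).
EXTENDED_RESIDUES = "BJZXUO"

GAP_CHARS = "-."

_STANDARD_SET = frozenset(STANDARD_RESIDUES)
_LENIENT_SET = frozenset(STANDARD_RESIDUES + EXTENDED_RESIDUES)

#: Line width used when writing FASTA.
FASTA_WRAP = 80


@dataclass(frozen=True)
class ProteinSequence:
    """An identified, validated amino-acid sequence.

    ``id`` is the FASTA header up to the first whitespace; ``description``
    is the remainder of the header line (possibly empty).  ``residues`` is
    an uppercase, gap-free amino-acid string.
    """

    id: str
    residues: str
    description: str = field(default="")

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues


def validate_residues(raw: str, *, strict: bool = True) -> str:
    """Uppercase ``raw`` and verify every character is an allowed residue code.

    Gap characters are never allowed in input sequences.  In strict mode only
    the 20 standard codes pass; lenient mode additionally accepts
    ``B J Z X U O``.  Raises :class:`ResidueValidationError` naming the first
    offending character and its 1-based position.
    """
    residues = raw.upper()
    allowed = _STANDARD_SET if strict else _LENIENT_SET
    for pos, ch in enumerate(residues, start=1):
        if ch in GAP_CHARS:
            raise ResidueValidationError(
                f"gap character {ch!r} at position {pos}: "
                "input sequences must be ungapped"
            )
        if ch not in allowed:
            hint = " (allowed only in lenient mode)" if ch in _LENIENT_SET else ""
            raise ResidueValidationError(
                f"disallowed character {ch!r} at position {pos}{hint}"
            )
    return residues


def _looks_like_path(source: str) -> bool:
    if source.lstrip().startswith(">"):
        return False
    return "\n" not in source


def read_fasta(
    source: Union[str, "os.PathLike[str]"], *, strict: bool = True
) -> List[ProteinSequence]:
    """Parse FASTA from a path or from raw FASTA text.

    Residues are uppercased and internal whitespace is stripped.  An empty
    source or one with no records raises :class:`MissingSequenceError`
    (the "missing sequence" condition); a malformed record raises
    :class:`FastaParseError` naming the line.
    """
    if isinstance(source, str) and not _looks_like_path(source):
        text = source
        origin = "<text>"
    else:
        origin = os.fspath(source)
        try:
            with open(origin, "r", encoding="utf-8") as fh:
                text = fh.read()
        except FileNotFoundError:
            raise MissingSequenceError(f"missing sequence file: {origin}")

    records: List[ProteinSequence] = []
    header: str | None = None
    chunks: List[str] = []
    header_line = 0

    def flush(line_no: int) -> None:
        if header is None:
            return
        residues = "".join("".join(chunks).split())
        if not residues:
            raise FastaParseError(
                f"{origin}: record {header!r} (line {header_line}) has no residues"
            )
        ident, _, desc = header.partition(" ")
        if not ident:
            raise FastaParseError(f"{origin}: empty header at line {header_line}")
        records.append(
            ProteinSequence(
                id=ident,
                residues=validate_residues(residues, strict=strict),
                description=desc.strip(),
            )
        )

    for line_no, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            flush(line_no)
            header = stripped[1:].strip()
            header_line = line_no
            chunks = []
        else:
            if header is None:
                raise FastaParseError(
                    f"{origin}: line {line_no} precedes the first '>' header"
                )
            chunks.append(stripped)
    flush(line_no=len(text.splitlines()))

    if not records:
        raise MissingSequenceError(f"missing sequence: no FASTA records in {origin}")
    return records


def write_fasta(
    seqs: Iterable[ProteinSequence], dest: Union[str, "os.PathLike[str]"]
) -> None:
    """Write sequences as wrapped FASTA; round-trips exactly through read_fasta."""
    seqs = list(seqs)
    if not seqs:
        raise MissingSequenceError("write_fasta: no sequences to write")
    with open(dest, "w", encoding="utf-8") as fh:
        for seq in seqs:
            header = seq.id if not seq.description else f"{seq.id} {seq.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(seq.residues), FASTA_WRAP):
                fh.write(seq.residues[i : i + FASTA_WRAP] + "\n")


def first_record(
    source: Union[str, "os.PathLike[str]"], *, strict: bool = True
) -> ProteinSequence:
    """Read a FASTA source and return its first record, warning if more exist."""
    records = read_fasta(source, strict=strict)
    if len(records) > 1:
        logger.warning(
            "FASTA source has %d records; using only the first (%s)",
            len(records),
            records[0].id,
        )
    return records[0]


def check_distinct(
    pattern: ProteinSequence,
    subject: ProteinSequence,
    *,
    allow_identical: bool = False,
) -> None:
    """Raise the "identical sequences" diagnostic unless overridden."""
    if pattern.residues == subject.residues:
        if allow_identical:
            logger.warning("identical sequences: pattern equals subject")
        else:
            raise IdenticalSequencesError(
                "identical sequences: pattern and subject are the same "
                "(pass allow_identical to proceed)"
            )
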