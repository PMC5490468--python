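"""Searching within alignments: indel runs, identity regions, subsequence
occurrences and position lookup.

All coordinates are 1-based closed intervals in alignment columns.  A
``gap_in_subject`` run means gap characters in the aligned subject (an
insertion in the pattern relative to the subject) and vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Literal

from .align import GAP, Alignment
from .errors import InputError
from .matrices import SubstitutionMatrix
from .metrics import AlignmentColumn, annotate_columns

Role = Literal["gap_in_pattern", "gap_in_subject"]


@dataclass(frozen=True)
class IndelRecord:
    """A maximal run of gap columns in one aligned string."""

    role: Role
    start: int  # 1-based alignment column
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length - 1


@dataclass(frozen=True)
class MatchRegion:
    """A closed interval of alignment columns."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InputError(f"invalid region ({self.start}, {self.end})")


def _gap_runs(aligned: str, role: Role) -> List[IndelRecord]:
    runs: List[IndelRecord] = []
    start = None
    for idx, ch in enumerate(aligned, start=1):
        if ch == GAP:
            if start is None:
                start = idx
        elif start is not None:
            runs.append(IndelRecord(role=role, start=start, length=idx - start))
            start = None
    if start is not None:
        runs.append(IndelRecord(role=role, start=start, length=len(aligned) - start + 1))
    return runs


def find_indels(alignment: Alignment) -> List[IndelRecord]:
    """All maximal gap runs in both aligned strings, sorted by start column."""
    runs = _gap_runs(alignment.aligned_pattern, "gap_in_pattern") + _gap_runs(
        alignment.aligned_subject, "gap_in_subject"
    )
    return sorted(runs, key=lambda r: (r.start, r.role))


def find_match_regions(alignment: Alignment) -> List[MatchRegion]:
    """Maximal runs of identity columns (both residues, equal)."""
    regions: List[MatchRegion] = []
    start = None
    for idx, (pc, sc) in enumerate(
        zip(alignment.aligned_pattern, alignment.aligned_subject), start=1
    ):
        ident = pc != GAP and pc == sc
        if ident and start is None:
            start = idx
        elif not ident and start is not None:
            regions.append(MatchRegion(start=start, end=idx - 1))
            start = None
    if start is not None:
        regions.append(MatchRegion(start=start, end=len(alignment)))
    return regions


def find_subsequence(
    alignment: Alignment, query: str, role: Literal["pattern", "subject"]
) -> List[MatchRegion]:
    """All occurrences of ``query`` in the degapped chosen sequence, mapped
    back to alignment-column coordinates.

    A hit spans any gap columns interleaved within it; overlapping
    occurrences are all reported.
    """
    if not query:
        raise InputError("subsequence query must be non-empty")
    query = query.upper()
    if any(c == GAP or c == "." for c in query):
        raise InputError("subsequence query must not contain gap characters")
    if role not in ("pattern", "subject"):
        raise InputError(f"unknown role {role!r}; expected 'pattern' or 'subject'")

    aligned = (
        alignment.aligned_pattern if role == "pattern" else alignment.aligned_subject
    )
    # Map degapped residue index -> alignment column (1-based).
    col_of: List[int] = [i for i, ch in enumerate(aligned, start=1) if ch != GAP]
    degapped = "".join(ch for ch in aligned if ch != GAP)

    hits: List[MatchRegion] = []
    start = degapped.find(query)
    while start != -1:
        hits.append(
            MatchRegion(start=col_of[start], end=col_of[start + len(query) - 1])
        )
        start = degapped.find(query, start + 1)
    return hits


def locate_position(
    alignment: Alignment,
    position: int,
    matrix: SubstitutionMatrix,
    *,
    lenient: bool = False,
) -> AlignmentColumn:
    """The annotated column at a 1-based alignment position."""
    n = len(alignment)
    if not 1 <= position <= n:
        raise InputError(
            f"position {position} out of range; valid range is 1..{n}"
        )
    return annotate_columns(alignment, matrix, lenient=lenient)[position - 1]
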