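"""Alignment-quality metrics and per-column annotation.

Four percent-identity variants differ only in the denominator:

PID 1  aligned positions plus internal gap positions
PID 2  aligned positions
PID 3  ungapped length of the shorter input sequence
PID 4  mean ungapped length of the two input sequences

"Aligned positions" are columns where both characters are residues;
"internal" gap columns exclude gap runs touching either end of the
alignment.  Identity is exact residue equality after uppercasing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Union

from .align import GAP, Alignment
from .errors import InputError
from .matrices import Conservation, SubstitutionMatrix
from .seqio import STANDARD_RESIDUES

PID_TYPES = (1, 2, 3, 4)

SCHEME_NAMES = (
    "hydropathy",
    "volume",
    "chemical",
    "charge",
    "hydrogen_don_acc",
    "polarity",
    "physicochemical",
)

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class PIDSet:
    """The four percent-identity values of one alignment."""

    pid1: float
    pid2: float
    pid3: float
    pid4: float

    def get(self, pid_type: int) -> float:
        return getattr(self, f"pid{pid_type}")

    def as_dict(self) -> Dict[str, float]:
        return {str(t): self.get(t) for t in PID_TYPES}


@dataclass(frozen=True)
class AlignmentColumn:
    """One aligned position with its substitution annotation."""

    position: int  # 1-based alignment column
    pattern_char: str
    subject_char: str
    log_odds: Optional[float]  # None iff the column contains a gap
    conservation: Conservation
    is_identity: bool
    is_indel: bool


def _column_stats(alignment: Alignment):
    p, s = alignment.aligned_pattern, alignment.aligned_subject
    identities = 0
    aligned = 0
    gap_cols = []
    for idx, (pc, sc) in enumerate(zip(p, s)):
        if pc == GAP or sc == GAP:
            gap_cols.append(idx)
        else:
            aligned += 1
            if pc == sc:
                identities += 1
    return identities, aligned, gap_cols


def _internal_gap_count(alignment: Alignment) -> int:
    """Gap columns excluding terminal gap runs of the alignment."""
    p, s = alignment.aligned_pattern, alignment.aligned_subject
    n = len(p)
    is_gap = [p[i] == GAP or s[i] == GAP for i in range(n)]
    first = 0
    while first < n and is_gap[first]:
        first += 1
    last = n - 1
    while last >= 0 and is_gap[last]:
        last -= 1
    return sum(1 for i in range(first, last + 1) if is_gap[i])


def percent_identity(alignment: Alignment, pid_type: int) -> float:
    """Percent identity of an alignment under one of the four definitions."""
    if pid_type not in PID_TYPES:
        raise InputError(f"unknown PID type {pid_type!r}; expected 1, 2, 3 or 4")
    identities, aligned, _ = _column_stats(alignment)
    if pid_type == 1:
        denom = aligned + _internal_gap_count(alignment)
    elif pid_type == 2:
        denom = aligned
    elif pid_type == 3:
        denom = min(alignment.pattern_length, alignment.subject_length)
    else:
        denom = (alignment.pattern_length + alignment.subject_length) / 2.0
    if denom == 0:
        return 0.0
    return 100.0 * identities / denom


def pid_set(alignment: Alignment) -> PIDSet:
    return PIDSet(*(percent_identity(alignment, t) for t in PID_TYPES))


def annotate_columns(
    alignment: Alignment, matrix: SubstitutionMatrix, *, lenient: bool = False
) -> List[AlignmentColumn]:
    """Annotate every alignment column with log-odds and conservation.

    Gap columns get an undefined (``None``) log-odds score and the
    ``undefined`` conservation class.
    """
    columns: List[AlignmentColumn] = []
    for idx, (pc, sc) in enumerate(
        zip(alignment.aligned_pattern, alignment.aligned_subject), start=1
    ):
        if pc == GAP or sc == GAP:
            columns.append(
                AlignmentColumn(
                    position=idx,
                    pattern_char=pc,
                    subject_char=sc,
                    log_odds=None,
                    conservation=Conservation.UNDEFINED,
                    is_identity=False,
                    is_indel=True,
                )
            )
        else:
            columns.append(
                AlignmentColumn(
                    position=idx,
                    pattern_char=pc,
                    subject_char=sc,
                    log_odds=matrix.lookup(pc, sc, lenient=lenient),
                    conservation=matrix.conservation_call(pc, sc, lenient=lenient),
                    is_identity=pc == sc,
                    is_indel=False,
                )
            )
    return columns


@dataclass(frozen=True)
class ClassificationScheme:
    """A total partition of the 20 standard residues into named subgroups."""

    name: str
    mapping: Dict[str, str]  # residue -> subgroup label

    def __post_init__(self) -> None:
        covered = set(self.mapping)
        expected = set(STANDARD_RESIDUES)
        if covered != expected:
            missing = "".join(sorted(expected - covered))
            extra = "".join(sorted(covered - expected))
            raise InputError(
                f"scheme {self.name!r} is not a partition of the 20 residues"
                + (f"; missing {missing}" if missing else "")
                + (f"; unexpected {extra}" if extra else "")
            )

    def subgroups(self) -> Dict[str, str]:
        groups: Dict[str, List[str]] = {}
        for res, grp in self.mapping.items():
            groups.setdefault(grp, []).append(res)
        return {g: "".join(sorted(rs)) for g, rs in groups.items()}


def classify_residue(residue: str, scheme: ClassificationScheme) -> str:
    """Subgroup of ``residue`` in ``scheme``; non-standard codes are unclassified."""
    return scheme.mapping.get(residue.upper(), UNCLASSIFIED)


def load_classification_table(
    path: Union[str, "os.PathLike[str]", None] = None,
) -> Dict[str, ClassificationScheme]:
    """Load classification schemes from a TSV (scheme, subgroup, residues).

    Defaults to the bundled table.  Every scheme is validated to partition
    the standard alphabet; duplicated residues raise.
    """
    if path is None:
        text = (resources.files("pairsub") / "data" / "classification.tsv").read_text(
            "utf-8"
        )
        origin = "<bundled>"
    else:
        origin = str(path)
        text = Path(path).read_text("utf-8")

    raw: Dict[str, Dict[str, str]] = {}
    for line_no, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split("\t")
        if len(parts) != 3:
            parts = stripped.split()
        if len(parts) != 3:
            raise InputError(
                f"{origin}:{line_no}: expected 'scheme subgroup residues'"
            )
        scheme, subgroup, residues = parts
        mapping = raw.setdefault(scheme, {})
        for res in residues.upper():
            if res in mapping:
                raise InputError(
                    f"{origin}:{line_no}: residue {res!r} assigned twice in "
                    f"scheme {scheme!r}"
                )
            mapping[res] = subgroup
    return {name: ClassificationScheme(name, mapping) for name, mapping in raw.items()}


def classify_alignment(
    alignment: Alignment, scheme: ClassificationScheme
) -> List[Dict[str, str]]:
    """Per-column subgroup labels for pattern and subject characters."""
    out = []
    for pc, sc in zip(alignment.aligned_pattern, alignment.aligned_subject):
        out.append(
            {
                "pattern": classify_residue(pc, scheme) if pc != GAP else "gap",
                "subject": classify_residue(sc, scheme) if sc != GAP else "gap",
            }
        )
    return out
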