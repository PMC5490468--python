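"""Affine-gap pairwise alignment of a pattern against a subject.

Five scoring modes are supported:

``global``
    Needleman–Wunsch; both sequences fully aligned, end gaps penalized.
``local``
    Smith–Waterman; best-scoring substring pair, score floored at 0.
``overlap``
    Ends-free: the alignment must start on the first row or column of the
    DP grid and end on the last row or column, so a prefix of one sequence
    and a suffix of one sequence may be skipped at no cost.
``global_local``
    The *whole pattern* aligned against some contiguous substring of the
    subject (subject prefix/suffix free).
``local_global``
    The *whole subject* aligned against some contiguous substring of the
    pattern (pattern prefix/suffix free).

Gap runs cost ``gap_open + L * gap_extend`` (the first gapped position pays
both).  The DP is the standard three-state Gotoh recursion: one state per
column kind — residue pair, gap in the aligned subject (consuming pattern),
gap in the aligned pattern (consuming subject).

Traceback tie-breaking is deterministic: residue pair over gap-in-subject
over gap-in-pattern, and the smallest (pattern, subject) end coordinate among
equal-scoring end cells.  Exactly one optimal alignment is reported.

Reported alignments are trimmed to the aligned region: positions skipped for
free by the mode are expressed through ``pattern_range``/``subject_range``
rather than terminal gap columns.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import List, Optional, Tuple, Union

from .errors import AlignmentError
from .matrices import MatrixConfig
from .seqio import ProteinSequence

GAP = "-"

NEG_INF = float("-inf")

# H-state traceback pointers.
_START, _DIAG, _GAP_IN_SUBJECT, _GAP_IN_PATTERN = 0, 1, 2, 3


class AlignmentMode(str, enum.Enum):
    GLOBAL = "global"
    LOCAL = "local"
    OVERLAP = "overlap"
    GLOBAL_LOCAL = "global-local"
    LOCAL_GLOBAL = "local-global"

    @classmethod
    def parse(cls, value: Union[str, "AlignmentMode"]) -> "AlignmentMode":
        if isinstance(value, cls):
            return value
        key = value.strip().lower().replace("_", "-")
        for mode in cls:
            if mode.value == key:
                return mode
        raise AlignmentError(
            f"unknown alignment mode {value!r}; choose from "
            + ", ".join(m.value for m in cls)
        )


@dataclass(frozen=True)
class Alignment:
    """A gapped pattern/subject string pair with score and coordinates.

    Ranges are 1-based closed intervals of *original* sequence positions
    covered by the alignment; ``None`` when the sequence contributes no
    residues (empty local alignment).
    """

    aligned_pattern: str
    aligned_subject: str
    score: float
    mode: AlignmentMode
    config_label: str
    pattern_range: Optional[Tuple[int, int]]
    subject_range: Optional[Tuple[int, int]]
    pattern_length: int
    subject_length: int

    def __post_init__(self) -> None:
        if len(self.aligned_pattern) != len(self.aligned_subject):
            raise AlignmentError("aligned strings differ in length")
        for pc, sc in zip(self.aligned_pattern, self.aligned_subject):
            if pc == GAP and sc == GAP:
                raise AlignmentError("gap/gap column in alignment")

    def __len__(self) -> int:
        return len(self.aligned_pattern)

    @property
    def is_empty(self) -> bool:
        return len(self.aligned_pattern) == 0


def _residues(seq: Union[ProteinSequence, str]) -> str:
    return seq.residues if isinstance(seq, ProteinSequence) else seq


def align_pair(
    pattern: Union[ProteinSequence, str],
    subject: Union[ProteinSequence, str],
    config: MatrixConfig,
    mode: Union[AlignmentMode, str],
    *,
    lenient: bool = False,
) -> Alignment:
    """Optimally align pattern vs subject under one matrix/penalty config."""
    mode = AlignmentMode.parse(mode)
    p = _residues(pattern)
    s = _residues(subject)
    if not p or not s:
        raise AlignmentError("cannot align an empty sequence")

    matrix = config.matrix
    try:
        sub = [[matrix.lookup(a, b, lenient=lenient) for b in s] for a in p]
    except Exception as exc:  # surface with config context
        raise AlignmentError(
            f"{config.label}: scoring failed ({exc}); possible causes are "
            "poorly constructed sequences or custom matrices"
        ) from exc

    go, ge = config.gap_open, config.gap_extend
    open_cost = go + ge
    m, n = len(p), len(s)

    H = [[NEG_INF] * (n + 1) for _ in range(m + 1)]
    E = [[NEG_INF] * (n + 1) for _ in range(m + 1)]  # gap in pattern (consumes subject)
    F = [[NEG_INF] * (n + 1) for _ in range(m + 1)]  # gap in subject (consumes pattern)
    Hp = [[_START] * (n + 1) for _ in range(m + 1)]
    Eopen = [[True] * (n + 1) for _ in range(m + 1)]
    Fopen = [[True] * (n + 1) for _ in range(m + 1)]

    local = mode is AlignmentMode.LOCAL
    top_free = mode in (AlignmentMode.OVERLAP, AlignmentMode.GLOBAL_LOCAL, AlignmentMode.LOCAL)
    left_free = mode in (AlignmentMode.OVERLAP, AlignmentMode.LOCAL_GLOBAL, AlignmentMode.LOCAL)

    H[0][0] = 0.0
    for j in range(1, n + 1):
        if top_free:
            H[0][j] = 0.0
        else:  # paid leading gap in pattern
            E[0][j] = go + j * ge
            Eopen[0][j] = j == 1
            H[0][j] = E[0][j]
            Hp[0][j] = _GAP_IN_PATTERN
    for i in range(1, m + 1):
        if left_free:
            H[i][0] = 0.0
        else:  # paid leading gap in subject
            F[i][0] = go + i * ge
            Fopen[i][0] = i == 1
            H[i][0] = F[i][0]
            Hp[i][0] = _GAP_IN_SUBJECT

    for i in range(1, m + 1):
        row_sub = sub[i - 1]
        Hi, Hi1 = H[i], H[i - 1]
        Ei = E[i]
        Fi, Fi1 = F[i], F[i - 1]
        for j in range(1, n + 1):
            e_open = Hi[j - 1] + open_cost
            e_ext = Ei[j - 1] + ge
            if e_open >= e_ext:
                Ei[j] = e_open
            else:
                Ei[j] = e_ext
                Eopen[i][j] = False

            f_open = Hi1[j] + open_cost
            f_ext = Fi1[j] + ge
            if f_open >= f_ext:
                Fi[j] = f_open
            else:
                Fi[j] = f_ext
                Fopen[i][j] = False

            best = Hi1[j - 1] + row_sub[j - 1]
            ptr = _DIAG
            if Fi[j] > best:
                best, ptr = Fi[j], _GAP_IN_SUBJECT
            if Ei[j] > best:
                best, ptr = Ei[j], _GAP_IN_PATTERN
            if local and best <= 0.0:
                best, ptr = 0.0, _START
            Hi[j] = best
            Hp[i][j] = ptr

    end_cells: List[Tuple[int, int]]
    if mode is AlignmentMode.GLOBAL:
        end_cells = [(m, n)]
    elif mode is AlignmentMode.GLOBAL_LOCAL:
        end_cells = [(m, j) for j in range(n + 1)]
    elif mode is AlignmentMode.LOCAL_GLOBAL:
        end_cells = [(i, n) for i in range(m + 1)]
    elif mode is AlignmentMode.OVERLAP:
        end_cells = [(m, j) for j in range(n + 1)] + [
            (i, n) for i in range(m + 1) if i != m
        ]
    else:  # local
        end_cells = [(i, j) for i in range(m + 1) for j in range(n + 1)]

    end = min(end_cells, key=lambda ij: (-H[ij[0]][ij[1]], ij[0], ij[1]))
    score = H[end[0]][end[1]]

    if local and score <= 0.0:
        return Alignment(
            aligned_pattern="",
            aligned_subject="",
            score=0.0,
            mode=mode,
            config_label=config.label,
            pattern_range=None,
            subject_range=None,
            pattern_length=m,
            subject_length=n,
        )

    # Traceback.
    i, j = end
    cols: List[Tuple[str, str]] = []
    state = "H"
    while True:
        if state == "H":
            ptr = Hp[i][j]
            if ptr == _START:
                break
            if ptr == _DIAG:
                cols.append((p[i - 1], s[j - 1]))
                i -= 1
                j -= 1
            elif ptr == _GAP_IN_SUBJECT:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            opened = Fopen[i][j]
            cols.append((p[i - 1], GAP))
            i -= 1
            if opened:
                state = "H"
        else:  # E
            opened = Eopen[i][j]
            cols.append((GAP, s[j - 1]))
            j -= 1
            if opened:
                state = "H"

    cols.reverse()
    aligned_pattern = "".join(pc for pc, _ in cols)
    aligned_subject = "".join(sc for _, sc in cols)
    i0, j0 = i, j
    pattern_range = (i0 + 1, end[0]) if end[0] > i0 else None
    subject_range = (j0 + 1, end[1]) if end[1] > j0 else None

    return Alignment(
        aligned_pattern=aligned_pattern,
        aligned_subject=aligned_subject,
        score=score,
        mode=mode,
        config_label=config.label,
        pattern_range=pattern_range,
        subject_range=subject_range,
        pattern_length=m,
        subject_length=n,
    )


MAX_ORACLE_CELLS = 64


def enumerate_best_score(
    pattern: Union[ProteinSequence, str],
    subject: Union[ProteinSequence, str],
    config: MatrixConfig,
    mode: Union[AlignmentMode, str],
) -> float:
    """Exact optimum by exhaustive enumeration of admissible alignments.

    Test oracle, independent of the DP: every alignment path is generated
    recursively and its gap runs are scored with the affine cost directly.
    Refuses instances with len(pattern) * len(subject) > 64.
    """
    mode = AlignmentMode.parse(mode)
    p = _residues(pattern)
    s = _residues(subject)
    m, n = len(p), len(s)
    if m == 0 or n == 0:
        raise AlignmentError("cannot align an empty sequence")
    if m * n > MAX_ORACLE_CELLS:
        raise AlignmentError(
            f"enumeration oracle refuses instance of size {m}x{n} (> {MAX_ORACLE_CELLS} cells)"
        )

    matrix = config.matrix
    go, ge = config.gap_open, config.gap_extend
    open_cost = go + ge

    if mode is AlignmentMode.GLOBAL:
        starts = [(0, 0)]
        is_end = lambda i, j: i == m and j == n
    elif mode is AlignmentMode.OVERLAP:
        starts = [(0, j) for j in range(n + 1)] + [(i, 0) for i in range(1, m + 1)]
        is_end = lambda i, j: i == m or j == n
    elif mode is AlignmentMode.GLOBAL_LOCAL:
        starts = [(0, j) for j in range(n + 1)]
        is_end = lambda i, j: i == m
    elif mode is AlignmentMode.LOCAL_GLOBAL:
        starts = [(i, 0) for i in range(m + 1)]
        is_end = lambda i, j: j == n
    else:  # local: start and end anywhere, floor 0
        starts = [(i, j) for i in range(m + 1) for j in range(n + 1)]
        is_end = lambda i, j: True

    best = NEG_INF

    def rec(i: int, j: int, score: float, last: str) -> None:
        nonlocal best
        if is_end(i, j) and score > best:
            best = score
        if i < m and j < n:
            rec(i + 1, j + 1, score + matrix.lookup(p[i], s[j]), "M")
        if j < n:
            rec(i, j + 1, score + (ge if last == "E" else open_cost), "E")
        if i < m:
            rec(i + 1, j, score + (ge if last == "F" else open_cost), "F")

    for i0, j0 in starts:
        rec(i0, j0, 0.0, "M")

    if mode is AlignmentMode.LOCAL and best < 0.0:
        best = 0.0
    return best


def rescore_alignment(alignment: Alignment, config: MatrixConfig) -> float:
    """Recompute the score of a traceback alignment column by column.

    Substitution columns are scored via matrix lookup and gap runs with the
    affine cost; free end regions are already trimmed from the reported
    alignment, so no end-gap special casing is needed.
    """
    total = 0.0
    run_char: Optional[str] = None
    run_len = 0
    for pc, sc in zip(alignment.aligned_pattern, alignment.aligned_subject):
        if pc == GAP or sc == GAP:
            side = "p" if pc == GAP else "s"
            if run_char == side:
                run_len += 1
            else:
                total += config.gap_cost(run_len)
                run_char, run_len = side, 1
        else:
            total += config.gap_cost(run_len)
            run_char, run_len = None, 0
            total += config.matrix.lookup(pc, sc)
    total += config.gap_cost(run_len)
    return total
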