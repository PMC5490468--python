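"""Substitution matrices: bundled PAM/BLOSUM tables, custom-matrix parsing,
log-odds construction from frequency models, and conservation calls.

A substitution score is a log-odds value

    s_ij = ln(q_ij / (p_i * p_j)) / lambda

where q_ij is the observed substitution frequency of residues i and j, p the
background frequencies, and lambda a positive scaling constant.  A positive
score marks a conservative substitution, a negative score a non-conservative
one; an exact zero is reported as its own ``neutral`` class.
"""

from __future__ import annotations

import enum
import logging
import os
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import List, Sequence, Tuple, Union

import numpy as np

from .errors import MasterFileError, MatrixError, MatrixParseError

logger = logging.getLogger(__name__)

#: Names of the ten bundled matrices.
PREDEFINED_MATRICES = (
    "PAM30",
    "PAM40",
    "PAM70",
    "PAM120",
    "PAM250",
    "BLOSUM45",
    "BLOSUM50",
    "BLOSUM62",
    "BLOSUM80",
    "BLOSUM100",
)

#: Tolerance beyond which an input matrix is considered asymmetric.
SYMMETRY_TOL = 1e-9


class Conservation(str, enum.Enum):
    """Sign class of a substitution score."""

    CONSERVATIVE = "conservative"
    NON_CONSERVATIVE = "non_conservative"
    NEUTRAL = "neutral"
    UNDEFINED = "undefined"  # gap columns only


class SubstitutionMatrix:
    """A symmetric table of log-odds scores over a residue alphabet."""

    def __init__(
        self,
        label: str,
        alphabet: Sequence[str],
        scores: np.ndarray,
        *,
        symmetrize: bool = False,
        tol: float = SYMMETRY_TOL,
    ) -> None:
        alphabet = tuple(alphabet)
        scores = np.asarray(scores, dtype=float)
        k = len(alphabet)
        if len(set(alphabet)) != k:
            raise MatrixParseError(f"{label}: duplicate residue codes in alphabet")
        if scores.shape != (k, k):
            raise MatrixParseError(
                f"{label}: score table is {scores.shape}, expected {k}x{k}"
            )
        if not np.all(np.isfinite(scores)):
            raise MatrixParseError(f"{label}: non-finite score values")
        asym = np.max(np.abs(scores - scores.T)) if k else 0.0
        if asym > tol:
            if symmetrize:
                logger.warning(
                    "%s: asymmetric by %.3g; symmetrizing by averaging", label, asym
                )
                scores = (scores + scores.T) / 2.0
            else:
                i, j = np.unravel_index(
                    np.argmax(np.abs(scores - scores.T)), scores.shape
                )
                raise MatrixParseError(
                    f"{label}: asymmetric at ({alphabet[i]},{alphabet[j]}): "
                    f"{scores[i, j]} != {scores[j, i]}"
                )
        self.label = label
        self.alphabet = alphabet
        self.scores = scores
        self._index = {c: i for i, c in enumerate(alphabet)}

    def __contains__(self, residue: str) -> bool:
        return residue in self._index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SubstitutionMatrix):
            return NotImplemented
        return self.alphabet == other.alphabet and np.array_equal(
            self.scores, other.scores
        )

    def __repr__(self) -> str:
        return f"SubstitutionMatrix({self.label!r}, {len(self.alphabet)} codes)"

    def lookup(self, a: str, b: str, *, lenient: bool = False) -> float:
        """Score of substituting residue ``a`` with ``b`` (symmetric).

        Gap characters have no log-odds score and always raise.  Residues
        outside the alphabet raise in strict mode and score 0 (with a
        warning) in lenient mode.
        """
        if a in "-." or b in "-.":
            raise MatrixError(
                f"{self.label}: log-odds score is undefined for gap pairs "
                f"({a!r}, {b!r})"
            )
        try:
            return float(self.scores[self._index[a], self._index[b]])
        except KeyError:
            missing = a if a not in self._index else b
            if lenient:
                logger.warning(
                    "%s: residue %r not in alphabet; scoring 0", self.label, missing
                )
                return 0.0
            raise MatrixError(
                f"{self.label}: residue {missing!r} not in matrix alphabet"
            )

    def conservation_call(self, a: str, b: str, *, lenient: bool = False) -> Conservation:
        """Classify the (a, b) substitution by the sign of its score."""
        s = self.lookup(a, b, lenient=lenient)
        if s > 0:
            return Conservation.CONSERVATIVE
        if s < 0:
            return Conservation.NON_CONSERVATIVE
        return Conservation.NEUTRAL

    def to_text(self) -> str:
        """Render in the NCBI flat format accepted by :func:`parse_matrix_text`."""
        lines = [f"# {self.label}", "  " + "  ".join(self.alphabet)]
        for code, row in zip(self.alphabet, self.scores):
            cells = " ".join(f"{v:3g}" for v in row)
            lines.append(f"{code} {cells}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class FrequencyModel:
    """Observed pair frequencies q, background frequencies p and scale lambda."""

    alphabet: Tuple[str, ...]
    pair_frequencies: np.ndarray  # q_ij, symmetric, entries in (0, 1]
    background: np.ndarray  # p_i, entries in (0, 1]
    scale: float  # lambda > 0

    def __post_init__(self) -> None:
        q = np.asarray(self.pair_frequencies, dtype=float)
        p = np.asarray(self.background, dtype=float)
        k = len(self.alphabet)
        if q.shape != (k, k) or p.shape != (k,):
            raise MatrixError("frequency model: shape mismatch with alphabet")
        if self.scale <= 0:
            raise MatrixError("frequency model: lambda must be positive")
        if np.any(q <= 0) or np.any(q > 1) or np.any(p <= 0) or np.any(p > 1):
            raise MatrixError("frequency model: probabilities must lie in (0, 1]")
        if np.max(np.abs(q - q.T)) > SYMMETRY_TOL:
            raise MatrixError("frequency model: q must be symmetric")
        object.__setattr__(self, "pair_frequencies", q)
        object.__setattr__(self, "background", p)


@dataclass(frozen=True)
class MatrixConfig:
    """One matrix bound to affine gap penalties under a display label."""

    matrix: SubstitutionMatrix
    gap_open: float
    gap_extend: float
    label: str

    def __post_init__(self) -> None:
        # Penalties are non-positive and *added* to the score; a run of
        # length L costs gap_open + L * gap_extend.
        for name in ("gap_open", "gap_extend"):
            value = getattr(self, name)
            if value > 0:
                logger.warning(
                    "%s: %s %.3g is positive; negating (penalties are added)",
                    self.label,
                    name,
                    value,
                )
                object.__setattr__(self, name, -value)

    def gap_cost(self, length: int) -> float:
        """Affine cost of a gap run: the first position pays open + extend."""
        if length <= 0:
            return 0.0
        return self.gap_open + length * self.gap_extend


def load_predefined(name: str) -> SubstitutionMatrix:
    """Load one of the ten bundled PAM/BLOSUM matrices by name."""
    key = name.upper()
    if key not in PREDEFINED_MATRICES:
        raise MatrixError(
            f"unknown predefined matrix {name!r}; available: "
            + ", ".join(PREDEFINED_MATRICES)
        )
    text = (resources.files("pairsub") / "data" / f"{key}.txt").read_text("utf-8")
    return parse_matrix_text(text, key)


def parse_matrix_text(
    text: str, label: str, *, symmetrize: bool = False
) -> SubstitutionMatrix:
    """Parse a space-delimited substitution matrix (NCBI flat layout).

    The first non-comment row is the column alphabet; each following row
    starts with its residue label.  ``#`` lines are comments.  Real-valued
    cells are accepted.
    """
    lines = [
        ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise MatrixParseError(f"{label}: no matrix content")
    alphabet = lines[0].split()
    for code in alphabet:
        if len(code) != 1:
            raise MatrixParseError(
                f"{label}: header entry {code!r} is not a single residue code"
            )
    k = len(alphabet)
    rows = lines[1:]
    if len(rows) != k:
        raise MatrixParseError(
            f"{label}: non-square table: {k} columns but {len(rows)} rows"
        )
    scores = np.zeros((k, k), dtype=float)
    col_of = {c: i for i, c in enumerate(alphabet)}
    seen = set()
    for row_no, line in enumerate(rows, start=1):
        tokens = line.split()
        row_label = tokens[0]
        if row_label not in col_of:
            raise MatrixParseError(
                f"{label}: row {row_no} label {row_label!r} not in column header"
            )
        if row_label in seen:
            raise MatrixParseError(f"{label}: duplicate row {row_label!r}")
        seen.add(row_label)
        cells = tokens[1:]
        if len(cells) != k:
            raise MatrixParseError(
                f"{label}: row {row_label!r} has {len(cells)} cells, expected {k}"
            )
        for col, cell in enumerate(cells):
            try:
                scores[col_of[row_label], col] = float(cell)
            except ValueError:
                raise MatrixParseError(
                    f"{label}: non-numeric cell {cell!r} at row {row_label!r}, "
                    f"column {alphabet[col]!r}"
                )
    return SubstitutionMatrix(label, alphabet, scores, symmetrize=symmetrize)


def load_matrix_file(
    path: Union[str, "os.PathLike[str]"], label: str | None = None
) -> SubstitutionMatrix:
    path = Path(path)
    if not path.is_file():
        raise MasterFileError(f"custom matrix file not found: {path}")
    return parse_matrix_text(path.read_text("utf-8"), label or path.stem)


def parse_master_file(path: Union[str, "os.PathLike[str]"]) -> List[MatrixConfig]:
    """Parse a custom-matrix master file into labelled configs.

    Each non-empty line holds a matrix filename followed by space-delimited
    gap and extension penalties; filenames resolve relative to the master
    file's directory and may repeat with different penalties.  Configs are
    labelled ``CM0``, ``CM1``, ... in file order.
    """
    master = Path(path)
    if not master.is_file():
        raise MasterFileError(
            "custom matrix option is enabled but the master file "
            f"{master} does not exist"
        )
    configs: List[MatrixConfig] = []
    for line_no, line in enumerate(master.read_text("utf-8").splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        tokens = stripped.split()
        filename = tokens[0]
        if len(tokens) < 3:
            raise MasterFileError(
                f"{master}:{line_no}: missing penalties for {filename!r} "
                "(expected: filename gap_penalty extension_penalty)"
            )
        if len(tokens) > 3:
            raise MasterFileError(
                f"{master}:{line_no}: too many fields ({len(tokens)}); "
                "expected filename and two penalties"
            )
        try:
            gap_open, gap_extend = float(tokens[1]), float(tokens[2])
        except ValueError:
            raise MasterFileError(
                f"{master}:{line_no}: non-numeric penalty in {tokens[1:]!r}"
            )
        matrix = load_matrix_file(master.parent / filename)
        label = f"CM{len(configs)}"
        configs.append(
            MatrixConfig(
                matrix=matrix, gap_open=gap_open, gap_extend=gap_extend, label=label
            )
        )
    if not configs:
        logger.warning("master file %s lists no matrices", master)
    return configs


def log_odds_from_frequencies(
    model: FrequencyModel, label: str = "custom"
) -> SubstitutionMatrix:
    """Build the log-odds matrix s_ij = ln(q_ij / (p_i p_j)) / lambda."""
    p = model.background
    with np.errstate(divide="raise"):
        expected = np.outer(p, p)
        scores = np.log(model.pair_frequencies / expected) / model.scale
    return SubstitutionMatrix(label, model.alphabet, scores)


def recover_pair_frequencies(matrix: SubstitutionMatrix, model: FrequencyModel) -> np.ndarray:
    """Invert the log-odds construction: q_ij = exp(lambda * s_ij) * p_i * p_j."""
    p = model.background
    return np.exp(model.scale * matrix.scores) * np.outer(p, p)


# Module-level wrappers matching the functional interface.

def lookup(matrix: SubstitutionMatrix, a: str, b: str, *, lenient: bool = False) -> float:
    return matrix.lookup(a, b, lenient=lenient)


def conservation_call(
    matrix: SubstitutionMatrix, a: str, b: str, *, lenient: bool = False
) -> Conservation:
    return matrix.conservation_call(a, b, lenient=lenient)


def _fmt_num(x: float) -> str:
    return f"{x:g}"


def parse_predefined_spec(spec: str) -> List[MatrixConfig]:
    """Parse the CLI syntax ``NAME:open:extend[,NAME:open:extend...]``."""
    configs: List[MatrixConfig] = []
    for chunk in spec.split(","):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(":")
        if len(parts) != 3:
            raise MatrixError(
                f"bad predefined spec {chunk!r}; expected NAME:gap_open:gap_extend"
            )
        name = parts[0]
        matrix = load_predefined(name)
        try:
            gap_open, gap_extend = float(parts[1]), float(parts[2])
        except ValueError:
            raise MatrixError(f"bad penalty in predefined spec {chunk!r}")
        label = name.upper()
        if any(c.label == label for c in configs):
            label = f"{label}({_fmt_num(gap_open)},{_fmt_num(gap_extend)})"
        configs.append(
            MatrixConfig(matrix=matrix, gap_open=gap_open, gap_extend=gap_extend, label=label)
        )
    if not configs:
        raise MatrixError(f"no matrix configs in spec {spec!r}")
    return configs
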