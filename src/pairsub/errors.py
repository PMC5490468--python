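"""Exception hierarchy.

Input/validation problems map to CLI exit code 2, alignment failures to 3.
"""


class PairsubError(Exception):
    """Base class for all package errors."""


class InputError(PairsubError):
    """Invalid user input (sequences, matrices, options). CLI exit code 2."""


class MissingSequenceError(InputError):
    """FASTA source contains no records."""


class FastaParseError(InputError):
    """Malformed FASTA record; message names the offending line."""


class ResidueValidationError(InputError):
    """Sequence contains a disallowed character."""


class IdenticalSequencesError(InputError):
    """Pattern and subject are identical (override with allow_identical)."""


class MatrixError(InputError):
    """Substitution matrix problem (unknown name, bad file, bad lookup)."""


class MatrixParseError(MatrixError):
    """Custom matrix text could not be parsed; message carries row/column context."""


class MasterFileError(MatrixError):
    """Custom-matrix master file problem (missing penalties, missing file)."""


class AlignmentError(PairsubError):
    """Pairwise alignment failed. CLI exit code 3."""


class ReportError(PairsubError):
    """Report assembly or serialization failed."""
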