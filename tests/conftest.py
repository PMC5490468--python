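import numpy as np
import pytest

from pairsub.align import Alignment, AlignmentMode
from pairsub.matrices import MatrixConfig, SubstitutionMatrix, load_predefined


def make_uniform_matrix(alphabet="ACDE", match=1.0, mismatch=-1.0, label="TOY"):
    k = len(alphabet)
    scores = np.full((k, k), float(mismatch))
    np.fill_diagonal(scores, float(match))
    return SubstitutionMatrix(label, alphabet, scores)


def make_config(matrix, gap_open=-2.0, gap_extend=-1.0, label="CFG"):
    return MatrixConfig(matrix=matrix, gap_open=gap_open, gap_extend=gap_extend, label=label)


def make_alignment(aligned_pattern, aligned_subject, *, pattern_length=None,
                   subject_length=None, mode=AlignmentMode.GLOBAL, score=0.0,
                   label="TEST"):
    """Build an Alignment directly from gapped strings (full-span ranges)."""
    np_len = sum(1 for c in aligned_pattern if c != "-")
    ns_len = sum(1 for c in aligned_subject if c != "-")
    return Alignment(
        aligned_pattern=aligned_pattern,
        aligned_subject=aligned_subject,
        score=score,
        mode=mode,
        config_label=label,
        pattern_range=(1, np_len) if np_len else None,
        subject_range=(1, ns_len) if ns_len else None,
        pattern_length=pattern_length if pattern_length is not None else np_len,
        subject_length=subject_length if subject_length is not None else ns_len,
    )


@pytest.fixture(scope="session")
def blosum62():
    return load_predefined("BLOSUM62")


@pytest.fixture
def toy_matrix():
    return make_uniform_matrix()


@pytest.fixture
def toy_config(toy_matrix):
    return make_config(toy_matrix)
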