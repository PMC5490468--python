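"""Deterministic generators of synthetic test inputs.

All randomness flows through one numpy ``default_rng`` stream derived from
``FixtureSpec.seed``, so every generated object is reproducible from the
spec alone.  Generated matrices always satisfy the validation rules of the
matrices module (symmetric, positive diagonal).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Tuple

import numpy as np

from .align import Alignment, AlignmentMode
from .errors import InputError
from .matrices import SubstitutionMatrix
from .seqio import STANDARD_RESIDUES, ProteinSequence


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    lengths: Tuple[int, int] = (5, 30)
    alphabet: str = STANDARD_RESIDUES
    mutation_rate: float = 0.1
    indel_rate: float = 0.05
    matrix_value_range: Tuple[int, int] = (-6, 8)

    def __post_init__(self) -> None:
        lo, hi = self.lengths
        if not (1 <= lo <= hi):
            raise InputError(f"invalid length range {self.lengths}")
        if not self.alphabet:
            raise InputError("alphabet must be non-empty")
        for name in ("mutation_rate", "indel_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise InputError(f"{name} must lie in [0, 1], got {rate}")
        vlo, vhi = self.matrix_value_range
        if vlo > vhi:
            raise InputError(f"invalid matrix value range {self.matrix_value_range}")

    @classmethod
    def from_mapping(cls, data: dict) -> "FixtureSpec":
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in data.items() if k in known}
        for key in ("lengths", "matrix_value_range"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_json(cls, path) -> "FixtureSpec":
        return cls.from_mapping(json.loads(Path(path).read_text("utf-8")))


def _rng(spec: FixtureSpec, rng: Optional[np.random.Generator]) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(spec.seed)


def random_sequence(
    spec: FixtureSpec,
    rng: Optional[np.random.Generator] = None,
    seq_id: str = "random",
) -> ProteinSequence:
    rng = _rng(spec, rng)
    lo, hi = spec.lengths
    length = int(rng.integers(lo, hi + 1))
    letters = rng.choice(list(spec.alphabet), size=length)
    return ProteinSequence(id=seq_id, residues="".join(letters))


def mutate_pair(
    seq: ProteinSequence,
    spec: FixtureSpec,
    rng: Optional[np.random.Generator] = None,
) -> ProteinSequence:
    """Derive a mutant: per-position substitutions at ``mutation_rate`` and
    deletions/insertions at ``indel_rate``.  Zero rates return an identical
    copy.  Substitutions always pick a *different* residue when the alphabet
    allows it."""
    rng = _rng(spec, rng)
    alphabet = spec.alphabet
    out = []
    for ch in seq.residues:
        if spec.indel_rate and rng.random() < spec.indel_rate:
            pass  # deletion
        elif spec.mutation_rate and rng.random() < spec.mutation_rate:
            others = [c for c in alphabet if c != ch]
            out.append(str(rng.choice(others)) if others else ch)
        else:
            out.append(ch)
        if spec.indel_rate and rng.random() < spec.indel_rate:
            out.append(str(rng.choice(list(alphabet))))  # insertion
    if not out:  # guarantee a valid (non-empty) sequence
        out.append(str(rng.choice(list(alphabet))))
    return ProteinSequence(id=f"{seq.id}_mut", residues="".join(out))


def random_matrix(
    spec: FixtureSpec,
    rng: Optional[np.random.Generator] = None,
    label: str = "RANDOM",
) -> SubstitutionMatrix:
    """A random symmetric integer matrix with positive diagonal.

    Diagonal entries are drawn from the intersection of the value range with
    [1, inf); if the range is entirely negative they are clamped to 1.
    """
    rng = _rng(spec, rng)
    alphabet = spec.alphabet
    k = len(alphabet)
    lo, hi = spec.matrix_value_range
    values = rng.integers(lo, hi + 1, size=(k, k)).astype(float)
    scores = np.triu(values) + np.triu(values, 1).T  # mirror upper triangle
    diag_lo = max(lo, 1)
    if diag_lo > hi:
        diag = np.ones(k)
    else:
        diag = rng.integers(diag_lo, hi + 1, size=k).astype(float)
    np.fill_diagonal(scores, diag)
    return SubstitutionMatrix(label, alphabet, scores)


def random_alignment(
    spec: FixtureSpec,
    rng: Optional[np.random.Generator] = None,
    config_label: str = "FIXTURE",
) -> Alignment:
    """A structurally valid random alignment (for metric/search tests).

    Column kinds are drawn independently: gap in one aligned string with
    probability ``indel_rate`` each, otherwise a residue pair that is an
    identity with probability ``1 - mutation_rate``.  The first column is
    always a residue pair so both ranges are non-empty.
    """
    rng = _rng(spec, rng)
    lo, hi = spec.lengths
    n_cols = int(rng.integers(lo, hi + 1))
    letters = list(spec.alphabet)
    pat, sub = [], []
    for idx in range(n_cols):
        r = rng.random()
        if idx > 0 and r < spec.indel_rate:
            pat.append("-")
            sub.append(str(rng.choice(letters)))
        elif idx > 0 and r < 2 * spec.indel_rate:
            pat.append(str(rng.choice(letters)))
            sub.append("-")
        else:
            a = str(rng.choice(letters))
            if rng.random() < spec.mutation_rate:
                others = [c for c in letters if c != a]
                b = str(rng.choice(others)) if others else a
            else:
                b = a
            pat.append(a)
            sub.append(b)
    aligned_pattern = "".join(pat)
    aligned_subject = "".join(sub)
    np_len = sum(1 for c in aligned_pattern if c != "-")
    ns_len = sum(1 for c in aligned_subject if c != "-")
    return Alignment(
        aligned_pattern=aligned_pattern,
        aligned_subject=aligned_subject,
        score=0.0,
        mode=AlignmentMode.GLOBAL,
        config_label=config_label,
        pattern_range=(1, np_len),
        subject_range=(1, ns_len),
        pattern_length=np_len,
        subject_length=ns_len,
    )


def with_seed(spec: FixtureSpec, seed: int) -> FixtureSpec:
    return replace(spec, seed=seed)
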