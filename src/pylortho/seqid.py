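"""Aligned sequence sets and pairwise percent-identity matrices.

The orthogonality analysis starts from multiple sequence alignments: one of
synthetase catalytic domains (protein) and one of tRNAs (nucleotide, aligned
by secondary structure upstream of this package).  This module parses aligned
FASTA, computes pairwise percent identity over the shared column space, and
extracts catalytic-domain sub-alignments defined by a window on a reference
sequence.

Percent-identity convention
---------------------------
The default convention, ``coverage``, scores a column when at least one of
the two sequences carries a residue there; two equal non-gap, non-ambiguous
residues count as a match, a residue opposite a gap counts as a mismatch,
and columns where both sequences are gapped are excluded from the
denominator.  Because published identity figures rarely state their
convention, two alternatives are available:

``aligned``
    only columns where *both* sequences carry a residue are scored;
``columns``
    every alignment column is scored (both-gap columns count as mismatches).

Ambiguity characters (``X`` for protein, ``N`` for nucleotide) never count
as matches under any convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import (
    AlignmentShapeError,
    DuplicateIdError,
    EmptyInputError,
    InsufficientInputError,
    InvalidMatrixError,
    MissingReferenceError,
    UndefinedIdentityError,
    WindowRangeError,
)

Alphabet = Literal["protein", "nucleotide"]

GAP = "-"
_AMBIGUOUS = {"protein": "X", "nucleotide": "N"}

IdentityConvention = Literal["coverage", "aligned", "columns"]


@dataclass(frozen=True)
class AlignedSequenceSet:
    """Named gapped sequences over a shared column space.

    Use :func:`aligned_set` or :func:`read_aligned_fasta` to construct one;
    both normalise case and gap characters and drop all-gap columns.
    """

    ids: tuple[str, ...]
    residues: tuple[str, ...]
    alphabet: Alphabet

    @property
    def column_count(self) -> int:
        return len(self.residues[0]) if self.residues else 0

    def __len__(self) -> int:
        return len(self.ids)

    def sequence(self, seq_id: str) -> str:
        try:
            return self.residues[self.ids.index(seq_id)]
        except ValueError:
            raise MissingReferenceError(f"no sequence with id {seq_id!r}")

    def subset(self, keep: Sequence[str]) -> "AlignedSequenceSet":
        """Restrict to the given ids, preserving the column space."""
        rows = [(i, self.sequence(i)) for i in keep]
        return AlignedSequenceSet(
            ids=tuple(i for i, _ in rows),
            residues=tuple(r for _, r in rows),
            alphabet=self.alphabet,
        )


def aligned_set(
    records: Iterable[tuple[str, str]], alphabet: Alphabet
) -> AlignedSequenceSet:
    """Build an :class:`AlignedSequenceSet` from ``(id, gapped_sequence)`` pairs.

    Sequences are upper-cased, ``.`` gaps become ``-``, and columns that are
    gaps in every record are dropped.
    """
    ids: list[str] = []
    seqs: list[str] = []
    for seq_id, seq in records:
        if not seq_id:
            raise DuplicateIdError("empty sequence id")
        if seq_id in ids:
            raise DuplicateIdError(f"duplicate sequence id {seq_id!r}")
        ids.append(seq_id)
        seqs.append(seq.upper().replace(".", GAP))
    if not ids:
        raise EmptyInputError("no sequences")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise AlignmentShapeError(
            f"sequences have unequal lengths: {sorted(lengths)}"
        )
    arr = np.array([list(s) for s in seqs], dtype="U1")
    keep = ~(arr == GAP).all(axis=0)
    arr = arr[:, keep]
    return AlignedSequenceSet(
        ids=tuple(ids),
        residues=tuple("".join(row) for row in arr),
        alphabet=alphabet,
    )


def read_aligned_fasta(path: str | Path, alphabet: Alphabet) -> AlignedSequenceSet:
    """Parse an aligned FASTA file into an :class:`AlignedSequenceSet`."""
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    return aligned_set(records, alphabet)


def percent_identity(
    a: str,
    b: str,
    alphabet: Alphabet = "protein",
    convention: IdentityConvention = "coverage",
) -> float:
    """Percent identity between two equal-length gapped sequences.

    See the module docstring for the scoring conventions.  Raises
    :class:`UndefinedIdentityError` when the denominator is empty (e.g. both
    sequences all-gap under the default convention).
    """
    if len(a) != len(b):
        raise AlignmentShapeError(
            f"sequence lengths differ: {len(a)} vs {len(b)}"
        )
    a = a.upper().replace(".", GAP)
    b = b.upper().replace(".", GAP)
    xa = np.frombuffer(a.encode("ascii"), dtype="S1")
    xb = np.frombuffer(b.encode("ascii"), dtype="S1")
    gap = GAP.encode("ascii")
    amb = _AMBIGUOUS[alphabet].encode("ascii")
    res_a = xa != gap
    res_b = xb != gap
    if convention == "coverage":
        scored = res_a | res_b
    elif convention == "aligned":
        scored = res_a & res_b
    elif convention == "columns":
        scored = np.ones(len(xa), dtype=bool)
    else:  # pragma: no cover - guarded by Literal type
        raise ValueError(f"unknown convention {convention!r}")
    denom = int(scored.sum())
    if denom == 0:
        raise UndefinedIdentityError(
            "no scored columns (both sequences gapped everywhere?)"
        )
    matches = int((scored & res_a & res_b & (xa == xb) & (xa != amb)).sum())
    return 100.0 * matches / denom


@dataclass(frozen=True)
class IdentityMatrix:
    """Symmetric pairwise percent-identity table over named sequences."""

    ids: tuple[str, ...]
    values: np.ndarray  # square, percent in [0, 100]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise InvalidMatrixError(f"expected {n}x{n} matrix, got {v.shape}")
        if not np.allclose(v, v.T, atol=1e-9):
            raise InvalidMatrixError("identity matrix is not symmetric")
        if np.nanmin(v) < -1e-9 or np.nanmax(v) > 100 + 1e-9:
            raise InvalidMatrixError("identity values outside [0, 100]")
        object.__setattr__(self, "values", v)

    def value(self, i: str, j: str) -> float:
        return float(self.values[self.ids.index(i), self.ids.index(j)])

    def subset(self, keep: Sequence[str]) -> "IdentityMatrix":
        idx = [self.ids.index(i) for i in keep]
        return IdentityMatrix(tuple(keep), self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().round(2).to_csv(path, sep="\t", float_format="%.2f")

    def write_json(self, path: str | Path) -> None:
        payload = {
            "ids": list(self.ids),
            "values": [[round(float(x), 6) for x in row] for row in self.values],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "IdentityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise InvalidMatrixError("row and column ids differ")
        return cls(tuple(str(i) for i in df.index), df.to_numpy(dtype=float))


def identity_matrix(
    aln: AlignedSequenceSet, convention: IdentityConvention = "coverage"
) -> IdentityMatrix:
    """All-pairs percent identity for an alignment.

    Vectorised over columns; requires at least two sequences and no all-gap
    records (drop those before calling).
    """
    n = len(aln)
    if n < 2:
        raise InsufficientInputError("identity matrix needs >= 2 sequences")
    arr = np.array([list(s) for s in aln.residues], dtype="U1")
    gapmask = arr == GAP
    if gapmask.all(axis=1).any():
        bad = [aln.ids[i] for i in np.nonzero(gapmask.all(axis=1))[0]]
        raise UndefinedIdentityError(
            f"all-gap records have undefined self-identity: {bad}"
        )
    if arr.shape[1] == 0:
        raise UndefinedIdentityError("alignment has no columns")
    amb = _AMBIGUOUS[aln.alphabet]
    res = ~gapmask
    vals = np.full((n, n), 100.0)
    for i in range(n - 1):
        rest = slice(i + 1, n)
        matches = ((arr[i] == arr[rest]) & res[i] & res[rest] & (arr[i] != amb)).sum(
            axis=1
        )
        if convention == "coverage":
            scored = (res[i] | res[rest]).sum(axis=1)
        elif convention == "aligned":
            scored = (res[i] & res[rest]).sum(axis=1)
        else:
            scored = np.full(n - i - 1, arr.shape[1])
        if (scored == 0).any():
            raise UndefinedIdentityError("pair with no scored columns")
        row = 100.0 * matches / scored
        vals[i, rest] = row
        vals[rest, i] = row
    return IdentityMatrix(aln.ids, vals)


@dataclass(frozen=True)
class DomainWindow:
    """1-based inclusive residue window on a named reference sequence."""

    reference_id: str
    start: int
    end: int

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise WindowRangeError(
                f"invalid window ({self.start}, {self.end}): need 1 <= start <= end"
            )


def extract_domain(
    aln: AlignedSequenceSet, window: DomainWindow
) -> AlignedSequenceSet:
    """Restrict an alignment to the columns spanned by a reference window.

    The window is expressed in ungapped residue coordinates of the reference
    sequence; the returned sub-alignment covers every alignment column from
    the reference's ``start``-th to ``end``-th residue inclusive (including
    internal gap columns).  Rows that become all-gap are retained; columns
    that become all-gap are dropped.
    """
    ref = aln.sequence(window.reference_id)
    residue_cols = [k for k, ch in enumerate(ref) if ch != GAP]
    if window.end > len(residue_cols):
        raise WindowRangeError(
            f"window end {window.end} exceeds reference ungapped length "
            f"{len(residue_cols)}"
        )
    lo = residue_cols[window.start - 1]
    hi = residue_cols[window.end - 1]
    arr = np.array([list(s) for s in aln.residues], dtype="U1")[:, lo : hi + 1]
    keep = ~(arr == GAP).all(axis=0)
    arr = arr[:, keep]
    return AlignedSequenceSet(
        ids=aln.ids,
        residues=tuple("".join(row) for row in arr),
        alphabet=aln.alphabet,
    )
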