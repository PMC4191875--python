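"""Alignment reading, 21-state encoding, reweighting and gap-run bookkeeping.

A multiple sequence alignment (MSA) is encoded over the alphabet
``{gap} + 20 amino acids``: the gap state is 0 and the canonical amino
acids are mapped to 1..20 in alphabetical one-letter order
(``ACDEFGHIKLMNPQRSTVWY``).  All column indices that leave this module
(gap runs, reports) are 1-based; raw numpy arrays are indexed 0-based as
usual.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, List, Sequence

import numpy as np
from Bio import SeqIO, AlignIO

#: canonical one-letter amino-acid order; state = 1-based index in this string
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
#: integer state reserved for the alignment gap
GAP_STATE = 0
#: alphabet size: 20 amino acids + gap
Q = 21

_GAP_CHARS = frozenset("-.")
_AMBIGUOUS = frozenset("BZXJUO")
_AA_TO_STATE = {c: i + 1 for i, c in enumerate(AA_ALPHABET)}
_STATE_TO_CHAR = "-" + AA_ALPHABET


class AlignmentError(ValueError):
    """Base class for alignment input problems."""


class MalformedAlignmentError(AlignmentError):
    """Rows of unequal length, or otherwise not a rectangular alignment."""


class EmptyInputError(AlignmentError):
    """The input contained no sequences."""


class EncodingError(AlignmentError):
    """A residue character outside the handled alphabet."""


@dataclass
class Alignment:
    """A rectangular character-level MSA.

    ``rows`` are equal-length uppercase strings over the amino-acid
    alphabet, gap characters ('-', '.') and ambiguity codes.
    """

    ids: List[str]
    rows: List[str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise EmptyInputError("alignment has no sequences")
        n = len(self.rows[0])
        for k, row in enumerate(self.rows):
            if len(row) != n:
                raise MalformedAlignmentError(
                    f"row {k + 1} has length {len(row)}, expected {n}"
                )

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def n_sequences(self) -> int:
        return len(self.rows)


@dataclass
class EncodedMSA:
    """Integer-encoded MSA with per-sequence weights.

    ``data`` is a ``(B, N)`` integer matrix with entries in ``[0, q-1]``,
    0 being the gap state.  ``weights`` are the reweighting factors of the
    sequences (all 1 until :func:`compute_weights` is applied); their sum
    is the effective number of sequences ``b_eff``.
    """

    data: np.ndarray
    weights: np.ndarray = None  # type: ignore[assignment]
    q: int = Q
    ids: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.ndim != 2:
            raise MalformedAlignmentError("encoded MSA must be a 2-D matrix")
        if self.weights is None:
            self.weights = np.ones(self.data.shape[0])
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.data.shape[0],):
            raise ValueError("weights must have one entry per sequence")
        if self.data.size and (self.data.min() < 0 or self.data.max() >= self.q):
            raise EncodingError(f"states must lie in [0, {self.q - 1}]")

    @property
    def n_sequences(self) -> int:
        return self.data.shape[0]

    @property
    def n_columns(self) -> int:
        return self.data.shape[1]

    @property
    def b_eff(self) -> float:
        return float(self.weights.sum())


@dataclass(frozen=True, order=True)
class GapRun:
    """A maximal run of gap states; ``start`` is a 1-based column index."""

    start: int
    length: int


def read_alignment(path, fmt: str = "fasta") -> Alignment:
    """Read an aligned FASTA or Stockholm file.

    For Stockholm, insert-state columns (lowercase residues and '.') are
    removed per sequence, leaving the match columns; '-' gaps are kept.
    """
    if fmt == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise EmptyInputError(f"no sequences found in {path}")
        ids = [r.id for r in records]
        rows = [str(r.seq).upper() for r in records]
    elif fmt == "stockholm":
        try:
            aln = AlignIO.read(str(path), "stockholm")
        except ValueError as exc:
            raise EmptyInputError(f"could not read Stockholm file {path}: {exc}") from exc
        ids = [r.id for r in aln]
        raw = [str(r.seq) for r in aln]
        # insert-state columns carry lowercase residues (their '.' padding
        # is normalized to '-' by the parser, so detect per column)
        is_insert = [any(row[c].islower() for row in raw)
                     for c in range(aln.get_alignment_length())]
        rows = [
            "".join(ch for ch, ins in zip(row, is_insert) if not ins).upper()
            for row in raw
        ]
    else:
        raise ValueError(f"unknown alignment format: {fmt!r}")
    return Alignment(ids=ids, rows=rows)


def encode_msa(aln: Alignment, ambiguous_as_gap: bool = True) -> EncodedMSA:
    """Encode an alignment over the 21-state alphabet (weights all 1).

    Gap characters map to state 0; canonical amino acids to 1..20 in
    alphabetical order; ambiguity codes (B, J, O, U, X, Z) map to the gap
    state by default, which is the common DCA convention.
    """
    B, N = aln.n_sequences, aln.n_columns
    data = np.zeros((B, N), dtype=np.int8)
    for s, row in enumerate(aln.rows):
        for c, ch in enumerate(row):
            state = _AA_TO_STATE.get(ch)
            if state is not None:
                data[s, c] = state
            elif ch in _GAP_CHARS:
                data[s, c] = GAP_STATE
            elif ch in _AMBIGUOUS:
                if not ambiguous_as_gap:
                    raise EncodingError(
                        f"ambiguity code {ch!r} at row {s + 1}, column {c + 1}"
                    )
                data[s, c] = GAP_STATE
            else:
                raise EncodingError(
                    f"unhandled character {ch!r} at row {s + 1}, column {c + 1}"
                )
    return EncodedMSA(data=data, ids=list(aln.ids))


def decode_row(row: Sequence[int]) -> str:
    """Inverse of the encoding for canonical states (gap rendered as '-')."""
    return "".join(_STATE_TO_CHAR[int(a)] for a in row)


def sequence_identity(x: Sequence[int], y: Sequence[int]) -> float:
    """Fraction of positions at which two encoded rows agree.

    The gap state counts as an ordinary 21st state, so gap-gap matches
    are matches.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    return float(np.mean(x == y))


def compute_weights(msa: EncodedMSA, threshold_x: float = 0.1) -> EncodedMSA:
    """Sequence reweighting against sampling bias in the alignment.

    Each sequence ``s`` receives weight ``1 / n_s`` where ``n_s`` is the
    number of sequences (itself included) whose identity with ``s`` is at
    least ``1 - threshold_x``; the default 0.1 downweights clusters of
    sequences more than 90% identical.  Returns a new :class:`EncodedMSA`
    with the weights set.
    """
    if not 0.0 < threshold_x < 1.0:
        raise ValueError(f"threshold_x must lie in (0, 1), got {threshold_x}")
    data = msa.data
    B, N = data.shape
    if B == 0:
        raise EmptyInputError("cannot reweight an empty MSA")
    # matches >= (1-x)*N, robust to float fuzz on the product
    min_matches = (1.0 - threshold_x) * N - 1e-9
    n_neighbors = np.zeros(B, dtype=np.int64)
    chunk = max(1, int(4e7) // max(B * N, 1))
    for lo in range(0, B, chunk):
        hi = min(lo + chunk, B)
        counts = (data[lo:hi, None, :] == data[None, :, :]).sum(axis=2)
        n_neighbors[lo:hi] = (counts >= min_matches).sum(axis=1)
    weights = 1.0 / n_neighbors
    return replace(msa, weights=weights)


def find_gap_runs(row: Sequence[int]) -> List[GapRun]:
    """Maximal runs of the gap state in one encoded row, 1-based starts."""
    is_gap = np.asarray(row) == GAP_STATE
    if is_gap.ndim != 1:
        raise ValueError("row must be 1-D")
    padded = np.concatenate(([False], is_gap, [False]))
    delta = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(delta == 1)
    ends = np.flatnonzero(delta == -1)
    return [GapRun(start=int(s) + 1, length=int(e - s)) for s, e in zip(starts, ends)]


def max_gap_run_length(msa: EncodedMSA) -> int:
    """Largest maximal gap-run length found anywhere in the alignment."""
    best = 0
    for row in msa.data:
        for run in find_gap_runs(row):
            if run.length > best:
                best = run.length
    return best


def save_weights(msa: EncodedMSA, path) -> None:
    """Write sequence weights as two-column plain text (id, weight)."""
    ids = msa.ids if msa.ids else [f"seq_{k + 1}" for k in range(msa.n_sequences)]
    with open(path, "w") as fh:
        for sid, w in zip(ids, msa.weights):
            fh.write(f"{sid}\t{w:.10g}\n")


def msa_from_strings(rows: Iterable[str], ids: Iterable[str] | None = None) -> EncodedMSA:
    """Convenience constructor: encode in-memory aligned strings."""
    rows = list(rows)
    ids = list(ids) if ids is not None else [f"seq_{k + 1}" for k in range(len(rows))]
    return encode_msa(Alignment(ids=ids, rows=[r.upper() for r in rows]))
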