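"""Coupling-strength scoring: Frobenius norms, APC, ranking, decimation.

Gauge-fixed coupling blocks are condensed to one score per column pair:
``FN_ij = ||J_ij||_F`` over the full 21x21 block (``fn21``) or over its
20x20 amino-acid submatrix with the gap row/column discarded *after*
gauge fixing (``fn20``, the plmDCA20 scoring).  The Average Product
Correction (APC) subtracts the background ``FN_i. * FN_.j / FN_..``
estimated from the score matrix itself, suppressing conservation and
phylogeny bias before pairs are ranked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .alignment import EncodedMSA
from .plm import (FitResult, OptimizerSettings, RegularizationConfig,
                  fit_model)

VARIANTS = ("fn21", "fn20")


@dataclass
class ScoreMatrix:
    """Symmetric per-pair score matrix; the diagonal is meaningless."""

    values: np.ndarray
    variant: str
    apc_applied: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]


@dataclass
class RankedContacts:
    """Separation-filtered pairs in descending score order, 1-based indices."""

    pairs: List[Tuple[int, int, float]]
    min_separation: int = 5

    def top(self, n: int) -> List[Tuple[int, int, float]]:
        return self.pairs[:n]

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


def frobenius_scores(fit: FitResult, variant: str = "fn21") -> ScoreMatrix:
    """Frobenius-norm score of every gauge-fixed pair block.

    ``fn20`` restricts the sum of squares to amino-acid states 1..20 of
    the *already gauge-fixed* block; the submatrix is not re-gauged.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    N = fit.n_sites
    values = np.zeros((N, N))
    couplings = fit.params.couplings
    for i in range(N):
        for j in range(i + 1, N):
            block = couplings.get((i, j))
            if block is None:
                raise KeyError(f"missing coupling block for pair ({i}, {j})")
            sub = block if variant == "fn21" else block[1:, 1:]
            v = float(np.sqrt((sub * sub).sum()))
            values[i, j] = values[j, i] = v
    return ScoreMatrix(values=values, variant=variant, apc_applied=False)


def apc_correct(fn: ScoreMatrix) -> ScoreMatrix:
    """Average Product Correction; means exclude the diagonal.

    ``CN_ij = FN_ij - mean_j'(FN_ij') * mean_i'(FN_i'j) / mean(FN)``.
    An all-zero input is returned unchanged (no division by zero).
    """
    if fn.apc_applied:
        raise ValueError("APC already applied to this score matrix")
    F = fn.values.copy()
    np.fill_diagonal(F, 0.0)
    N = F.shape[0]
    if N < 2:
        raise ValueError("APC needs at least two columns")
    row_mean = F.sum(axis=1) / (N - 1)
    total_mean = F.sum() / (N * (N - 1))
    if total_mean == 0.0:
        return ScoreMatrix(values=np.zeros_like(F), variant=fn.variant,
                           apc_applied=True)
    corrected = F - np.outer(row_mean, row_mean) / total_mean
    np.fill_diagonal(corrected, 0.0)
    return ScoreMatrix(values=corrected, variant=fn.variant, apc_applied=True)


def rank_contacts(scores: ScoreMatrix, min_separation: int = 5) -> RankedContacts:
    """Rank pairs ``(i, j)``, ``j - i >= min_separation``, by descending score.

    Ties are broken lexicographically on ``(i, j)`` so the ranking is a
    reproducible total order.  Output indices are 1-based.
    """
    V = scores.values
    if not np.all(np.isfinite(V[~np.eye(V.shape[0], dtype=bool)])):
        raise ValueError("score matrix has non-finite off-diagonal entries")
    N = V.shape[0]
    entries = [
        (i + 1, j + 1, float(V[i, j]))
        for i in range(N) for j in range(i + min_separation, N)
    ]
    entries.sort(key=lambda e: (-e[2], e[0], e[1]))
    return RankedContacts(pairs=entries, min_separation=min_separation)


def decimate_fit(msa: EncodedMSA, reg: Optional[RegularizationConfig] = None,
                 use_gaps: bool = False, rounds: int = 0,
                 fraction_per_round: float = 0.1,
                 settings: Optional[OptimizerSettings] = None,
                 n_jobs: int = 1,
                 variant: str = "fn21"
                 ) -> Tuple[FitResult, List[frozenset]]:
    """Iterative decimation: refit with the weakest couplings frozen at zero.

    Each round ranks the not-yet-masked pair blocks by their current APC
    score, masks the weakest ``floor(fraction * remaining)`` of them, and
    refits with masked blocks constrained to zero.  ``rounds=0``
    reproduces :func:`fit_model` exactly.  Returns the final fit and the
    cumulative mask after each round.
    """
    if rounds < 0:
        raise ValueError("rounds must be >= 0")
    if not 0.0 < fraction_per_round < 1.0:
        raise ValueError("fraction_per_round must lie in (0, 1)")
    masked: frozenset = frozenset()
    history: List[frozenset] = []
    fit = fit_model(msa, reg, use_gaps, settings, n_jobs=n_jobs)
    for _ in range(rounds):
        cn = apc_correct(frobenius_scores(fit, variant)).values
        N = cn.shape[0]
        remaining = [
            (i, j) for i in range(N) for j in range(i + 1, N)
            if (i, j) not in masked
        ]
        n_mask = int(np.floor(fraction_per_round * len(remaining)))
        remaining.sort(key=lambda p: (cn[p], p))
        masked = masked | frozenset(remaining[:n_mask])
        if len(masked) >= N * (N - 1) // 2:
            raise ValueError("decimation would mask every pair block")
        history.append(masked)
        fit = fit_model(msa, reg, use_gaps, settings, n_jobs=n_jobs,
                        masked_pairs=masked)
    return fit, history


def write_scores(ranked: RankedContacts, path, variant: str = "fn21",
                 apc: bool = True, model: str = "plmDCA") -> None:
    """Tab-separated score file: ``i<TAB>j<TAB>score``, 1-based, descending."""
    with open(path, "w") as fh:
        fh.write(f"# variant={variant} apc={apc} "
                 f"min_separation={ranked.min_separation} model={model}\n")
        for i, j, s in ranked:
            fh.write(f"{i}\t{j}\t{s:.10g}\n")


def read_scores(path) -> RankedContacts:
    """Read a score file written by :func:`write_scores`."""
    pairs: List[Tuple[int, int, float]] = []
    min_sep = 5
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for token in line[1:].split():
                    if token.startswith("min_separation="):
                        min_sep = int(token.split("=", 1)[1])
                continue
            i, j, s = line.split("\t")
            pairs.append((int(i), int(j), float(s)))
    return RankedContacts(pairs=pairs, min_separation=min_sep)
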