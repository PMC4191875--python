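"""Structural contact maps and positive-predictive-value evaluation.

Two residues are in contact under the C-beta criterion when their
C-beta atoms (C-alpha for glycine) are at most 8.0 A apart, and under
the heavy-atom criterion when any pair of their non-hydrogen atoms is at
most 8.5 A apart.  Predictions are scored by PPV (precision): the
number of true contacts among the top-n ranked pairs divided by n,
considering only pairs with sequence separation >= 5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from Bio.PDB import PDBParser

from .scoring import RankedContacts

CRITERIA = {"cbeta_8": 8.0, "heavy_8p5": 8.5}


@dataclass
class ContactMap:
    """Symmetric boolean contact matrix plus per-column resolution flags."""

    contacts: np.ndarray
    criterion: str
    resolved: np.ndarray

    def __post_init__(self) -> None:
        self.contacts = np.asarray(self.contacts, dtype=bool)
        self.resolved = np.asarray(self.resolved, dtype=bool)
        n = self.contacts.shape[0]
        if self.contacts.shape != (n, n):
            raise ValueError("contact matrix must be square")
        if self.resolved.shape != (n,):
            raise ValueError("resolved flags must match matrix size")

    @property
    def n_sites(self) -> int:
        return self.contacts.shape[0]


@dataclass
class PPVCurve:
    n_values: np.ndarray
    ppv: np.ndarray


class StructureError(ValueError):
    """Problems locating the requested chain/residues in a structure."""


def _residue_coords(residue, criterion: str) -> Optional[np.ndarray]:
    """Atom coordinates relevant to a criterion, or None if unusable.

    cbeta_8 uses the single C-beta atom (C-alpha for glycine);
    heavy_8p5 uses all non-hydrogen atoms.  Biopython's parser resolves
    alternate locations to the highest-occupancy conformer.
    """
    if criterion == "cbeta_8":
        name = "CA" if residue.get_resname().strip() == "GLY" else "CB"
        if name in residue:
            return np.asarray(residue[name].get_coord(), dtype=float)[None, :]
        return None
    coords = [
        atom.get_coord()
        for atom in residue.get_atoms()
        if (atom.element or "").strip().upper() not in ("H", "D")
    ]
    if not coords:
        return None
    return np.asarray(coords, dtype=float)


def contact_map_from_structure(path, chain_id: str, mapping: Dict[int, int],
                               criterion: str = "cbeta_8",
                               n_columns: Optional[int] = None) -> ContactMap:
    """Contact map of a PDB chain, mapped onto alignment columns.

    ``mapping`` sends 1-based alignment columns to residue sequence
    numbers of the chain; unmapped columns and mapped residues without
    usable coordinates are marked unresolved.  Only the first MODEL of a
    multi-model file is used.
    """
    if criterion not in CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}")
    if not mapping:
        raise StructureError("empty column-to-residue mapping")
    threshold = CRITERIA[criterion]
    model = PDBParser(QUIET=True).get_structure("s", str(path))[0]
    if chain_id not in model:
        raise StructureError(f"chain {chain_id!r} not found in {path}")
    chain = model[chain_id]
    by_resnum = {}
    for residue in chain:
        hetflag, resnum, _ = residue.get_id()
        if hetflag.strip() == "":
            by_resnum.setdefault(resnum, residue)

    N = n_columns if n_columns is not None else max(mapping)
    coords: List[Optional[np.ndarray]] = [None] * N
    for col, resnum in mapping.items():
        if not 1 <= col <= N:
            raise StructureError(f"mapped column {col} outside 1..{N}")
        residue = by_resnum.get(resnum)
        if residue is not None:
            coords[col - 1] = _residue_coords(residue, criterion)
    resolved = np.array([c is not None for c in coords])
    if not resolved.any():
        raise StructureError("no mapped residue has usable coordinates")

    contacts = np.zeros((N, N), dtype=bool)
    idx = np.flatnonzero(resolved)
    for a_pos, i in enumerate(idx):
        for j in idx[a_pos + 1:]:
            d = np.linalg.norm(coords[i][:, None, :] - coords[j][None, :, :],
                               axis=-1).min()
            if d <= threshold:
                contacts[i, j] = contacts[j, i] = True
    return ContactMap(contacts=contacts, criterion=criterion, resolved=resolved)


def _counted_predictions(pred: RankedContacts, truth: ContactMap
                         ) -> List[bool]:
    """Truth labels of predictions, skipping unresolved-residue pairs."""
    labels = []
    for i, j, _ in pred:
        if j > truth.n_sites:
            raise ValueError(
                f"prediction ({i}, {j}) outside contact map of size {truth.n_sites}"
            )
        if truth.resolved[i - 1] and truth.resolved[j - 1]:
            labels.append(bool(truth.contacts[i - 1, j - 1]))
    return labels


def ppv_curve(pred: RankedContacts, truth: ContactMap,
              mode: str = "absolute",
              fractions: Sequence[float] = tuple(np.arange(1, 11) / 10)
              ) -> PPVCurve:
    """Precision of the top-n predictions as a function of n.

    Pairs touching unresolved residues are skipped and do not consume
    rank positions.  ``absolute`` mode reports every n up to the number
    of counted predictions; ``relative`` mode reports n = ceil(f * N)
    over the given fraction grid (clipped to the available predictions).
    """
    labels = _counted_predictions(pred, truth)
    if not labels:
        return PPVCurve(n_values=np.array([], dtype=int), ppv=np.array([]))
    cum_tp = np.cumsum(labels)
    if mode == "absolute":
        n_values = np.arange(1, len(labels) + 1)
    elif mode == "relative":
        N = truth.n_sites
        n_values = np.unique([
            min(len(labels), max(1, math.ceil(f * N))) for f in fractions
        ])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return PPVCurve(n_values=n_values, ppv=cum_tp[n_values - 1] / n_values)


def ppv_at(pred: RankedContacts, truth: ContactMap, n: int) -> float:
    """PPV of the top-n counted predictions (top-``available`` if fewer)."""
    labels = _counted_predictions(pred, truth)
    n_used = min(n, len(labels))
    if n_used == 0:
        return float("nan")
    return float(np.sum(labels[:n_used]) / n_used)


def mean_ppv_at(pred_set: Sequence[Tuple[RankedContacts, ContactMap]]
                ) -> Dict[str, float]:
    """Mean PPV at L/5, L/2 and L predictions across proteins.

    L is each protein's length (the contact-map dimension); the mean is
    unweighted across proteins.
    """
    if not pred_set:
        raise ValueError("need at least one (prediction, contact map) pair")
    sums = {"L/5": 0.0, "L/2": 0.0, "L": 0.0}
    for pred, truth in pred_set:
        L = truth.n_sites
        for key, n in (("L/5", round(L / 5)), ("L/2", round(L / 2)), ("L", L)):
            sums[key] += ppv_at(pred, truth, max(1, n))
    return {key: value / len(pred_set) for key, value in sums.items()}


def weighted_moving_average(series: Sequence[float], w: int) -> np.ndarray:
    """Triangular moving average with arithmetic-progression weights.

    The window spans 2w+1 positions; the center is weighted w, offsets
    +-k are weighted max(w - k, 0), so the +-w edges carry weight zero.
    At the series boundaries the window (with its weights) is truncated.
    For w=1 only the center has nonzero weight, so the series is
    returned unchanged.
    """
    if w < 1:
        raise ValueError("window half-width w must be >= 1")
    x = np.asarray(series, dtype=float)
    T = x.size
    out = np.empty(T)
    offsets = np.arange(-w, w + 1)
    weights = np.maximum(w - np.abs(offsets), 0).astype(float)
    for t in range(T):
        pos = t + offsets
        ok = (pos >= 0) & (pos < T)
        out[t] = float(weights[ok] @ x[pos[ok]] / weights[ok].sum())
    return out


def write_contact_map(cmap: ContactMap, path) -> None:
    """Export contacts as a 1-based ``i j`` pair list."""
    with open(path, "w") as fh:
        fh.write(f"# criterion={cmap.criterion} n={cmap.n_sites}\n")
        N = cmap.n_sites
        for i in range(N):
            for j in range(i + 1, N):
                if cmap.contacts[i, j]:
                    fh.write(f"{i + 1} {j + 1}\n")


def read_mapping(path) -> Dict[int, int]:
    """Two-column plain-text table: alignment column -> residue number."""
    mapping: Dict[int, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            col, resnum = line.split()
            mapping[int(col)] = int(resnum)
    return mapping


def write_mapping(mapping: Dict[int, int], path) -> None:
    with open(path, "w") as fh:
        for col in sorted(mapping):
            fh.write(f"{col}\t{mapping[col]}\n")
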