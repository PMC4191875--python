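"""Ground-truth generators: planted Potts models, Gibbs-sampled MSAs,
injected gap stretches and toy structures with known contact maps.

These emulate the inputs the inference is designed for — alignments with
a sparse set of strongly coupled column pairs, optionally corrupted by
the long shared gap stretches that real alignments acquire from modular
insertions/deletions.  They deliberately omit phylogenetic correlation
between rows: sampled sequences are (thinned) draws from a single
stationary distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .alignment import EncodedMSA, GAP_STATE, Q, find_gap_runs
from .benchmark import ContactMap
from .plm import GapRunTable, PottsParameters, _site_logits, zero_sum_gauge


@dataclass
class PlantedModel:
    """A Potts model with known sparse coupling support (the ground truth)."""

    params: PottsParameters
    true_pairs: Set[Tuple[int, int]]  # 1-based (i, j), i < j
    generator_seed: int


@dataclass
class GapInjectionSpec:
    """Where and how to inject shared gap stretches into an MSA.

    ``column_range`` is a 1-based inclusive ``(start, end)`` pair;
    ``fraction_of_rows`` of the rows are gapped there, either across the
    full range or over a per-row random-length prefix of it.
    """

    column_range: Tuple[int, int]
    fraction_of_rows: float
    pattern: str = "full_range"

    def __post_init__(self) -> None:
        lo, hi = self.column_range
        if not 1 <= lo <= hi:
            raise ValueError(f"bad column range {self.column_range}")
        if not 0.0 < self.fraction_of_rows <= 1.0:
            raise ValueError("fraction_of_rows must lie in (0, 1]")
        if self.pattern not in ("full_range", "random_length"):
            raise ValueError(f"unknown pattern {self.pattern!r}")


def make_planted_model(N: int, n_pairs: int, coupling_strength: float = 6.0,
                       field_scale: float = 0.5, seed: int = 0, q: int = Q,
                       min_separation: int = 5) -> PlantedModel:
    """Random sparse model: ``n_pairs`` coupled pairs at separation >= 5.

    Each planted block is a random zero-sum-gauge ``q x q`` matrix scaled
    to the requested Frobenius norm, so the generation truth already
    lives in the inference gauge; fields are i.i.d. normal with scale
    ``field_scale``.  Defaults give per-entry coupling magnitudes around
    ``coupling_strength / q`` (~0.3), i.e. strongly coevolving pairs.
    """
    rng = np.random.default_rng(seed)
    eligible = [(i, j) for i in range(N) for j in range(i + min_separation, N)]
    if n_pairs > len(eligible):
        raise ValueError(
            f"cannot place {n_pairs} pairs at separation >= {min_separation} "
            f"in {N} columns (only {len(eligible)} eligible)"
        )
    chosen = [eligible[k] for k in
              rng.choice(len(eligible), size=n_pairs, replace=False)]
    couplings: Dict[Tuple[int, int], np.ndarray] = {}
    for pair in sorted(chosen):
        block = zero_sum_gauge(rng.normal(size=(q, q)))
        norm = np.sqrt((block * block).sum())
        couplings[pair] = block * (coupling_strength / norm)
    fields = (rng.normal(scale=field_scale, size=(N, q)) if field_scale > 0
              else np.zeros((N, q)))
    return PlantedModel(
        params=PottsParameters(fields_h=fields, couplings=couplings),
        true_pairs={(i + 1, j + 1) for i, j in chosen},
        generator_seed=seed,
    )


def _clamped_gap_table(table: Optional[GapRunTable],
                       bound: float) -> Optional[GapRunTable]:
    if table is None:
        return None
    return GapRunTable(
        entries={k: float(np.clip(v, -bound, bound))
                 for k, v in table.entries.items()},
        max_length_L=table.max_length_L,
    )


def sample_msa_gibbs(model: PottsParameters, B: int, burn_in: int = 100,
                     thinning: int = 10, seed: int = 0,
                     use_gaps: bool = False,
                     gap_param_bound: float = 10.0) -> EncodedMSA:
    """Single-chain single-site Gibbs sampler for the (gap-)Potts model.

    One chain is initialized uniformly at random and swept site by site;
    row ``k`` of the output is the state after ``burn_in + k * thinning``
    full sweeps.  Gap-run energies are included iff ``use_gaps``; their
    parameters are clamped to ``|g| <= gap_param_bound`` to keep the
    chain away from degenerate all-gap attractors.
    """
    if B < 1:
        raise ValueError("need B >= 1 samples")
    N, q = model.n_sites, model.q
    sample_params = model
    if use_gaps and model.gap_params is not None:
        sample_params = PottsParameters(
            fields_h=model.fields_h, couplings=dict(model.couplings),
            gap_params=_clamped_gap_table(model.gap_params, gap_param_bound),
        )
    rng = np.random.default_rng(seed)
    state = rng.integers(0, q, size=N).astype(np.int64)
    rows = np.empty((B, N), dtype=np.int8)

    def sweep() -> None:
        for r0 in range(N):
            logits = _site_logits(state, r0, sample_params, use_gaps)
            gumbel = -np.log(-np.log(rng.random(q)))
            state[r0] = int(np.argmax(logits + gumbel))

    for _ in range(burn_in):
        sweep()
    rows[0] = state
    for k in range(1, B):
        for _ in range(thinning):
            sweep()
        rows[k] = state
    return EncodedMSA(data=rows, q=q)


def inject_gap_stretches(msa: EncodedMSA, spec: GapInjectionSpec,
                         seed: int = 0) -> EncodedMSA:
    """Overwrite a seeded subset of rows with a gap stretch.

    ``full_range`` gaps the whole column range in every selected row;
    ``random_length`` gaps a per-row random-length prefix of the range.
    Weights are reset to 1 — reweighting should be recomputed afterwards.
    """
    lo, hi = spec.column_range
    if hi > msa.n_columns:
        raise ValueError(
            f"column range {spec.column_range} outside 1..{msa.n_columns}"
        )
    rng = np.random.default_rng(seed)
    B = msa.n_sequences
    n_rows = int(round(spec.fraction_of_rows * B))
    selected = rng.choice(B, size=n_rows, replace=False)
    data = msa.data.copy()
    for s in selected:
        if spec.pattern == "full_range":
            data[s, lo - 1:hi] = GAP_STATE
        else:
            length = int(rng.integers(1, hi - lo + 2))
            data[s, lo - 1:lo - 1 + length] = GAP_STATE
    return EncodedMSA(data=data, q=msa.q, ids=list(msa.ids))


# ---------------------------------------------------------------------------
# toy structures


def _toy_calpha_coords(N: int, shape: str) -> np.ndarray:
    spacing = 3.8  # consecutive C-alpha distance, Angstrom
    if shape == "straight":
        coords = np.zeros((N, 3))
        coords[:, 0] = spacing * np.arange(N)
        return coords
    if shape == "hairpin":
        # two antiparallel strands 6 A apart: long-range cross-strand contacts
        m = N // 2
        coords = np.zeros((N, 3))
        coords[:m, 0] = spacing * np.arange(m)
        coords[m:, 0] = spacing * (N - 1 - np.arange(m, N))
        coords[m:, 1] = 6.0
        return coords
    raise ValueError(f"unknown toy shape {shape!r}")


def _format_pdb(ca: np.ndarray, cb: np.ndarray) -> str:
    # standard ATOM record columns: serial 7-11, name 13-16, resName 18-20,
    # chain 22, resSeq 23-26, x/y/z 31-54, occupancy/B 55-66, element 77-78
    lines = []
    serial = 1
    for k in range(ca.shape[0]):
        for name, xyz in (("CA", ca[k]), ("CB", cb[k])):
            lines.append(
                f"ATOM  {serial:5d} {name:^4s} ALA A{k + 1:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
                f"           C"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def toy_structure_fixture(N: int, seed: int = 0, shape: str = "hairpin",
                          threshold: float = 8.0
                          ) -> Tuple[str, Dict[int, int], ContactMap]:
    """Synthetic PDB text, identity column mapping, and its C-beta map.

    The chain is a poly-alanine trace with C-beta placed 1.53 A off each
    C-alpha, rigidly rotated/translated by a seeded random isometry (so
    parsing is exercised while all distances are preserved).  The
    returned :class:`ContactMap` is computed directly from the emitted
    coordinates under the C-beta criterion.
    """
    if N < 2:
        raise ValueError("need N >= 2 residues")
    ca = _toy_calpha_coords(N, shape)
    cb = ca + np.array([0.0, 0.0, 1.53])
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(3, 3))
    qmat, _ = np.linalg.qr(A)
    if np.linalg.det(qmat) < 0:
        qmat[:, 0] = -qmat[:, 0]
    shift = rng.uniform(-5, 5, size=3)
    ca = ca @ qmat.T + shift
    cb = cb @ qmat.T + shift
    # map truth from the coordinates as written to file (3-decimal precision)
    ca = np.round(ca, 3)
    cb = np.round(cb, 3)
    d = np.linalg.norm(cb[:, None, :] - cb[None, :, :], axis=-1)
    contacts = d <= threshold
    np.fill_diagonal(contacts, False)
    cmap = ContactMap(contacts=contacts, criterion="cbeta_8",
                      resolved=np.ones(N, dtype=bool))
    mapping = {col: col for col in range(1, N + 1)}
    return _format_pdb(ca, cb), mapping, cmap


def write_fasta(msa: EncodedMSA, path) -> None:
    """Write an encoded MSA back out as aligned FASTA."""
    from .alignment import decode_row

    ids = msa.ids if msa.ids else [f"seq_{k + 1}" for k in range(msa.n_sequences)]
    with open(path, "w") as fh:
        for sid, row in zip(ids, msa.data):
            fh.write(f">{sid}\n{decode_row(row)}\n")
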