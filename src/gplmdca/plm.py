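"""Asymmetric pseudo-likelihood inference of Potts models with gap-run terms.

The model over aligned sequences ``a = (a_1 .. a_N)``, ``a_i`` in a
``q``-state alphabet (gap = state 0), is

    P(a)  proportional to  exp( sum_i h_i(a_i) + sum_{i<j} J_ij(a_i, a_j)
                                + sum_{i,l} g_i^l Gamma_i^l(a) )

where ``Gamma_i^l(a)`` indicates a maximal gap run of length ``l``
beginning at column ``i`` and the ``g_i^l`` are gap-run propensities
(absent in the plain Potts model).  The joint normalizer is intractable,
so parameters are learned by maximizing, per site ``r``, the
L2-regularized weighted log of the conditional ``P(a_r | a_{\\r})`` —
the asymmetric pseudo-likelihood scheme.  The per-site coupling
estimates are then averaged into symmetric blocks and projected onto the
zero-sum (Ising) gauge before any scoring.

Column/site indices in the public API are 1-based, matching the gap-run
table convention; matrices are ordinary 0-based numpy arrays.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.optimize
import scipy.sparse as sp
from joblib import Parallel, delayed

from .alignment import EncodedMSA, GAP_STATE, max_gap_run_length

GapKey = Tuple[int, int]  # (1-based start column, run length)


@dataclass
class GapRunTable:
    """Sparse map (start column, run length) -> gap-run parameter g_i^l.

    ``max_length_L`` is the meta-parameter L: the largest gap-run length
    carrying a parameter, set per alignment to the longest observed run
    (0 for a gap-free alignment, in which case the table is empty).
    Missing entries act as exact zeros.
    """

    entries: Dict[GapKey, float] = field(default_factory=dict)
    max_length_L: int = 0

    def get(self, start: int, length: int) -> float:
        return self.entries.get((start, length), 0.0)


@dataclass
class RegularizationConfig:
    """L2 penalty strengths applied to the weight-normalized objective."""

    lambda_h: float = 0.01
    lambda_J: float = 0.01
    lambda_g: float = 0.01

    def __post_init__(self) -> None:
        if min(self.lambda_h, self.lambda_J, self.lambda_g) < 0:
            raise ValueError("regularization strengths must be non-negative")


@dataclass
class OptimizerSettings:
    """Deterministic quasi-Newton (L-BFGS-B) settings; zero initialization."""

    gtol: float = 1e-5
    max_iter: int = 500
    maxcor: int = 10
    ftol: float = 1e-12
    record_history: bool = False


@dataclass
class PottsParameters:
    """Fields, symmetric pair couplings and (optional) gap-run parameters.

    ``couplings`` maps 0-based site pairs ``(i, j)`` with ``i < j`` to
    ``(q, q)`` blocks ``J_ij(a_i, a_j)``; absent pairs are exact zeros.
    """

    fields_h: np.ndarray  # (N, q)
    couplings: Dict[Tuple[int, int], np.ndarray] = field(default_factory=dict)
    gap_params: Optional[GapRunTable] = None

    def __post_init__(self) -> None:
        self.fields_h = np.asarray(self.fields_h, dtype=float)
        self._adjacency: Optional[list] = None

    @property
    def n_sites(self) -> int:
        return self.fields_h.shape[0]

    @property
    def q(self) -> int:
        return self.fields_h.shape[1]

    def site_adjacency(self, r0: int):
        """Cached list of (other_site, block, axis) for site ``r0`` (0-based)."""
        if self._adjacency is None:
            adj = [[] for _ in range(self.n_sites)]
            for (i, j), block in self.couplings.items():
                adj[i].append((j, block, 0))  # logits over a_i: J[:, a_j]
                adj[j].append((i, block, 1))  # logits over a_j: J[a_i, :]
            self._adjacency = adj
        return self._adjacency[r0]


@dataclass
class SiteParameters:
    """Parameters of one site conditional in the asymmetric scheme.

    ``J`` maps 0-based partner site to a ``(q, q)`` block oriented
    ``J[a_r, a_partner]``; ``gap`` holds the site's local gap-run entries.
    """

    h: np.ndarray
    J: Dict[int, np.ndarray] = field(default_factory=dict)
    gap: Dict[GapKey, float] = field(default_factory=dict)


@dataclass
class SiteFit:
    params: SiteParameters
    objective: float
    grad_inf_norm: float
    converged: bool
    n_iterations: int
    objective_history: List[float] = field(default_factory=list)


@dataclass
class FitResult:
    """Symmetrized, gauge-fixed model plus per-site optimization metadata."""

    params: PottsParameters
    per_site_objectives: np.ndarray
    converged_flags: np.ndarray
    config: dict
    site_gap_tables: Optional[List[GapRunTable]] = None
    masked_pairs: frozenset = frozenset()

    @property
    def n_sites(self) -> int:
        return self.params.n_sites


# ---------------------------------------------------------------------------
# gap-run energetics


def _flank_gap_lengths(row: Sequence[int], r0: int) -> Tuple[int, int]:
    """(lambda, rho): consecutive gaps immediately left/right of 0-based r0."""
    lam = 0
    i = r0 - 1
    while i >= 0 and row[i] == GAP_STATE:
        lam += 1
        i -= 1
    rho = 0
    n = len(row)
    i = r0 + 1
    while i < n and row[i] == GAP_STATE:
        rho += 1
        i += 1
    return lam, rho


def local_gap_energy(row: Sequence[int], r: int, candidate_state: int,
                     gaps: GapRunTable) -> float:
    """Gap-run energy of placing ``candidate_state`` at 1-based column ``r``.

    Only runs touching column ``r`` depend on the candidate: with lambda
    gaps immediately left and rho immediately right, a gap candidate
    creates the run (r - lambda, lambda + rho + 1), while a non-gap
    candidate leaves the flanking runs (r - lambda, lambda) and
    (r + 1, rho) intact.  Absent table entries contribute 0.
    """
    n = len(row)
    if not 1 <= r <= n:
        raise IndexError(f"column {r} outside 1..{n}")
    r0 = r - 1
    lam, rho = _flank_gap_lengths(row, r0)
    if candidate_state == GAP_STATE:
        return gaps.get(r - lam, lam + rho + 1)
    energy = 0.0
    if lam > 0:
        energy += gaps.get(r - lam, lam)
    if rho > 0:
        energy += gaps.get(r + 1, rho)
    return energy


def _site_logits(row: Sequence[int], r0: int, params: PottsParameters,
                 use_gaps: bool) -> np.ndarray:
    """Unnormalized conditional log-weights of site r0 given the rest of row."""
    logits = params.fields_h[r0].astype(float).copy()
    for other, block, axis in params.site_adjacency(r0):
        if axis == 0:
            logits += block[:, row[other]]
        else:
            logits += block[row[other], :]
    if use_gaps and params.gap_params is not None:
        table = params.gap_params
        r = r0 + 1
        lam, rho = _flank_gap_lengths(row, r0)
        logits[GAP_STATE] += table.get(r - lam, lam + rho + 1)
        base = 0.0
        if lam > 0:
            base += table.get(r - lam, lam)
        if rho > 0:
            base += table.get(r + 1, rho)
        if base:
            logits[1:] += base
    return logits


def conditional_logprobs(row: Sequence[int], r: int, params: PottsParameters,
                         use_gaps: bool = False) -> np.ndarray:
    """log P(a_r = s | rest of row) for every state s; 1-based column r.

    The value of ``row`` at column ``r`` is ignored.
    """
    if not np.all(np.isfinite(params.fields_h)):
        raise FloatingPointError("non-finite field parameters")
    logits = _site_logits(row, r - 1, params, use_gaps)
    if not np.all(np.isfinite(logits)):
        raise FloatingPointError("non-finite conditional logits")
    m = logits.max()
    lse = m + np.log(np.exp(logits - m).sum())
    return logits - lse


# ---------------------------------------------------------------------------
# per-site optimization problem


def _gap_runlengths(data: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Per-cell lengths of the gap run ending (left) / starting (right) there."""
    B, N = data.shape
    is_gap = data == GAP_STATE
    left = np.zeros((B, N), dtype=np.int32)
    right = np.zeros((B, N), dtype=np.int32)
    for c in range(N):
        left[:, c] = np.where(is_gap[:, c], (left[:, c - 1] if c else 0) + 1, 0)
    for c in range(N - 1, -1, -1):
        right[:, c] = np.where(
            is_gap[:, c], (right[:, c + 1] if c < N - 1 else 0) + 1, 0
        )
    return left, right


class SiteProblem:
    """Objective/gradient of one site's regularized conditional likelihood.

    The parameter vector is the concatenation of the site fields ``h``
    (q), the directed coupling blocks toward each free partner (flattened
    ``J[a_partner, a_r]`` design weights) and the site's local gap-run
    parameters.  The data terms are weight-averaged by ``1 / b_eff``.
    """

    def __init__(self, msa: EncodedMSA, r: int, reg: RegularizationConfig,
                 use_gaps: bool, partners: Optional[Sequence[int]] = None,
                 max_gap_length: Optional[int] = None,
                 extra_gap_keys: Sequence[GapKey] = (),
                 _runlengths=None):
        data = msa.data
        B, N = data.shape
        if not 1 <= r <= N:
            raise IndexError(f"column {r} outside 1..{N}")
        self.q = msa.q
        self.r0 = r - 1
        self.B = B
        self.weights = msa.weights
        self.b_eff = float(msa.weights.sum())
        if self.b_eff <= 0:
            raise ValueError("degenerate weights: b_eff must be positive")
        self.reg = reg
        self.use_gaps = use_gaps
        self.partners = (
            [i for i in range(N) if i != self.r0]
            if partners is None else sorted(partners)
        )
        self.y = data[:, self.r0].astype(np.int64)

        # one-hot design over partner states: X[s, p*q + a] = 1
        P = len(self.partners)
        cols = (np.arange(P)[None, :] * self.q
                + data[:, self.partners].astype(np.int64))
        rows = np.repeat(np.arange(B), P)
        self.X = sp.csr_matrix(
            (np.ones(B * P), (rows, cols.ravel())), shape=(B, P * self.q)
        )

        self.gap_keys: List[GapKey] = []
        self.Cg = self.Cn = None
        if use_gaps:
            L = (max_gap_run_length(msa) if max_gap_length is None
                 else max_gap_length)
            self.max_gap_length = L
            left, right = _runlengths if _runlengths is not None else _gap_runlengths(data)
            r0 = self.r0
            lam = left[:, r0 - 1] if r0 > 0 else np.zeros(B, dtype=np.int32)
            rho = right[:, r0 + 1] if r0 < N - 1 else np.zeros(B, dtype=np.int32)
            key_index: Dict[GapKey, int] = {}
            g_rows, g_cols, n_rows, n_cols = [], [], [], []

            def _col(key: GapKey) -> int:
                if key not in key_index:
                    key_index[key] = len(self.gap_keys)
                    self.gap_keys.append(key)
                return key_index[key]

            for s in range(B):
                la, rh = int(lam[s]), int(rho[s])
                full = la + rh + 1
                if full <= L:
                    g_rows.append(s)
                    g_cols.append(_col((r - la, full)))
                if la > 0:
                    n_rows.append(s)
                    n_cols.append(_col((r - la, la)))
                if rh > 0:
                    n_rows.append(s)
                    n_cols.append(_col((r + 1, rh)))
            for key in extra_gap_keys:
                _col(key)
            K = len(self.gap_keys)
            self.Cg = sp.csr_matrix(
                (np.ones(len(g_rows)), (g_rows, g_cols)), shape=(B, K)
            )
            self.Cn = sp.csr_matrix(
                (np.ones(len(n_rows)), (n_rows, n_cols)), shape=(B, K)
            )

    # -- parameter packing --------------------------------------------------

    @property
    def n_coupling_params(self) -> int:
        return len(self.partners) * self.q * self.q

    @property
    def n_params(self) -> int:
        return self.q + self.n_coupling_params + len(self.gap_keys)

    def pack(self, site: SiteParameters) -> np.ndarray:
        q = self.q
        theta = np.zeros(self.n_params)
        theta[:q] = site.h
        W = theta[q:q + self.n_coupling_params].reshape(len(self.partners), q, q)
        for p, other in enumerate(self.partners):
            block = site.J.get(other)
            if block is not None:
                # design weight W[p, a_partner, a_r] = J[a_r, a_partner]
                W[p] = np.asarray(block).T
        for k, key in enumerate(self.gap_keys):
            theta[q + self.n_coupling_params + k] = site.gap.get(key, 0.0)
        return theta

    def unpack(self, theta: np.ndarray) -> SiteParameters:
        q = self.q
        h = theta[:q].copy()
        W = theta[q:q + self.n_coupling_params].reshape(len(self.partners), q, q)
        J = {other: W[p].T.copy() for p, other in enumerate(self.partners)}
        gap = {
            key: float(theta[q + self.n_coupling_params + k])
            for k, key in enumerate(self.gap_keys)
        }
        return SiteParameters(h=h, J=J, gap=gap)

    # -- objective ----------------------------------------------------------

    def value_and_grad(self, theta: np.ndarray) -> Tuple[float, np.ndarray]:
        q = self.q
        nW = self.n_coupling_params
        h = theta[:q]
        W = theta[q:q + nW].reshape(-1, q)
        g = theta[q + nW:]

        logits = self.X @ W + h
        if g.size:
            logits[:, GAP_STATE] += self.Cg @ g
            base = self.Cn @ g
            logits[:, 1:] += base[:, None]

        m = logits.max(axis=1, keepdims=True)
        ez = np.exp(logits - m)
        sez = ez.sum(axis=1)
        lse = (m.ravel() + np.log(sez))
        picked = logits[np.arange(self.B), self.y]
        wn = self.weights / self.b_eff
        f = float(wn @ (lse - picked))

        E = ez / sez[:, None]
        E[np.arange(self.B), self.y] -= 1.0
        E *= wn[:, None]

        reg = self.reg
        grad = np.empty_like(theta)
        grad[:q] = E.sum(axis=0) + 2.0 * reg.lambda_h * h
        grad[q:q + nW] = (self.X.T @ E).ravel() + 2.0 * reg.lambda_J * theta[q:q + nW]
        if g.size:
            grad[q + nW:] = (
                self.Cg.T @ E[:, GAP_STATE]
                + self.Cn.T @ E[:, 1:].sum(axis=1)
                + 2.0 * reg.lambda_g * g
            )
        f += (reg.lambda_h * float(h @ h)
              + reg.lambda_J * float(theta[q:q + nW] @ theta[q:q + nW])
              + reg.lambda_g * float(g @ g))
        return f, grad


def site_objective_and_gradient(msa: EncodedMSA, r: int, site_params: SiteParameters,
                                reg: RegularizationConfig, use_gaps: bool
                                ) -> Tuple[float, SiteParameters]:
    """Evaluate one site's regularized objective and its exact gradient.

    The gradient is returned in the same shape as the parameters.  Gap
    keys provided in ``site_params.gap`` but never reachable in the data
    still incur their quadratic penalty.
    """
    problem = SiteProblem(msa, r, reg, use_gaps,
                          extra_gap_keys=tuple(site_params.gap))
    f, grad = problem.value_and_grad(problem.pack(site_params))
    return f, problem.unpack(grad)


def fit_site(msa: EncodedMSA, r: int, reg: Optional[RegularizationConfig] = None,
             use_gaps: bool = False,
             settings: Optional[OptimizerSettings] = None,
             partners: Optional[Sequence[int]] = None,
             x0: Optional[np.ndarray] = None,
             _runlengths=None, _max_gap_length=None) -> SiteFit:
    """Optimize one site conditional from zero initialization (deterministic)."""
    reg = reg if reg is not None else RegularizationConfig()
    settings = settings if settings is not None else OptimizerSettings()
    problem = SiteProblem(msa, r, reg, use_gaps, partners=partners,
                          max_gap_length=_max_gap_length, _runlengths=_runlengths)
    theta0 = np.zeros(problem.n_params) if x0 is None else np.asarray(x0, float)
    history: List[float] = []
    callback = None
    if settings.record_history:
        callback = lambda xk: history.append(problem.value_and_grad(xk)[0])
    res = scipy.optimize.minimize(
        problem.value_and_grad, theta0, jac=True, method="L-BFGS-B",
        callback=callback,
        options=dict(maxiter=settings.max_iter, maxcor=settings.maxcor,
                     ftol=settings.ftol, gtol=settings.gtol),
    )
    f, grad = problem.value_and_grad(res.x)
    gnorm = float(np.abs(grad).max()) if grad.size else 0.0
    return SiteFit(
        params=problem.unpack(res.x),
        objective=float(f),
        grad_inf_norm=gnorm,
        converged=bool(gnorm < settings.gtol),
        n_iterations=int(res.nit),
        objective_history=history,
    )


# ---------------------------------------------------------------------------
# whole-model fit


def symmetrize_couplings(directed: Dict[int, Dict[int, np.ndarray]]
                         ) -> Dict[Tuple[int, int], np.ndarray]:
    """Average the two directed estimates of each pair block.

    ``directed[r][i]`` is site r's estimate oriented ``J[a_r, a_i]``; the
    symmetric block is ``J_ij = (J^(i)_{i,j} + J^(j)_{j,i}^T) / 2`` with
    orientation ``(a_i, a_j)`` for ``i < j``.
    """
    out: Dict[Tuple[int, int], np.ndarray] = {}
    for i in directed:
        for j, block in directed[i].items():
            if i < j:
                other = directed.get(j, {}).get(i)
                if other is None:
                    raise KeyError(f"missing directed estimate for pair ({j}, {i})")
                out[(i, j)] = 0.5 * (block + other.T)
    return out


def zero_sum_gauge(J: np.ndarray) -> np.ndarray:
    """Project a coupling block onto the zero-sum (Ising) gauge.

    ``J'(a,b) = J(a,b) - mean_a J(., b) - mean_b J(a, .) + mean J(., .)``;
    afterwards every row and column sums to zero.  Idempotent linear map.
    """
    J = np.asarray(J, dtype=float)
    row_mean = J.mean(axis=1, keepdims=True)
    col_mean = J.mean(axis=0, keepdims=True)
    return J - row_mean - col_mean + J.mean()


def collapse_duplicate_rows(msa: EncodedMSA) -> EncodedMSA:
    """Merge identical rows, summing their weights (objective-equivalent)."""
    uniq, inverse = np.unique(msa.data, axis=0, return_inverse=True)
    if uniq.shape[0] == msa.data.shape[0]:
        return msa
    weights = np.zeros(uniq.shape[0])
    np.add.at(weights, inverse, msa.weights)
    return EncodedMSA(data=uniq, weights=weights, q=msa.q)


def fit_model(msa: EncodedMSA, reg: Optional[RegularizationConfig] = None,
              use_gaps: bool = False,
              settings: Optional[OptimizerSettings] = None,
              n_jobs: int = 1,
              masked_pairs: Sequence[Tuple[int, int]] = (),
              collapse_duplicates: bool = True) -> FitResult:
    """Fit every site conditional, symmetrize and gauge-fix the couplings.

    Sites are independent, so the result is identical for any degree of
    parallelism.  ``masked_pairs`` (0-based ``i < j``) are frozen at zero
    and excluded from the per-site designs (decimation support).  Gap
    parameters are per-site nuisance values kept in ``site_gap_tables``;
    only the couplings feed contact scoring.
    """
    reg = reg if reg is not None else RegularizationConfig()
    settings = settings if settings is not None else OptimizerSettings()
    N = msa.n_columns
    if N < 2:
        raise ValueError("need an alignment with at least 2 columns")
    work = collapse_duplicate_rows(msa) if collapse_duplicates else msa
    masked = frozenset((min(i, j), max(i, j)) for i, j in masked_pairs)

    runlengths = _gap_runlengths(work.data) if use_gaps else None
    L = max_gap_run_length(work) if use_gaps else 0

    def partners_of(r0: int) -> List[int]:
        return [i for i in range(N) if i != r0
                and (min(i, r0), max(i, r0)) not in masked]

    def one_site(r0: int) -> SiteFit:
        return fit_site(work, r0 + 1, reg, use_gaps, settings,
                        partners=partners_of(r0),
                        _runlengths=runlengths, _max_gap_length=L)

    if n_jobs == 1:
        fits = [one_site(r0) for r0 in range(N)]
    else:
        fits = Parallel(n_jobs=n_jobs, backend="threading")(
            delayed(one_site)(r0) for r0 in range(N)
        )

    q = msa.q
    fields = np.stack([fits[r0].params.h for r0 in range(N)])
    directed = {r0: fits[r0].params.J for r0 in range(N)}
    couplings = symmetrize_couplings(directed)
    couplings = {pair: zero_sum_gauge(block) for pair, block in couplings.items()}
    for i, j in masked:
        couplings[(i, j)] = np.zeros((q, q))

    site_gap_tables = None
    if use_gaps:
        site_gap_tables = [
            GapRunTable(entries=dict(fits[r0].params.gap), max_length_L=L)
            for r0 in range(N)
        ]

    config = dict(
        use_gaps=use_gaps,
        lambda_h=reg.lambda_h, lambda_J=reg.lambda_J, lambda_g=reg.lambda_g,
        gtol=settings.gtol, max_iter=settings.max_iter,
        b_eff=msa.b_eff, n_sequences=msa.n_sequences, n_columns=N, q=q,
        max_gap_length=L,
        n_masked_pairs=len(masked),
    )
    return FitResult(
        params=PottsParameters(fields_h=fields, couplings=couplings),
        per_site_objectives=np.array([f.objective for f in fits]),
        converged_flags=np.array([f.converged for f in fits], dtype=bool),
        config=config,
        site_gap_tables=site_gap_tables,
        masked_pairs=masked,
    )


# ---------------------------------------------------------------------------
# serialization


def save_fit(fit: FitResult, path) -> None:
    """Write a FitResult to an ``.npz`` container (lossless round trip)."""
    pairs = sorted(fit.params.couplings)
    stacked = (np.stack([fit.params.couplings[p] for p in pairs])
               if pairs else np.zeros((0, fit.params.q, fit.params.q)))
    np.savez(
        path,
        fields_h=fit.params.fields_h,
        pair_i=np.array([p[0] for p in pairs], dtype=np.int64),
        pair_j=np.array([p[1] for p in pairs], dtype=np.int64),
        couplings=stacked,
        per_site_objectives=fit.per_site_objectives,
        converged_flags=fit.converged_flags,
        masked_i=np.array([p[0] for p in sorted(fit.masked_pairs)], dtype=np.int64),
        masked_j=np.array([p[1] for p in sorted(fit.masked_pairs)], dtype=np.int64),
        config_json=np.array(json.dumps(fit.config)),
    )


def load_fit(path) -> FitResult:
    with np.load(path, allow_pickle=False) as z:
        pairs = list(zip(z["pair_i"].tolist(), z["pair_j"].tolist()))
        couplings = {pair: z["couplings"][k].copy() for k, pair in enumerate(pairs)}
        masked = frozenset(zip(z["masked_i"].tolist(), z["masked_j"].tolist()))
        return FitResult(
            params=PottsParameters(fields_h=z["fields_h"].copy(),
                                   couplings=couplings),
            per_site_objectives=z["per_site_objectives"].copy(),
            converged_flags=z["converged_flags"].copy(),
            config=json.loads(str(z["config_json"])),
            masked_pairs=masked,
        )
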