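# Methods

## Model

Sequences are encoded over `q = 21` states: gap = 0 (also used for the
ambiguity codes B, J, O, U, X, Z), amino acids 1–20 in alphabetical
one-letter order. The joint model is a Potts distribution with fields
`h_i(a)` and couplings `J_ij(a, b)`; the gap-aware variant adds one
scalar `g_i^l` per (start column `i`, run length `l`) for maximal gap
runs, with `l` bounded by the meta-parameter `L`, set per alignment to
the longest observed run. For a gap-free alignment `L = 0` and the gap
table is empty, which makes the gap-aware fit identical to the plain
one — a deliberate property, used by the test suite. The number of gap
parameters is at most `N·L`, negligible next to the
`N(N−1)/2 · q²` couplings.

Only the runs touching a column depend on that column's state, so the
conditional energy at column `r` needs just the flanking gap counts
(λ to the left, ρ to the right): a gap at `r` activates
`g_{r−λ}^{λ+ρ+1}`, a residue activates `g_{r−λ}^{λ}` and `g_{r+1}^{ρ}`
(when the flanks are nonempty). Entries absent from the table — in
particular runs longer than `L` reachable only by toggling `r` —
contribute zero.

## Inference

The joint normalizer is intractable, so each column's conditional
`P(a_r | a_{\r})` is maximized independently (asymmetric
pseudo-likelihood). Per column this is an L2-regularized multinomial
logistic regression with one-hot features of the other columns plus the
sparse gap-run features above; it is implemented with a sparse design
matrix and analytic gradients, optimized by L-BFGS-B from zero
initialization (gradient tolerance 1e−5, 500 iterations cap), which
makes results deterministic without any seed. Convexity of each site
problem plus the line search guarantee monotone descent; per-site
independence guarantees bit-identical results under any parallelism.

The weighted negative log-conditional is normalized by `b_eff`
(sequence weights: `1/n_s` where `n_s` counts sequences at ≥ 90%
identity, gap positions included, self included). Penalties
`λ_h = λ_J = λ_g = 0.01` act on this normalized objective; they follow
common pseudo-likelihood DCA practice and are exposed in
`RegularizationConfig`. Duplicate rows may be collapsed with summed
weights; the objective is unchanged.

Directed coupling estimates are averaged,
`J_ij = (J^{(i)}_{ij} + J^{(j)T}_{ji}) / 2`, and every block is
explicitly projected onto the zero-sum gauge
`J ← J − rowmean − colmean + mean` before scoring: the L2 penalty only
pushes toward that gauge approximately at finite λ. Gap parameters are
per-site nuisance values — the asymmetric scheme gives each conditional
its own copy, no cross-site reconciliation is attempted — and they are
excluded from scoring.

## Scoring

`fn21` is the Frobenius norm of the gauge-fixed 21×21 block; `fn20`
restricts the sum of squares to the amino-acid submatrix of the *same*
gauge-fixed block (no re-gauging), so gap observations still shape the
estimate but gap-state couplings are discarded from the score. APC
subtracts `mean_i · mean_j / mean` computed with the diagonal excluded
(the convention of the APC literature; an all-zero matrix short-circuits
to zero). Ranking keeps pairs with separation ≥ 5 and breaks ties
lexicographically so output files are bit-reproducible. Decimation
ranks whole pair blocks by current APC score, freezes the weakest
`floor(0.1 · remaining)` per round at zero, and refits; round zero is
exactly the plain fit.

## Benchmarking

Contact maps come from standard PDB input via Biopython (first MODEL,
highest-occupancy altloc): Cβ–Cβ ≤ 8.0 Å (Cα for glycine — the
universal convention) or minimum heavy-atom distance ≤ 8.5 Å. The
column→residue mapping is an explicit two-column table; automatic
structure alignment is out of scope. Unmapped columns and residues
without usable coordinates are "unresolved"; predictions touching them
are skipped without consuming rank positions, so missing density is not
penalized. PPV at `n` is the fraction of true contacts among the top
`n` counted predictions, reported at absolute `n`, at `ceil(f·N)` over
a 0.1-step fraction grid, and at `round(L/5)`, `round(L/2)`, `L` (if
fewer counted predictions than `n` exist, the available ones are used).
The triangular weighted moving average (center weight `w`, decreasing
by 1 per offset, truncated with its weights at the boundaries) is
provided for smoothing per-position series; `w = 1` is the identity.

## Synthetic data

The generator emulates the regime the method targets, with known ground
truth:

- **Planted models**: `n_pairs` column pairs at separation ≥ 5 receive
  random zero-sum-gauge 21×21 blocks scaled to a common Frobenius norm;
  generation truth therefore lives in the inference gauge. Defaults:
  N = 40, 15 pairs, block norm 6.0 (per-entry magnitude ≈ 0.3, i.e.
  strongly coevolving pairs — chosen so that recovery is
  information-limited by sampling noise rather than trivially easy or
  impossible at the default alignment depth), field scale 0.5.
- **Sampling**: a single-chain single-site Gibbs sampler (burn-in 100
  sweeps, thinning 10, default B = 2000 rows) reusing the same
  conditional-energy code the inference uses; correctness is checked
  against exact enumeration on two-column models. Gap parameters are
  clamped to |g| ≤ 10 during sampling to avoid degenerate all-gap
  attractors.
- **Gap injection**: a seeded fraction of rows (default experiment:
  40%) has a 12-column range set to gaps, either the full range or a
  random-length prefix per row — the "shared gap stretch" signature of
  modular insertions/deletions that real alignment pipelines produce.
- **Toy structures**: poly-alanine traces (straight chain or two-strand
  hairpin, 3.8 Å spacing, Cβ 1.53 Å off Cα) written as standard PDB
  text after a seeded rigid rotation; their contact maps are computed
  directly from the emitted coordinates, giving closed-form truth for
  the benchmark parser.

What the generator does *not* emulate: phylogenetic correlation between
rows (samples are thinned draws from one stationary chain), alignment
uncertainty, column-dependent amino-acid composition beyond the random
fields, and insert-state structure. Tests passing on these inputs
therefore validate the estimator and its bookkeeping under the model's
own assumptions, not performance on real protein families.

## Numerical choices and edge cases

- Identity-based reweighting uses `matches ≥ (1−x)·N` with a 1e−9
  slack against float fuzz in the product.
- Two-column alignments with `min_separation ≥ N` rank zero pairs —
  an empty result, not an error.
- `apc_correct` refuses double application; `frobenius_scores` raises
  on a missing pair block (masked blocks are stored as explicit zeros).
- The optimizer's convergence flag is recomputed from the returned
  point (max-norm of the analytic gradient below 1e−5); non-convergent
  sites are reported, not fatal.
- Fitting independent-site data with a vanishing coupling penalty is
  ill-posed at q = 21: rare state pairs quasi-separate the conditional
  and inflate couplings. The test suite documents this by keeping a
  finite coupling penalty in that scenario; flat (gauge) directions are
  pinned only by the penalty, so field comparisons are made on the
  gauge-invariant effective field.
- The Gibbs-sampler total-variation check against exact enumeration
  runs on a reduced q = 3 alphabet: at q = 21 the multinomial noise
  floor of the TV statistic at 5·10⁴ samples (~0.037 for a near-uniform
  441-cell joint) would exceed the scale being probed. The full
  alphabet is covered by a chi-square goodness-of-fit test instead.

## Problem sizes

The study-scale experiments (contact recovery, gap-artifact
suppression) use N = 40 columns, B = 2000 sequences and 15 planted
pairs — deep enough for clean recovery under the default coupling
strength, small enough that the entire acceptance run completes in
seconds on one CPU. Two-site oracle checks use exhaustive enumeration
(441 or 9 joint states) and 5·10⁴ Gibbs samples.
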