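# gplmdca

Gap-aware direct coupling analysis (DCA) for protein residue–residue
contact prediction.

Columns of a deep multiple sequence alignment (MSA) that co-evolve tend
to be in spatial contact in the folded protein. DCA separates such
*direct* couplings from indirect correlation by fitting a global
statistical model to the alignment. This package implements
pseudo-likelihood DCA over the 21-state alphabet (20 amino acids + gap)
together with two defenses against a systematic failure mode of plain
Potts models: shared stretches of gaps in the alignment masquerade as
strong couplings, producing high-ranking false-positive "contacts"
between gap-rich columns.

## Model and scoring

The baseline model over aligned sequences `a = (a_1 … a_N)` is the Potts
model

    P(a) ∝ exp( Σ_i h_i(a_i) + Σ_{i<j} J_ij(a_i, a_j) )

with per-column fields `h_i` and pairwise coupling blocks `J_ij`
(21×21). The gap-aware extension (**gplmDCA**) adds run propensities

    … + Σ_{i,l} g_i^l Γ_i^l(a)

where `Γ_i^l(a) = 1` iff a maximal gap run of length `l` begins at
column `i`, and `l` ranges up to the longest run observed in the
alignment. These terms give the model an explicit, cheap way to account
for long shared gap stretches, so that the pairwise couplings no longer
have to.

Parameters are learned by **asymmetric pseudo-likelihood maximization**:
each column's conditional distribution given the rest of the sequence is
an L2-regularized multinomial regression, optimized independently per
column (L-BFGS, deterministic from zero initialization); the two
directed estimates of each `J_ij` are then averaged and projected onto
the zero-sum (Ising) gauge. Sequences are reweighted so that clusters
more than 90% identical count once (`b_eff` effective sequences).

Pairs are ranked by the Frobenius norm of the gauge-fixed coupling
blocks with the Average Product Correction (APC). Two scoring variants
are available:

- `fn21` — norm over the full 21×21 block (plain plmDCA / gplmDCA);
- `fn20` — norm over the 20×20 amino-acid submatrix, discarding the gap
  row/column *after* gauge fixing (**plmDCA20**).

Optional **decimation** repeatedly refits while freezing the weakest
fraction of coupling blocks at zero. A benchmarking harness computes
structural contact maps (Cβ ≤ 8 Å, or any heavy-atom pair ≤ 8.5 Å) and
positive predictive value (PPV) at the top `L/5`, `L/2`, `L`
predictions, with sequence separation ≥ 5 throughout.

A synthetic-data module generates ground-truth inputs: planted sparse
Potts models, single-chain Gibbs-sampled alignments, injected gap
stretches, and toy PDB structures with known contact maps.

## Worked example

Simulate an alignment from a planted model with 15 coupled column pairs,
fit, and score:

```sh
$ gplmdca simulate -N 40 --n-pairs 15 -B 2000 --seed 11 -o demo
$ gplmdca fit demo.fasta -o demo
reading demo.fasta (fasta)
B=2000 N=40 b_eff=2000.00
wrote demo.scores.tsv, demo.fit.npz, demo.runlog.json
$ head -6 demo.scores.tsv
# variant=fn21 apc=True min_separation=5 model=plmDCA
13	37	0.2849069706
3	21	0.260295076
19	39	0.2337916837
11	20	0.2322137893
1	23	0.2311371598
```

Each line is a 1-based column pair and its APC-corrected coupling
strength, in descending order — the prediction that columns 13 and 37
are in contact is the most confident. Comparing against
`demo.truth.json` (the generator's planted pairs), 13 of the top 15
predictions are planted pairs for this seed. `gplmdca bench` evaluates
such a score file against a PDB structure plus a column→residue mapping
and prints PPV at `L/5`, `L/2` and `L`; `gplmdca fit --model gplmDCA`
fits the gap-aware model, and `--model plmDCA20` switches to gap-excluded
scoring.

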