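# Methods

## Model and hypotheses

Data are n iid pairs (X, Y) with X ∈ {1..I}, Y ∈ {1..J}, summarized as an
I×J table of counts o_ij with margins o_i+, o_+j and expected counts
e_ij = o_i+ o_+j / n. The null hypothesis is independence, p_ij = q_i r_j
for all cells, where p_ij are joint cell probabilities and q, r the
marginals. The departure from independence is measured by
D = Σ_ij (p_ij − q_i r_j)², which is zero exactly under independence and,
unlike the χ² divergence Σ (p_ij − q_i r_j)²/(q_i r_j), carries no
cell-probability denominators — so it weighs all cells equally rather than
amplifying low-probability cells.

## The estimator D̂ and the USP statistic Û

D̂ is the fourth-order U-statistic with kernel

h(z₁, z₂, z₃, z₄) = Σ_ij [ 1{z₁=(i,j)} 1{z₂=(i,j)}
                           − 2·1{z₁=(i,j)} 1{x₂=i} 1{y₃=j}
                           + 1{x₁=i} 1{y₂=j} 1{x₃=i} 1{y₄=j} ],

averaged over all n(n−1)(n−2)(n−3) ordered 4-tuples of distinct
observation indices. Taking expectations term by term gives
E h = Σ (p_ij² − 2 p_ij q_i r_j + q_i² r_j²) = D, so D̂ is unbiased; it is
in fact the unique minimum-variance unbiased estimator of D.

`dhat_brute` implements this definition literally (kernel kept as the
indicator double sum, tuples enumerated; O(n⁴·IJ), intended for n ≲ 12).
`dhat_closed_form` is the O(IJ) counts-only equivalent, obtained by
resolving each kernel term's distinct-index constraints with
inclusion–exclusion:

- same-cell pairs: Σ o_ij(o_ij−1) / (n(n−1));
- cell×row×column triples (a ≠ b ≠ c):
  −2 Σ [o_ij o_i+ o_+j − o_ij o_i+ − o_ij o_+j − o_ij² + 2 o_ij] / (n(n−1)(n−2));
- row-pair×column-pair quadruples (all distinct):
  Σ [o_i+(o_i+−1) o_+j(o_+j−1) − 4 o_ij (o_i+−1)(o_+j−1) + 2 o_ij(o_ij−1)]
  / (n(n−1)(n−2)(n−3)).

The closed form is treated as *derived, then validated*: the test suite
checks it against the brute-force definition to 1e-9 on random tables with
4 ≤ n ≤ 8, and against an exact rational-arithmetic evaluation.

The USP statistic

Û = Σ (o_ij − e_ij)² / (n(n−3)) − 4 Σ o_ij e_ij / (n(n−2)(n−3)),  n ≥ 4,

is the part of D̂ that changes under y-permutations; D̂ − Û is a function of
the margins only (verified exactly in the suite), so ranking Û across
permuted datasets is equivalent to ranking D̂ and the two yield identical
tests.

## Permutation protocol

Given B (default 999), the engine draws B uniformly random permutations
σ(b) of the y-labels, re-tabulates (x_k, y_{σ(b)(k)}), evaluates the
statistic on each, and reports rank/(B+1) where rank is the position of the
observed statistic among all B+1 in decreasing order. Since each permuted
dataset preserves both margins (asserted at run time) and is an exact draw
from the conditional null, the test's Type I error is at most α for every n.

Ties are broken at random, implemented by ranking (statistic, jitter) pairs
with iid uniform jitter from the same seeded generator; this is what makes
the size guarantee exact when the statistic's permutation distribution has
atoms. A deterministic alternative, p = (1 + #{T_b ≥ T_obs})/(B+1)
(`tie_break="conservative"`), never decreases p and is offered for users
who need seed-free reproducibility.

All four tests share one vectorized evaluation path: the B permuted tables
are tabulated in a single batch (bincount over offset cell indices), and
each statistic is computed on the (B, I, J) count stack with the expected
counts held fixed — they depend only on margins, which permutation
preserves. The generic `permutation_pvalue` accepts any user statistic and
reproduces the fast path draw-for-draw at the same seed.

Conventions for empty cells keep everything defined on tables with zero
rows/columns: cells with e_ij = 0 contribute 0 to Pearson's χ² (they force
o_ij = 0) and cells with o_ij = 0 contribute 0 to G (the x log x limit).
The χ²-quantile versions always use (I−1)(J−1) degrees of freedom from the
declared dimensions, deliberately inheriting the classical behaviour they
are compared against.

## Fisher's exact test

For 2×2 tables the exact two-sided test is delegated to
scipy.stats.fisher_exact (hypergeometric enumeration, summing the
probabilities of tables no more probable than the observed one). For
general I×J the same ordering is estimated by Monte Carlo: B tables are
sampled from the fixed-margins (multivariate hypergeometric) null via the
identical y-permutation sampler, each table is scored by its null
log-probability (only Σ log o_ij! varies once margins are fixed), and the
observed table is ranked with the same tie-break convention as the
permutation tests. With the conservative tie-break the Monte-Carlo p
converges to the exact "at most as probable" tail, which the suite checks
against the 2×2 enumeration.

## Simulation designs

**Sparse** (default I=5, J=8): base probabilities p_ij ∝ 2^{−(i+j)}
(normalized by (1−2^{−I})(1−2^{−J})), a product distribution whose cell
mass halves per step right or down; the alternative adds ε to cells (1,1)
and (2,2) and subtracts ε from (1,2) and (2,1) (1-based). The perturbation
cancels within each affected row and column, so the marginals are
unchanged and D = 4ε² exactly. Admissible ε must keep p₁₂ − ε and p₂₁ − ε
non-negative (≈ 0.13 at I=5, J=8); the default grid is ε ∈ {0, 0.01, …,
0.10}. This design concentrates the dependence in the *highest*-probability
cells — the regime where Pearson's denominators hurt most.

**Dense** (default I=6, J=8): p_ij = 1/(IJ) + (−1)^{i+j} ε, a checkerboard
on the uniform distribution; with even I, J the marginals stay uniform and
D = IJ ε². The default grid caps ε at 1/(2IJ), half the uniform cell mass.
Here e_ij is nearly constant, Pearson's statistic is essentially a scaled
version of Û's leading term (their Spearman rank correlation across
simulated tables exceeds 0.95), and all four tests perform similarly.

Tables are sampled as multinomial draws of n on the IJ cell probabilities.

## Study drivers, scales and Monte-Carlo error

- `power_study`: per ε and per test, the fraction of `reps` simulated
  tables with p ≤ α, with SE = √(p̂(1−p̂)/reps). At ε = 0 it is a size
  study. Defaults: n=100, reps=500, B=99 (SE ≈ 2% near p̂ = 0.5; a full
  curve runs in seconds); study-quality runs (reps=10⁴, B=999) are plain
  argument changes.
- `estimator_study`: `reps` draws of D̂ per ε via the vectorized closed
  form (violin-plot data), with per-ε means, variances and true D.
- `resample_study`: treats an observed table's proportions o_ij/n as the
  joint, redraws multinomial tables of the same n, reports per-test
  rejection rates.
- `subsample_study`: draws m of the n observations uniformly at random and
  re-tabulates. The default draws **with replacement** (iid from the
  empirical distribution, equivalently a multinomial of size m); this is
  the reading under which the package reproduces the reference rejection
  rates for the bundled survey table (≈ 0.70 for the USP test at m=150).
  True without-replacement subsampling (`replace=False`) is also provided;
  its hypergeometric concentration around the scaled-down table lowers
  every test's rejection rate substantially (≈ 0.52 for the USP test in
  the same setting), so the two readings are *not* interchangeable.

Choosing B=99 instead of 999 coarsens the p-value grid (rejection at
α=0.05 means rank ≤ 5 of 100) and typically costs one to three points of
power; the desk-scale defaults accept this in exchange for ~10× speed, and
all reported comparisons quote the protocol used.

Seeding: every public entry point takes an integer seed; studies derive
independent child generators per ε / sub-study via `SeedSequence` spawning,
so whole studies are bit-reproducible.

## What the synthetic designs do and do not emulate

The generators produce exactly the stated joint distributions with iid
sampling — no overdispersion, clustering, measurement error or missingness,
and fixed (I, J) known in advance. Passing the power/size benchmarks
therefore demonstrates correctness of the statistics and the permutation
protocol under the stated sampling models, not robustness of any test to
non-iid survey data. The two bundled real tables are fixed count matrices;
their "true" dependence is unknown, and the resampling/subsampling studies
characterize test behaviour *around* those observed tables, not ground
truth.

## Numerical choices and degenerate inputs

- Counts are validated as non-negative integers; zero rows/columns are
  retained, never dropped (dropping them silently changes the hypothesis).
- Û requires n ≥ 4 (its coefficients are undefined below); statistics on
  the all-zero table raise a degenerate-table error.
- Probability arrays must sum to 1 within 1e-12; design identities
  (D = 4ε², D = IJε²) hold to 1e-12.
- The closed-form/brute-force agreement tolerance is 1e-9 (absolute);
  float tie comparison in rank-equivalence checks is done in exact rational
  arithmetic, because distinct float summation orders can perturb exact
  ties at the 1e-17 level.
- Fisher Monte-Carlo scores tables by Σ gammaln(o_ij + 1) plus a
  margin-only constant, avoiding underflow of the raw hypergeometric
  probability.
- Permutation batches are chunked so the tiled permutation matrix stays
  within ~16 MB regardless of B.

## Known limitations

- Two-way tables only; no k-way or continuous/functional extensions of the
  U-statistic framework.
- No asymptotic null distribution for Û is provided — the test is purely
  permutation-based by design.
- `dhat_brute` is exponential-cost in practice beyond n ≈ 12 and exists as
  an oracle, not a user path.
- The exact Fisher mode covers 2×2 only; larger tables use Monte Carlo
  (no network algorithm).
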