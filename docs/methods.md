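# Methods

## Probability estimation

A data matrix `D` holds `m` samples (rows) of `n` real-valued variables
(columns); the transpose flag lets the same file be analysed either way
(e.g. genes-as-variables or cells-as-variables). Each variable is binned
into `N_j` equal-width cells on its own observed range `[min_j, max_j]`,
with code `min(floor((x - lo) * N / (hi - lo)), N - 1)`: cells are half-open,
the maximum lands in the last bin, and a value exactly on an interior
boundary goes to the higher bin (forced by the floor rule; documented, not
configurable). Constant variables collapse to a single bin of entropy 0
rather than erroring — real expression matrices contain silent genes.
Atomic probabilities are occupancy counts divided by `m`, so each mass is an
integer multiple of `1/m`; joints are stored sparsely (support ≤ `m`, while
the nominal box count `prod N_j` is astronomically larger). Estimating on a
subset of variables equals marginalizing the full-joint estimate, so every
lattice computation works face-locally.

The default graining is `N = 9` for continuous data of the scale this
estimator targets; every analysis accepts a global or per-variable override,
and the graining/sample-size sweep (`landscape_sweep`) is the tool for
choosing `N` on a given dataset (a pertinent graining sits at a critical
point of the mean information path, inside the regime where `k_u` is not
yet limiting).

## Information measures

All logarithms are base 2 (bits), `0·log 0 = 0`, and zero-probability
conditioning branches are dropped. `I_k` is computed by the alternating
entropy sum over sub-subsets from a cached per-face entropy table rather
than by recursion on conditional informations: each `H_k` is reused by every
superset's alternating sum, and a landscape of all three measures costs one
entropy table. Conditional entropy and conditional interaction information
are computed by direct conditioning (weighted sums over conditioning
outcomes); unit tests verify they equal the entropy-difference and
chain-rule forms to 1e-10 on Dirichlet-sampled joints.

The atomic decomposition `eta_J` (the degree-|J| information of face J
conditioned on the joint of all remaining variables; for J the full set the
conditioning is empty, so `eta_[n] = I_n`) is implemented twice on purpose:
by its conditioning definition, and from an entropy table by Moebius
inversion of `I_k(X_I) = sum over J containing I of eta_J`, expanding each
`I` term through the alternating sum. The two routes agree to 1e-10 and the
reconstruction identities (superset sums giving `I_k`, meeting sums giving
`H_k`) are part of the test suite.

Numerical tolerances: identity and independence checks use absolute 1e-10 on
analytic laws and 1e-9 on empirical estimates; distribution normalization is
enforced at 1e-12.

A dense batched evaluator (`interaction_information_batch`) computes `I_k`
for arrays of small dense laws; it exists for Monte-Carlo sweeps (1e5 laws)
and is cross-checked against the sparse route in tests.

## Landscapes and paths

Faces are enumerated in (degree, lexicographic) order up to a cap `kmax`
(default `min(n, 12)`; the full lattice costs `2^n - 1` faces and a guard
refuses more than 2e6 without an explicit override). The `H`-landscape is
non-decreasing along inclusion chains; `I` and `G` landscapes derive from
the same entropy table.

An information path adds one variable per step; by the chain rule the slope
`I_{k+1} - I_k` equals minus the conditional mutual information of the added
variable given the prefix. Extremal paths take only strictly descending
steps (conditional MI > `tol`); `direction="max"` follows the slowest
descent (argmax of the next value — the ordering that sustains dependence
longest), `direction="min"` the steepest. A path ends at its **first
minimum**: the point where no candidate still descends, i.e. every
continuation's conditional MI has changed sign. This operationalizes the
sign-change stopping criterion symmetrically for both directions.

Design choices that were genuinely open:

- **Search strategy.** The permutation space is `n!`; the default is greedy
  best-first from every starting variable (beam width configurable), with
  an exhaustive enumeration of all descending chains available for
  `n <= 12` as an oracle. On planted-module fixtures the greedy terminal
  value equals the exhaustive optimum (tested).
- **Deduplication and ranking.** Paths that permute the same variable set
  are collapsed to the ordering with extremal cumulative information;
  results are ranked by (length, terminal value), ties to the
  lexicographically smallest sequence.
- **Slope resolution `tol`.** Default 0 (the literal sign-change rule,
  correct for exact laws). Empirical `I` values fluctuate at order `1/m`,
  and with `tol = 0` those fluctuations count as descent and extend paths
  arbitrarily; analyses of sampled data should set `tol` a little above the
  estimation noise (0.01 bits at `m ~ 10^3` in the bundled examples).
- **Terminal collapse.** A maximal path ends *at* its minimum, so its last
  step — a large conditional MI landing at `I ~ 0` — typically drags in one
  unrelated variable (observed as single misclassifications when paths are
  read as clusters). `InfoPath.core_variables(tol)` returns the prefix
  before the collapse; component grouping of top paths uses full supports.
- Paths are reported up to `k_u` by default; behaviour beyond `k_u` is
  deliberately not interpreted.

## Undersampling dimension

Empirical entropies can never exceed `log2 m`, and once a face saturates
(every sample alone in its box) all extensions inherit the value. Per
degree, the fraction of faces with `|H_k - log2 m| <= 1e-9` is recorded
(an exact equality in principle, made a floating comparison); `k_u` is one less
than the first degree whose fraction exceeds `p_u = 0.05`, or `kmax` when
nothing saturates. Landscape fits warn when `kmax > k_u`.

The companion concentration result motivates treating saturation as the
default expectation rather than evidence of structure: for laws drawn
uniformly from the simplex on `r^k` states, the probability that `H_k` falls
at or below `eps·k·log2 r` is at most `eps` for `eps <= 1/e`
(`low_entropy_fraction` estimates this tail by flat-Dirichlet Monte Carlo —
the flat Dirichlet is the uniform measure on the simplex in affine
coordinates).

## Shuffle test of k-dependence

Each column of the discrete matrix is independently permuted, which
preserves every marginal exactly while randomizing the joints. The null for
degree `k` pools the `I_k` values of all `C(n, k)` faces over `n_shuffles`
shuffles (default 17) — a global test; per-face exact nulls would need
orders of magnitude more shuffles. Thresholds are empirical
(inverted-CDF) quantiles: one-sided upper at `p2 = 0.05` for `k = 2`
(where `I_2 >= 0`), symmetric two-sided splitting `pk = 0.1` equally
between tails for `k >= 3`. A flagged face means its dependence is
*specific* relative to random marginal-preserving dependence at that sample
size — not that independence is rejected in the strict sense; finite-sample
shuffled `I_k` distributions are themselves biased away from zero, which is
exactly what the pooled null absorbs.

## Synthetic fixtures: what they emulate, and what they do not

The generators provide data with fully known information structure: the
extremal three-bit laws (identical/opposite bits at `I_3 = +1`; the two
parity laws at `I_3 = -1`, pairwise independent — the unique minimizers,
since `I_3 = -1` forces unbiased, pairwise-independent bits supported on a
fixed parity class), product-uniform laws and i.i.d. samples from
them, stationary Markov-chain joints (initial law = stationary law of the
kernel), planted modules (noisy copies of a latent source among independent
columns; each entry resampled independently with probability `copy_noise`),
two-block variants with separate sources, and flat-Dirichlet simplex draws.
Continuous fixtures smear integer codes uniformly inside unit cells so the
binning path is exercised end to end.

Defaults used in the bundled tests were chosen as realistic desk-scale
conditions and fixed: module/block sizes 3–5 among 6–10 variables,
`copy_noise` 0.05–0.1, `m` 1000–2000 samples, binary alphabets for fixtures
(the graining default of 9 targets continuous data). These fixtures have
i.i.d. rows, sharp module boundaries and uniform marginals; real expression
data has skewed marginals, dropout, correlated sampling and soft modules,
so passing tests demonstrate correctness of the estimators and search, not
that any particular biological dataset is well resolved at these `m`, `N`.

## Known limitations

- Equal-width binning only; no adaptive/equal-frequency graining or density
  estimation.
- The full lattice is `O(2^n)`: practical to `n ~ 20` only with capped
  `kmax`; the greedy path search is a heuristic above `n = 12`.
- The shuffle null is pooled per degree, not per face; individual-face
  p-values are not provided.
- `I_k` estimates are biased at finite `m`; no bias correction is applied —
  the undersampling dimension and shuffle test bound the interpretable
  regime instead.
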