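# infolattice

Higher-order information analysis of tabular measurements: joint entropies,
multivariate mutual information and total correlation computed on **every
subset of variables** (the simplicial lattice), with information landscapes,
extremal information paths, an undersampling diagnostic and a
marginal-preserving shuffle test of k-dependence.

The package is aimed at systems-biology style data — expression of *n* genes
across *m* cells, activity of *n* units across *m* trials — where pairwise
statistics miss collective structure: groups of variables can be pairwise
independent yet strongly dependent as a group, and modules of co-varying
variables only stand out at the degree of the module.

## The quantities

Measurements are binned (equal-width, `N` bins per variable on its observed
`[min, max]` range) and joint probabilities estimated by counting. All
information values are in bits. For a subset of variables
`X_I = (X_{i1}, ..., X_{ik})`:

- **Joint entropy** `H_k(X_I) = -sum_x p(x) log2 p(x)`.
- **Interaction information**
  `I_k(X_I) = sum over non-empty T within I of (-1)^(|T|+1) H(X_T)` —
  the alternating inclusion–exclusion sum of joint entropies. `I_1 = H`,
  `I_2` is Shannon mutual information, and for `k >= 3` the sign is
  informative: `I_k > 0` flags shared correlation, `I_k < 0` flags synergy —
  dependence invisible in every lower-dimensional projection (for three
  unbiased bits the extremes are exactly `+1` for identical variables and
  `-1` for the XOR/parity configuration).
- **Total correlation** `G_k(X_I) = sum_i H(X_i) - H(X_I)`, non-negative and
  zero exactly on independent laws.
- The variables are jointly independent **iff** all `2^n - n - 1` values
  `I_k, k >= 2` vanish.

The *landscape* of a measure is its value on every face of the lattice,
organised by degree. An *information path* adds one variable at a time; the
step slope is minus a conditional mutual information, so paths descend while
the added variable still shares conditional information with the prefix and
end at their **first minimum** (a conditional-independence criterion).
Finite samples impose `H_k <= log2 m`; the **undersampling dimension**
`k_u` is the last degree at which saturated faces remain rarer than 5%, and
significance of individual `I_k` values is assessed against a pooled null of
column-shuffled (marginal-preserving) replicates.

## Worked example

Two latent sources, four noisy copies of each (8 variables, 1000 samples) —
the model recovers the two modules blindly:

```python
import infolattice as il

matrix, labels = il.synthetic.two_population_samples(
    (4, 4), 1000, seed=5, block_strengths=(0.05, 0.05))
res = il.InformationLattice(matrix, n_bins=2).fit()
print(res.summary())
```

```
Information lattice analysis
============================================================
samples (m): 1000    variables (n): 8
graining (N): [2, 2, 2, 2, 2, 2, 2, 2]
lattice dimension cap (kmax): 8
undersampling dimension (ku, p_u=0.05): 8

per-degree summary (bits):
 k  faces  mean_H  mean_I   max_I   min_I        argmax_I  saturated
 1      8  0.9995  0.9995  1.0000  0.9985               7     0.0000
 2     28  1.6998  0.2993  0.7352  0.0000             6;7     0.0000
 3     56  2.1896  0.0888  0.6392 -0.0025           0;2;3     0.0000
 4     70  2.5395  0.0182  0.5941 -0.0011         4;5;6;7     0.0000
 5     56  2.8035  0.0014  0.0057 -0.0031       1;3;4;5;7     0.0000
 ...
```

Every variable carries ~1 bit (`mean_H` at k=1); the degree-4 argmax face
`4;5;6;7` is exactly one planted block, and mean information collapses to ~0
beyond k=4 — dependence lives inside the blocks, not across them. The two
longest maximal information paths recover both blocks:

```python
for p in res.paths(direction="max", tol=0.01)[:2]:
    print(p.variables, [round(v, 3) for v in p.values], p.stop_reason)
```

```
(3, 2, 0, 1, 5) [1.0, 0.735, 0.639, 0.582, -0.001] first-minimum
(7, 6, 4, 5, 3) [1.0, 0.735, 0.637, 0.594, -0.001] first-minimum
```

Each path sustains high information through its own block, then collapses to
~0 on the first foreign variable and stops; `p.core_variables(0.01)` drops
the collapsed step and yields the exact blocks `{0,1,2,3}` and `{4,5,6,7}`.

The same pipeline is scriptable from a shell:

```sh
infolattice simulate --kind two-population --n 8 --m 1000 --seed 5 --out data.csv
infolattice run data.csv -N 2 --outdir report/
```

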