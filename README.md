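# seqsector

**Do statistical-coupling-analysis sectors predict functional residues any
better than plain sequence conservation?**

Statistical coupling analysis (SCA) combines pairwise correlations in a
multiple sequence alignment with conservation-derived positional weights
into a matrix whose leading eigenvector defines a "sector" — a group of
putatively coevolving, functionally important residues. For proteins with
a single sector, however, the top eigenvector of the SCA matrix tracks the
matrix's own diagonal (a single-site quantity), so sector membership is
largely a restatement of conservation. `seqsector` implements the full
analysis needed to make — and stress-test — that comparison:

- projection-method SCA (positional weights, projected alignment,
  absolute-covariance SCA matrix, spectral decomposition, top-eigenvector
  sector at the ~25% rule);
- relative-entropy conservation with the gap-aware background convention;
- the statistical battery comparing sector against equally sized conserved
  sets on mutational data (one-tailed Fisher exact enrichment, χ²
  homogeneity of contingency tables, two-sided Mann–Whitney *U* on effect
  distributions, sector-size sweeps, eigenvector regression of phenotypes);
- the structural "touching" criterion for domain-insertion experiments
  (fixed-radius spheres on the four peptide-bond atoms) and conservation
  versus distance from the protein's core;
- an idealized model of the SCA matrix's top eigenmode explaining the
  diagonal-dominated top eigenvector, with the scaling experiment that
  separates sampling noise from phylogenetic bias;
- seeded synthetic generators (independent columns, planted co-varying
  sector, star phylogeny) so every stage is testable without downloads.

## The core quantities

Conservation of column *i* is the Kullback–Leibler divergence (in nats)

    D_i = Σ_a f_i(a) ln[ f_i(a) / q(a) ],

where `f_i(a)` is the column frequency of amino acid *a* (gap included)
and `q` a database background whose gap entry is the alignment-average gap
fraction. The projection method maps alignment cell `a_ki` to

    x̃_ki = φ_i(a) f_i(a) / sqrt(Σ_{b≠gap} φ_i(b)² f_i(b)²),   x̃ = 0 at gaps,

with log-odds weights `φ_i(a) = ln[ f_i(a)(1−q(a)) / ((1−f_i(a))q(a)) ]`,
and the SCA matrix is the element-wise absolute value of the population
covariance of `x̃`. The sector is the top quarter of columns by
top-eigenvector loading. The idealized eigenmode model
`M_ij = x·sqrt(Δ_i Δ_j)` (i≠j), `M_ii = Δ_i` yields
`λ_top ≈ x/(1+x)·ΣΔ_i` and `v_top ∝ sqrt(Δ_i)` — the reason the sector is
conservation-dominated whenever the off-diagonal entries carry a uniform
positive bias, e.g. from taking absolute covariances.

## Worked example

```python
from seqsector import SCA, GeneratorSpec, backgrounds, sample_independent_alignment
from seqsector.simulate import heterogeneous_profile, sample_mutational_effects

profile = heterogeneous_profile(100, seed=0)          # conservation levels
spec = GeneratorSpec(kind="independent", N=500, n=100, seed=0,
                     conservation_profile=profile)
aln = sample_independent_alignment(spec)

res = SCA(aln, background=backgrounds.uniform_background()).fit()
print(res.summary())

data = sample_mutational_effects(res.conservation, noise_sd=0.25, seed=0)
cmp = res.compare_with_conservation(data)
print(f"overlap: {cmp['overlap']:.2f}  Mann-Whitney p: {cmp['p_mannwhitney']:.3f}")
```

prints

```
Statistical coupling analysis (projection method)
=================================================
sequences (N):            500
columns after filtering:  100
top eigenvalue:           0.8844
second eigenvalue:        0.3413
sector size (25% rule):   25
r(v_top, sqrt diag):      0.9622
r(v_top, conservation):   0.8807
overlap: 0.68  Mann-Whitney p: 0.193
```

The top eigenvector correlates at r ≈ 0.96 with the square root of the
SCA-matrix diagonal even though the alignment has *no* correlations
between columns — the conservation-dominated top mode. The sector and the
equally sized most-conserved set share 68% of their positions, and the
Mann–Whitney test finds no difference between their mutational-effect
distributions (p = 0.19): on single-sector data, conservation predicts
function as well as the SCA sector.

A command-line pipeline mirrors the library
(`seqsector simulate|conserve|sca|compare|touch|theory|all`); see
`seqsector --help`.

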