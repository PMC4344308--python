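# Methods

## The analysis

`seqsector` asks a narrow, well-posed question about statistical coupling
analysis (SCA): for proteins in which SCA identifies a single sector, does
the top-eigenvector sector carry functional information beyond what
per-column conservation already provides? The package implements both
halves of the comparison — the SCA pipeline and the conservation
baseline — plus the statistical battery that adjudicates between them,
and a mechanistic model of why the two are so entangled.

### Conservation

Conservation of alignment column *i* is the relative entropy
D_i = Σ_a f_i(a) ln(f_i(a)/q(a)) over the 21-symbol alphabet (20 amino
acids + gap), in nats. Natural logarithms are used throughout: any other
base rescales every D_i by the same constant and leaves all rankings and
set selections unchanged.

The sum over symbols includes the gap, which forces a background gap
frequency. The default (`average_gap`) sets q(gap) to the alignment-wide
mean column gap fraction and rescales the 20 amino-acid background
entries by 1 − q(gap); the alternative (`ignore_gap`) renormalises each
column over its non-gap cells and sets q(gap) = 0. The two agree exactly
on gap-free alignments and, in practice, give very similar rankings
elsewhere.

The 20-amino-acid background is the Robinson–Robinson database-average
table; a uniform background (0.05 each) is available so that numeric
tests are self-contained, and any user table can be supplied. Results on
real alignments depend mildly on this choice; all synthetic results in
the test suite use the uniform background.

### Projection-method SCA

Columns with 40% or more gaps are removed first (the threshold is
inclusive and configurable). The positional weights are the log-odds
φ_i(a) = ln[f(1−q)/((1−f)q)] for the 20 amino acids; the weight diverges
at frequencies 0 and 1, so frequencies are clamped to [ε, 1−ε] with
ε = 0.001 before the logarithm — the minimal regularisation that leaves
the weight exact everywhere else. The weights compare column frequencies
against the *amino-acid* database background: when the 21-symbol
background has been gap-rescaled for the conservation formula, the
amino-acid part is renormalised back to a proper distribution before
computing φ.

Each alignment cell is collapsed to the single number
x̃_ki = φ_i(a)f_i(a)/‖φ_i f_i‖ (zero at gaps; a column whose weighted
frequency vector vanishes — e.g. every frequency at background — projects
to zero with a logged warning). Column frequencies are gap-inclusive in
both the numerator and the normalisation; this is the one place the
formula is underdetermined, and the choice is pinned by a brute-force
oracle test. The SCA matrix is the element-wise absolute value of the
*population* covariance (divisor N) of the projected alignment.

Eigenvectors are unit-norm with the sign fixed so the component sum is
nonnegative, making sector extraction deterministic. The sector is
rank-based: the round(0.25·n) columns with the largest top-eigenvector
components (half-up rounding; ties to the lower column index). A
rank-based rule is preferred to a numeric loading threshold because it is
deterministic and matches the stated outcome — a sector of about a
quarter of the positions (82 of 328 for the lac repressor, 21 of 84 for
the PDZ alignment).

### The comparison battery

Functional sites are called by an explicit rule: |effect| ≥ threshold
(e.g. a free-energy shift of at least 1 kcal/mol) or a loss-of-function
substitution count ≥ threshold (default 8, sweepable 1–10). The battery
then compares the sector against the equally sized most-conserved set:

- **Fisher exact (one-tailed).** The exact hypergeometric upper tail of
  the in-set functional count — the enrichment direction. Degenerate
  margins return p = 1 with a warning.
- **χ² between two contingency tables.** The two tables share their
  universe, so comparing all four cells would double-count the out-of-set
  row; instead the two in-set (functional, not-functional) rows form a
  2×2 homogeneity layout with 1 degree of freedom. No continuity
  correction by default; a Yates option is provided since published
  analyses rarely state the convention.
- **Mann–Whitney U (two-sided)** on the per-position effect
  distributions of the two sets. Exact enumeration when both sets have at
  most 8 members and the data are tie-free; otherwise the normal
  approximation with tie correction and no continuity correction (so
  identical samples give exactly p = 1). The sector and the conserved set
  typically overlap 60–80%; they are compared as given, which means the
  samples are not independent — a caveat inherent to the original
  analyses and documented rather than "fixed", since disjointifying the
  sets would change the question being asked.
- **Size sweep** and **eigenvector regression** (OLS of per-position
  phenotypes on top-eigenvector components plus intercept, reporting R²)
  complete the battery.

No multiple-testing correction is applied across sweeps, matching the
analyses being reproduced.

### Structural touching

For domain-insertion experiments the perturbation acts at the peptide
bond preceding the insertion residue. Spheres of radius 4 Å (3 and 5 Å
for robustness) are centred on the four peptide-bond atoms; a residue
touches the site if any heavy atom falls within any sphere (inclusive).
The identity of the "four atoms" is not standardised; this implementation
uses C and O of the preceding residue and N and Cα of the insertion
residue, since the amide hydrogen is absent from X-ray structures. The
centre-of-mass analysis uses the unweighted mean over heavy atoms
(geometric centre) and residue heavy-atom centroids; mass weighting and a
Cα variant change distances negligibly at this resolution.

### The idealized top eigenmode

The absolute value in the SCA matrix gives its off-diagonal entries a
positive bias even for uncorrelated columns. The idealized matrix
M_ii = Δ_i, M_ij = x·sqrt(Δ_i Δ_j) captures this with a single
off-diagonal scale x. The eigenvalue equation gives the exact
self-consistency relation v_i(λ − Δ_i(1−x)) = x·d_i·Σ_j d_j v_j
(d = sqrt(Δ)); when λ_top dominates every Δ_i this yields
λ_top ≈ x/(1+x)·ΣΔ_i and v_top ∝ sqrt(Δ_i). The printed closed form of
the intermediate relation is typographically ambiguous in its source, so
the implementation tests the relation re-derived directly from the
eigenvalue equation, which reduces to the sqrt-Δ form in the λ ≫ Δ limit.
For uniform Δ = c the matrix is c(1−x)I + cx·11ᵀ with top eigenvalue
c(1+(n−1)x) exactly, which anchors the approximation's error band
2(x + 1/(nx)) used in the tests.

The off-diagonal scale is estimated from a real SCA matrix as
x̂ = mean_{i<j} C̃_ij/sqrt(C̃_ii C̃_jj). Its dependence on alignment
depth N distinguishes two origins: pure sampling noise makes x̂ decay
(the measured exponent is ≈ −0.5, consistent with the N^(−1/2) magnitude
of sample-covariance fluctuations; the exponent is reported, not asserted
against −1), while genuine uniform correlations such as shared ancestry
keep x̂ approximately flat. The experiment fits log x̂ against log N by
least squares over the ladder N ∈ {200, 400, 800, 1600} (n = 60 columns,
5 replicates per depth); the ladder starts at 200 so the sampling-noise
floor sits below the ancestry plateau of the phylogeny generator.

## Synthetic data

The generators produce the statistical regimes the analysis must
distinguish; all take explicit integer seeds and no global random state.

**Independent columns.** Column *i* emits one dominant residue with
probability p_i and spreads the remainder uniformly over the other 19
amino acids. The default heterogeneous profile draws p_i uniformly on
[0.05, 0.5] — from the background level (no conservation) up to one half,
the diversity regime of deep homolog alignments. This range is also where
this emission model's projected column variance (≈ p(1−p) after the
self-normalising projection) grows monotonically with conservation; above
one half the variance falls again, a regime real alignments escape
because their residual amino-acid distributions are not uniform. Study
conditions therefore stay below 0.5, and the "heterogeneity" ladder in
the spectral-gap test widens the profile range upward from the background
level rather than spreading it symmetrically.

**Planted sector.** Each sequence carries a hidden binary state; within a
designated column group the state shifts the dominant-residue frequency
to p ± δ with δ = coupling·min(p, 1−p). Two properties are built in by
construction: the column *marginal* is exactly the independent model's
(states are equiprobable), so planted columns are indistinguishable from
background by conservation and coupling = 0 reproduces the independent
generator bit-for-bit at the same seed; and the modulation acts on the
*frequency* of a single dominant residue rather than swapping two
symmetric residues, because the projection collapses any two residues
with equal column frequency to the same value — a symmetric swap would be
statistically invisible to SCA. The price of exact marginal preservation
is that emission stays stochastic even at coupling 1, so within-sector
amino-acid correlations saturate below 1 (indicator correlation 2/3 at
p = 0.4) rather than reaching it. States are assigned as a random
permutation of an exactly balanced vector rather than i.i.d. coin flips:
with i.i.d. states the random state imbalance shifts all sector columns'
empirical conservation coherently, which both adds a spurious rank-one
component and makes the (independence-assuming) Mann–Whitney comparison
of conservation values anti-conservative. The default width for the
planted-sector end-to-end setting is n = 400 columns with a 20-column
sector at N = 1000: wide enough that the global positive-bias mode stays
above the planted block mode, so the block appears in a subleading
eigenvector (empirically eigenvector 2), mirroring the multi-sector
reading in which the top mode is discarded as global.

**Star phylogeny.** A few ancestors (default 5) are drawn from the
independent model; each sequence copies a random ancestor and redraws
each position with probability `mutation_rate` (default 0.1). This
creates weak, uniform correlations across all columns whose magnitude
does not decay with N. `mutation_rate = 1` reproduces the independent
generator exactly.

**Mutational effects.** Per-position effects are a monotone function of
conservation plus Gaussian noise (default: identity link, sd 0.25 — about
half the 0–0.57 nat signal range at the default profile), emulating
datasets in which conservation predicts functional impact. The
noise-free, identity-link case makes the functional set equal the
top-conserved set exactly, which anchors the tests.

### What the generators do and do not emulate

The generators reproduce heterogeneous conservation, block correlations
and uniform phylogeny-like correlations — the three statistical
ingredients of the analysis. They do **not** emulate: gaps (synthetic
alignments are gap-free; gap handling is tested on hand-built
alignments), realistic amino-acid substitution preferences, tree-shaped
phylogenies, or the residue-residue dependence of real mutational scans.
Passing tests therefore establish that the implementation behaves
correctly in the stated regimes, not that real proteins satisfy those
regimes; real-data conclusions also depend on the unpublished background
frequency table and on alignment construction, both outside this
package's scope.

## Numerical choices

- Frequency clamp ε = 0.001 in the positional weights; configurable.
- Rounding half-up for the sector size; ties in any ranking break toward
  the lower column index; eigenvector orientation by nonnegative
  component sum.
- KL terms with f = 0 contribute zero; f > 0 with q = 0 is an error
  naming the column and symbol.
- Exact/asymptotic switch for Mann–Whitney at 8 per side (configurable);
  no continuity correction in the normal approximation.
- χ² on identical in-set rows short-circuits to p = 1 (statistic is
  exactly zero); zero expected cells report a missing value.
- Population covariance (divisor N); matrices symmetrised against
  roundoff before eigendecomposition.

## Problem sizes

Simulation-based tests run at N = 500–1000 sequences and n = 60–400
columns with 5–100 seeded replicates per property; these sizes put
sampling fluctuations well below the effect sizes being asserted while
each test completes in seconds.

## Known limitations

- Single-chain, first-model structure handling; no solvent accessibility
  or surface-site determination (surface sites are an experimental input).
- No sequence-identity reweighting of alignments; no ICA rotation or
  multi-eigenvector sector definitions.
- The statistical battery inherits the independence assumptions of its
  tests; positions in a protein are not independent samples, and no
  evolutionary-model-based correction is attempted.
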