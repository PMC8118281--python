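# Methods

## Synthetic study design

The generator emulates a two-cohort facial-genetics study: a
family-structured sibling cohort used only for biometric matching and trait
derivation, and a larger cohort of unrelated individuals that defines the
reference segmentation and shape spaces, is scored on the traits, and is the
GWAS sample. Both cohorts are drawn from one generative model so
genotype–phenotype links are consistent across stages.

**Template.** Landmarks are sampled on an ellipsoid-like surface (axes
70 × 90 × 55 mm, i.e. wider than deep) and mirrored across the x = 0 plane;
the left/right pairing map is an explicit involution. The template is
exactly bilaterally symmetric by construction.

**Genotypes.** Per SNP, a minor-allele frequency is drawn uniformly from
`maf_range` (default 0.05–0.5). Unrelated individuals are binomial(2, MAF)
draws. Siblings receive one allele from each of two simulated parents with
probability `parent_dosage / 2` per transmission — true Mendelian hard
calls, giving expected sibling dosage correlation 0.5 rather than imposing
it through a correlated-Gaussian shortcut. A small leading block of SNPs is
labeled chromosome X to exercise the male 0/2 recoding; the remainder cycle
chromosomes 1–22 with sorted uniform positions.

**Faces.** Each face is

    X_i = T + Σ_k u_ik · s · B_k + C_i · c · D + ε_i

with `T` the template, `B_k` unit-Frobenius-norm displacement fields, `s`
the factor scale (`factor_scale`, default 2 mm per latent SD), covariate
effects `D` (same construction, scaled by `covariate_effect_scale`), and
isotropic landmark noise `ε` (`noise_sd`, default 0.5 mm). Displacement
fields are Gaussian radial basis functions centered at random template
points with bandwidth 0.3 × template diameter — spatially coherent, hence
segment-localizable — and are symmetrized with the pairing map so their
effect survives extraction of the symmetric shape component.

Latent factor values decompose as `u = √g·a + √(1−g)·e` with
`g = genetic_variance_fraction` (default 0.6). The additive-genetic part `a`
is itself a mixture `√c·(causal SNP score) + √(1−c)·(polygenic)` with
`c = causal_variance_fraction` (default 0.5 when causal SNPs exist). The
polygenic part uses parent-midpoint plus segregation sampling
(`mid + N(0, ½)`), so both components carry sibling correlation 0.5; the
empirical sibling latent correlation converges to 0.5 (checked at 1,000
families within ±0.05), and the genetic/environmental variance split matches
`g` within 10% at n ≥ 2,000.

**Covariates.** Sex (binary), age (uniform 5–15 y, a pediatric sibling
cohort), height, weight, and a two-level camera label acting as a batch
effect. Each covariate drives its own RBF displacement field, which is what
makes the PLSR adjustment testable.

**Cohort sizes.** The default family-size distribution
{2: 163/194, 3: 28/194, 4: 1/194, 5: 2/194} reproduces a 424-child,
194-family sibling cohort containing 273 unique pairs, the bookkeeping the
matching stage assumes (546 experiments per segment, two per pair). Tests
that need a particular statistical property scale sizes to that property:
e.g. the CMC-above-diagonal check uses 200 families (~574 experiments) so
the binomial comparison at rank-1% is decisively powered, with signal
parameters (variance fractions, factor scale, noise) untouched.

**What the generator does not emulate.** Texture/appearance, facial
asymmetry, scanning artifacts, linkage disequilibrium between SNPs
(genotypes are independent per SNP given the pedigree), population
stratification, and non-additive genetic effects. Passing tests therefore
demonstrate correctness of the machinery under an additive, LD-free,
symmetric-face model — not performance claims about real imaging data.

## Alignment and confounder adjustment

GPA iterates translation removal, optional unit-centroid-size scaling, and
batched orthogonal-Procrustes rotation onto the running consensus until the
consensus RMS change falls below 1e-8 (maximum 100 iterations; convergence
is typically 2–3 iterations). The output orientation is canonicalized to the
consensus principal axes with third-moment sign fixing, making the result
invariant to a global similarity transform of the inputs.

Symmetrization pools originals with their reflected-relabeled copies in one
GPA whose consensus is projected onto the bilaterally symmetric subspace
each iteration. With a symmetric consensus, the optimal rotation of a
reflected copy is exactly the reflection-conjugate of the original's
rotation, so the averaged symmetric component is mirror-symmetric to
machine precision — a property the tests assert at 1e-10. The asymmetric
component (original minus reflection) is computed implicitly and discarded.

PLSR residualization uses centered, unscaled PLS (matching the common
`plsregress` convention) with the component count defaulting to the
covariate design rank, which makes it equivalent to multivariate OLS
residualization — the conservative choice given that no component count is
canonical. Residuals keep the response mean (`Y − Ŷ + mean(Y)`) so adjusted
shapes remain shapes. Constant covariate columns are dropped with a warning;
requesting more components than the design rank reduces the count with a
warning. The identical routine residualizes genotype dosages in the GWAS
stage, after X-chromosome males are recoded 0/2.

Facial size enters the confounder design as pre-scaling centroid size, the
GPA-native size measure.

## Segmentation and shape spaces

Landmark similarity is Escoufier's RV coefficient between the two
landmarks' 3-column coordinate blocks across individuals, computed from
cross-covariance Frobenius norms in a single einsum pass. RV is in [0, 1],
equals squared Pearson correlation in the univariate case, and is undefined
(an error, not 0) for zero-variance blocks.

Bisection uses the symmetric normalized Laplacian
`L = I − D^{−1/2} S D^{−1/2}`; the Fiedler vector is split by 2-means
(10 restarts, seeded). Since 1-D k-means clusters are contiguous, the split
is a cut point in Fiedler order; the cut is clipped so each child retains at
least `2^(remaining_depth − 1)` landmarks whenever the node is large enough
to host a full subtree, and falls back to the median cut when the clustering
degenerates. This guarantees the full `2^(d+1) − 1` segments (63 at depth 5)
for any cohort with at least `2^d` landmarks, while preserving the spectral
geometry of well-separated splits (planted two-block similarity matrices
are recovered exactly). Nodes that cannot split stop early, are flagged
`truncated`, and warn.

Per segment the cohort's landmarks are re-aligned by GPA before PCA;
parallel analysis (default 100 column-permutations, 95th percentile)
chooses the retained dimension count, contiguous from the top, with a floor
of 1 and a cap at the numerically positive eigenvalues. Segments need at
least 3 landmarks to carry a space (2-point shapes are all identical after
scaling); at full scale (thousands of landmarks) this bound is never
active. Other cohorts enter a segment space by per-individual Procrustes
fit onto the stored segment consensus followed by projection onto the
retained eigenvectors.

## Matching, traits, GWAS

Similarity values are "lower is more similar"; angles are radians measured
from the shape-space origin (the reference mean). σ-normalization uses the
reference-space standard deviations `√λ_k`, configurable in principle but
fixed here because projected cohorts live in the reference space. Ties in
ranking receive the maximal competition rank (pessimistic, deterministic)
and are flagged. Rank-k% membership is `rank / gallery_size ≤ k/100` with
no rounding. Feature-level fusion concatenates per-segment (optionally
σ-normalized) scores in fixed segment order before applying the Euclidean
formulas.

Trait selection requires, in both query directions: top-1% rank ratio and a
similarity value within the lowest 2.5 percentile of the segment's pooled
query-to-candidate similarities (the pool choice — all candidate
comparisons rather than sibling pairs only — is the implemented reading;
the percentile is applied per segment). Several pairs from one family are
kept as separate traits; Meff is the sole independence correction, with the
integer snap guard (eigenvalues within 1e-9 of an integer are rounded
before the floor) protecting the fractional-part rule from floating-point
noise. Degenerate traits (opposite siblings averaging to the zero vector)
are errors.

The association engine is closed-form simple OLS (`β = cov/var`,
`SE = √(RSS/(n−2)/Sxx)`, two-sided t on n−2 df), vectorized over the
SNP × trait grid and verified against the matrix solver at 1e-10.
Meta-analysis is fixed-effects IVW of effect estimates (weights 1/SE²);
a sample-size-weighted Stouffer z is available as a sensitivity option.
Peak grouping is greedy lead-first on a 1-Mb center-to-center window within
chromosome, order-independent by construction (deterministic tie-breaks on
p, then position and id); an optional gap-merge approximates manual
LD-based merging of adjacent regions and is off by default since no LD
exists in the simulated genotypes. p-values are floored at the smallest
positive double rather than reported as 0.

## Pipeline and interfaces

`run_pipeline` chains the stages, writes TSV/VCF/JSON artifacts plus an
`.npz` array container for shape spaces and trait vectors, and records a
manifest with SHA-256 hashes per stage; identical configs produce
byte-identical TSV outputs. The CLI (`sibface simulate|preprocess|segment|
match|traits|gwas|run-all`) is a thin wrapper with exit codes 0/1/2
(ok / user error / internal). Genotype interchange uses uncompressed VCF
(GT hard calls written, GT or DS read via cyvcf2); PLINK binary I/O is not
provided.

## Problem sizes used in the shipped checks

Unit and acceptance tests run on scaled-down cohorts chosen as the smallest
sizes at which each statistical property is decisively testable: 100
landmarks / 500 unrelated individuals for segmentation and matching checks,
1,000–2,000 families for kinship-correlation convergence, n = 3,000 with
300 SNPs for the planted-SNP power check (20 replicates), and 2,000 null
regressions for type-I calibration. The full-scale design (7,160 landmarks,
~8,000 genotyped individuals, millions of SNPs) is outside what a
single-machine test suite should carry, and none of the shipped numbers are
performance claims at that scale.

## Known limitations

- Spectral bisection is one of several defensible readings of
  "hierarchical spectral clustering"; Laplacian variant, split rule and the
  balance floor are configurable in code but alternatives are not exposed
  end-to-end.
- The trait-selection similarity pool and the per-segment application of
  the 2.5-percentile filter are implementation choices where the procedure
  admits more than one reading; both are isolated behind
  `select_pairs` parameters.
- VCF handling covers GT/DS dosage fields of well-formed files; it is not a
  general-purpose variant-annotation reader.
- The identification stage recomputes galleries per experiment; at cohort
  sizes far beyond ~10⁴ individuals a blocked implementation would be
  needed.
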