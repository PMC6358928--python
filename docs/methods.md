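# Methods

This note records the statistical models behind each module, the defaults
and why they were chosen, what the simulator does and does not emulate, and
the numerical conventions that matter when comparing output against other
software.

## Data model and formats

Diploid microsatellite genotypes are unordered allele pairs with positive
integer codes; a missing genotype is a distinct sentinel (never allele 0).
Genepop files are parsed in the classic dialect (2- or 3-digit alleles,
`pop` in any capitalisation, comma or whitespace after the id); any
all-zero allele field, including half-missing codes such as `001000`, is
treated as a fully missing genotype so no phantom allele can enter counts.
On write, the id column carries the sampling-location label on every line
(common Genepop practice), which is what makes a write→read round trip
recover the group structure; individual ids are not representable in the
format and do not survive. Allele codes are opaque labels everywhere except
the stepwise mutation models of the bottleneck module, where the integer
value is the repeat score. Site coordinates are planar meters internally;
lon/lat inputs are converted to pairwise meters by the haversine formula at
computation time.

## Diversity statistics

* **Na** counts distinct non-missing alleles; a locus with no data in a
  group is reported absent, not zero.
* **Rs** is the El Mousadik & Petit rarefaction estimator
  `Σ_a [1 − C(N−N_a, g)/C(N, g)]`, evaluated in log-gamma space. The
  rarefaction size `g` defaults to the per-locus minimum gene count over
  the compared groups (the behaviour of the classic F-statistics programs),
  not a global constant, so loci with different missingness are each
  rarefied as deep as their own data allow.
* **Hs** is Nei's unbiased gene diversity `n/(n−1)(1 − Σ p²)` with `n` in
  genes. The frequency-only form is the default because it depends on the
  data only through allele frequencies; program variants that add an
  observed-heterozygosity correction differ in the third decimal.
* Summary rows use the sample SD (n−1). Group differences are tested with
  Kruskal–Wallis on the per-locus values (midranks, tie correction).
* **Hd** is the unbiased haplotype diversity; **Nd** is per-site nucleotide
  diversity `2 n/(n−1) Σ_{i<j} f_i f_j d_ij / L` with alignment columns
  containing a gap or N excluded pairwise.

## Differentiation machinery

The exact Hardy–Weinberg test uses Levene's conditional distribution of
genotype tables given allele counts; tables are fully enumerated for ≤ 4
alleles and sampled by random gene pairing otherwise. Being an exact
conditional test its p-values are discrete and slightly conservative —
the test suite checks validity (level ≤ nominal) rather than exact
uniformity, which no implementation of this test can deliver.

The genotypic differentiation test crosses unordered genotype classes
(heterozygotes pooled, A/B ≡ B/A) with the two groups — genotype rather
than allele tables, because colony-level structure expresses itself in
genotype frequencies. The permutation null reallocates individuals between
the groups preserving sizes; both table margins are then fixed, so expected
counts are constant and the whole null distribution is vectorised. All
permutation p-values use the add-one estimator `(b+1)/(n_perm+1)`: p is
never zero and the test is exact-level at conventional alphas. The default
permutation count is 10,000 everywhere for consistency.

Per-locus p-values for a pair of locations are combined with Fisher's
method (df = 2 × informative loci; a permutation p of 0 would be clamped to
`1/(n_perm+1)` with a warning, though the add-one estimator never produces
one).

θ is the Weir & Cockerham (1984) ratio-of-sums estimator over loci and
alleles; missing data are excluded locus-wise, and the tests verify it
against an independently arranged mean-squares (ANOVA) implementation.

## Colony delineation

Locations are merged when their combined p ≥ α/(number of pairs)
(Bonferroni over the pairs actually compared, i.e. per site — this matches
adjusted thresholds of the order 0.05/105 for 15 locations; Holm is
available by flag). Merging is single-linkage over the non-significant
pairs: a chain A–B, B–C of non-significant comparisons places A, B, C in
one colony even if A–C is significant, and every such triangle
inconsistency is listed in the partition report rather than silently
absorbed.

## Family-type classification

Decision order per colony: (1) more than four alleles at any locus →
mixed; (2) otherwise any locus incompatible with every candidate parental
pair, or a significant across-loci Mendelian G-test → extended; (3)
otherwise simple. Compatibility certificates at a locus are > 4 alleles,
> 4 genotype classes, or ≥ 3 homozygote classes. Candidate parental pairs
are enumerated over the observed alleles; the pair used for the G-test
maximises the multinomial likelihood, with ties broken toward fewer
distinct parental alleles then lexicographic order (deterministic,
parsimony-favouring). Expected classes are the chosen pair's Mendelian
ratios; classes with expected count < 1 are pooled with the smallest-E
remaining class; Williams' correction is applied per locus — without it
the summed G at 20 workers rejects at ~6.5% instead of 5%, with it the
measured type-I error is ~4.5%. df = Σ (classes after pooling − 1); loci
whose chosen pair produces a single offspring class contribute nothing.
Loci with fewer than 10 scored workers provide evidence flags but are kept
out of the G-test (small-sample G is anti-conservative); α is applied per
colony with no sequential correction. An extended call with ≤ 3 alleles at
every locus carries an explicit "mixed family cannot be excluded" flag —
with so few alleles fusion cannot add a fifth allele, so the two breeding
structures are observationally equivalent.

## Bottleneck battery

For each polymorphic locus, equilibrium samples of the same gene count are
simulated on Kingman coalescent genealogies with Poisson mutations
(rate θ/2 per lineage per 2N generations) and accepted only when they show
exactly the observed number of alleles; θ is first calibrated by bisection
on the expected allele count (exact `E[K] = Σ θ/(θ+i)` under IAM; stochastic
bisection for the stepwise models, which need a larger θ for the same K).
Mutation models: IAM — each mutation is a novel allele; SMM — ±1 repeat
step; TPM — single step with probability 0.70, otherwise a ±geometric jump
tuned to variance 30 (the classic defaults of the reference
heterozygosity-excess program; both exposed as parameters).

`DH = (He − mean Heq)/SD(Heq)` standardises each locus. The sign test is a
two-tailed Poisson-binomial test of the number of He-excess loci, with each
locus's excess probability estimated from its own simulations (the
distribution of Heq is skewed, so this is not ½). Wilcoxon signed-rank
tests on DH are exact for ≤ 15 informative loci and use the normal
approximation above. The mode-shift indicator pools alleles into ten
frequency classes ((0,0.1] … (0.9,1.0]); "normal L-shaped" requires the
rarest class to hold strictly the most alleles. Repeated batteries can
share an `HeqLibrary` cache keyed by (gene count, allele count, model):
the conditioned equilibrium distribution depends on the data only through
that key, and at the default simulation depth the Monte-Carlo error of the
cached means and SDs is negligible beside SD(Heq) itself.

## Haplotype networks

Step distances are Hamming distances with gap/N columns excluded pairwise.
The connection limit comes from a finite-sites Poisson model of our own
derivation in the spirit of classic statistical parsimony: with L sites and
j observed differences, the per-site mutation intensity λ is solved from
the Jukes–Cantor-corrected divergence, and the probability that the
observed pattern arose without superimposed or parallel change is
`[λe^{−λ}/d]^j [e^{−λ}/(1−d)]^{L−j}` (d = j/L); the limit is the largest j
still exceeding the confidence level (default 0.95; 0.90 available). For a
658-bp alignment this gives limits of 8 (95%) and 11 (90%) steps — more
conservative than the classical implementations, a known property of this
derivation, and monotone in both L and confidence. The network itself is a
Kruskal minimum-spanning network with tie retention: within each weight
class, every edge joining components that were distinct when the class
began is kept, so equally short alternative connections survive; edges
longer than the limit are discarded and unattached haplotypes are reported,
with multi-step edges standing for steps − 1 unsampled intermediates.

## Isolation by distance

Pairwise θ between sampling locations (computed even within one colony) is
linearized as θ/(1−θ) — negative estimates pass through — and correlated
with ln distance in meters over the lower triangle. Significance is a
one-tailed Mantel permutation test (simultaneous row/column permutation,
add-one p). Distances of 0 m between distinct points are replaced by half
the smallest nonzero distance before the log.

## The simulator, and what passing tests mean

Cluster allele frequencies draw a shared base vector per locus from a
symmetric Dirichlet(α) and then each cluster from Dirichlet(τ·base) with
τ = (1−d)/d, so the divergence knob d approximates the expected pairwise
F<sub>ST</sub> (verified by simulation to ±0.05 at d = 0.2). Colony
pedigrees: simple families are i.i.d. Mendelian offspring of one random
pair; extended families breed m neotenics per generation by random mating
within the current reproductive pool (selfing excluded, sib and
parent–offspring mating allowed) for g generations, with workers from the
final pool — realized inbreeding grows with g, and g = 0 reduces to the
simple family; mixed families pool workers of two unrelated pairs at a
configurable fraction. Sampling points take 20 workers each, matching the
standard collection-point protocol, placed uniformly in a configured area.
Bottleneck test-beds initialise the ancestral gene pool at mutation-drift
equilibrium (Chinese-restaurant sampling under IAM, a coalescent sample
under SMM/TPM — the stationary distribution of a Wright–Fisher population's
2N genes under the coalescent approximation), then crash and drift forward
with per-model mutation before sampling. mtDNA haplotypes place the
requested number of substitutions per tree edge at globally distinct sites
(infinite-sites), so pairwise step distances equal path sums by
construction.

Reference study conditions used by the recovery benchmarks
(`termipop.evaluation`): 20 workers per colony/point; the allele-rich
8-locus regime (5–32 alleles per locus, Dirichlet α = 2) for family-type
recovery — colony fusion is only detectable where loci are polymorphic
enough for five alleles to co-occur, and a separate 2–3-allele regime
documents the indistinguishability case; 6 polymorphic 6-allele loci for
colony delineation; extended families at g = 3, m = 10; mixed fusions at
50:50. Problem sizes in the benchmarks (200 colonies per type, 100
delineation sites, 200 null replicates per test at 999 permutations, 100
crash replicates at 2,000 conditioned simulations per locus) were chosen to
keep each benchmark to roughly a minute on one core while leaving the
binomial confidence intervals tight enough to be informative.

What the simulator does **not** emulate: genotyping error and allelic
dropout, null alleles, mutation during the pedigree, spatially structured
dispersal or budding within colonies, linkage between loci, and selection.
Passing recovery tests therefore demonstrate that the inference machinery
is correct and well calibrated under its own model assumptions; on field
data, scoring artefacts and within-colony spatial structure can only lower
the realized accuracy.

## Known limitations

* The parsimony limit is a model-based reconstruction, conservative
  relative to the classical statistical-parsimony programs (see above);
  networks built at the same nominal confidence may leave divergent
  haplotypes unattached earlier.
* The Wilcoxon battery needs ≥ 4 polymorphic loci to be meaningful; the
  report flags smaller panels rather than refusing.
* Single-linkage colony merging is order-independent but, by design,
  transitive: heavily chained non-significance can merge locations whose
  direct comparison is significant; such pairs are reported.
* The exact HWE and permutation tests are discrete; their p-values are
  valid but conservative at small samples.
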