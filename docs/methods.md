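# Methods

`mbgblup` studies a practical question in small-ruminant breeding: how
accurately can genomic BLUP predict the breeding values of purebred sires
when the reference population is purebred, crossbred, or a mixture — and
does accounting for breed-specific marker allele frequencies in the
relationship matrix help? Because the industry datasets this question is
usually asked of are proprietary, the package pairs the analysis pipeline
with a forward-in-time simulator that reproduces the relevant statistical
structure at desk scale.

## The prediction model

For phenotype records y the mixed model is

    y = X b + Z1 g + W w + Z1 Q q + Z2 s + e

* `b` — fixed effects: birth type, rearing type, sex, an age covariate and
  contemporary group (site × birth year × management group);
* `g ~ N(0, G σg²)` — additive genetic values with a *genomic*
  relationship matrix G in place of the pedigree numerator matrix;
* `Q q` — breed-proportion covariates (pedigree-derived Q rows, one column
  per breed minus a reference breed), fitted as fixed; constant or aliased
  columns are dropped with a recorded warning;
* `w ~ N(0, I σw²)` — maternal effects per dam;
* `s ~ N(0, I σs²)` — sire-by-flock interaction effects;
* `e ~ N(0, I σe²)`.

Henderson's mixed model equations are assembled densely and solved by
Cholesky factorization; `G` is inverted after an optional +0.01 diagonal
stabilization that is applied *only* when the plain factorization fails,
and recorded in the fit metadata. Solutions are verified against a direct
GLS oracle in the tests (max |Δ| < 1e-8 on random instances). Prediction
error variances come from the additive block of the inverse coefficient
matrix.

Variance components for the full model are supplied by the caller (in the
simulation study: the generator's truth). For the reduced
additive-plus-residual animal model an EM-REML estimator is provided; it
works in the eigenbasis of G (O(n p²) per iteration after one
eigendecomposition) and inherits EM's monotone restricted likelihood,
which is asserted per iteration in the tests. Components are floored at a
tiny positive value; boundary hits surface through the convergence flag.

## The two relationship matrices

* **G1** (genotype-based): `G1 = ZZ' / (2 Σ p_j (1-p_j))` with
  `Z_ij = M_ij − 2 p_j`, `M` the 0/1/2 count of the second allele, and
  `p_j` the observed frequency in the reference set. With
  observed-subset frequencies every Z column is centred, so G1 rows sum
  to zero exactly — a property the tests exploit.
* **G2** (gametic, breed-specific frequencies): each parental haplotype
  (0/1 alleles) is centred by the allele frequency of its *own breed of
  origin*; `G2_i = Z_i Z_i' / Σ p_j(1-p_j)` for the paternal (i = 1) and
  maternal (i = 2) gamete sets and `G2 = (G2_1 + G2_2)/2`. Only animals
  whose parents are > 97% purebred (so each gamete has a well-defined
  breed) are eligible. Three choices the formula leaves open are made
  explicit and recorded in the matrix metadata:
  * when one gametic matrix mixes several breeds, its denominator is the
    haplotype-count-weighted average of the per-breed Σp(1−p);
  * loci monomorphic within a breed contribute zero to that breed's
    centring and are excluded from that breed's denominator term;
  * the paternal×maternal cross products are omitted, exactly as the
    two-term average implies; a `full_gametic` variant that includes them
    (and, with pooled frequencies, reproduces G1 to machine precision —
    tested) is available for comparison.

A structural consequence worth knowing: for a pair of animals G1 sums
four gamete-pair products while G2 keeps two, and the omitted cross
products carry as much realized segment-sampling variance as the retained
ones. The element-wise correlation between G1 and G2 off-diagonals is
therefore bounded by `sqrt((σk² + σn²/2)/(σk² + σn²))` — at most 1/√2 for
unrelated pairs — where σk² is pedigree-relationship variance and
σn² ≈ 1/Me is segment-sampling noise. At ~1000 markers on a 3-Morgan
desk-scale genome this correlation sits near 0.8 even with strong
half-sib structure; values like 0.94 require tens of thousands of markers
and deep multi-breed pedigrees. The accuracy consequences are small
(mean G1−G2 accuracy gap < 0.05 in the scenario runs), matching the
expectation that breed-specific centring has limited impact when most
frequencies are intermediate.

GRM diagnostics include eigen-PCA with a k-means breed-cluster purity,
element correlations, and gametic relationship summaries between a
haplotype class (e.g. all paternal focal-breed gametes of the reference)
and an animal group (e.g. the validation sires).

## Genotype and phenotype QC

The SNP cascade applies, in a fixed documented order: per-call confidence
masking (< 0.6 becomes a no-call), SNP call rate < 95%, SNP
heterozygosity deviating more than 3 SD from the panel mean (recomputed
on the surviving panel; the per-SNP reading of the heterozygosity rule is
used, a per-sample variant was considered and not enabled), minor allele
frequency < 1%, sex-chromosome drop, and a Hardy-Weinberg χ² (1 df) test
at p < 1e-15 on all animals pooled. Each SNP is charged to the first
filter that removes it and counts reconcile exactly. Duplicate samples
are detected by Pearson correlation ≥ 0.99 of the 0/1/2 vectors over
jointly non-missing calls (a mean-imputed screen at a safely lower cutoff
pre-selects candidate pairs, which are then re-checked exactly); the
later-indexed member of a pair is removed. Missing genotypes are then
imputed by the SNP mean 2p̂ — a deliberate frequency-preserving stand-in
for phasing-based imputation that leaves GRMs essentially unchanged at
the ≤5% missingness the pipeline produces (element correlation with the
truth matrix > 0.99, tested). Phenotype records more than 4 SD from the
grand mean are removed, with the threshold computed once, not iterated.

## Breed composition and phase

Breed proportions are computed by recursive averaging of parental
proportions through the pedigree, capped at 6 generations; unlabelled
founders and truncated paths accrue to an explicit `unknown`
pseudo-breed so rows always sum to 1 (verified against an independent
founder-path enumeration oracle). Crossbred reference sets are selected
by per-breed thresholds (defaults 45%/45%/35%, the lower third threshold
compensating for a smaller eligible pool). Haplotype breed-of-origin
labels come either from the pedigree rule (parent > 97% purebred) or, in
simulation studies, from the generator's exact per-allele ancestry; the
two agree on all eligible non-founder animals (tested). A rule-based
trio phasing routine (homozygous offspring, or heterozygous offspring
with at least one homozygous parent) provides partial phase for real
data; unresolved double-heterozygote loci are left missing and counted.

## The simulator

Diploid, locus-explicit forward simulation on a uniform genetic map
(default three 1-Morgan chromosomes × 550 loci; crossovers
Poisson-per-Morgan, no interference, random start strand). Base allele
frequencies are Beta(2,2); within-chromosome LD accumulates over 50
random-mating generations at census 250 before the breeds split. Each of
four breeds then drifts independently at Ne = 150 for (120, 80, 50, 50)
generations — the first breed (the Merino analog) most distinct, the two
terminal analogs mutually closest, so the GRM principal components
reproduce the characteristic multi-breed layout. Wright's pure-drift
expectation 1 − (1 − 1/(2Ne))^t for FST is recovered within a few percent
(tested at Ne = 50, t = 100).

A trait is controlled by 150 QTL sampled from segregating loci and, by
default, *excluded* from the marker panel (markers tag, but do not
contain, the causal variants). Every allele carries a breed-of-origin
code, and each QTL has one additive effect per breed, multivariate normal
with equicorrelation ρ across breeds; an animal's true breeding value
sums allele content × the effect of that allele's origin breed. Effects
are rescaled once so the focal-breed additive variance equals
h²σp². Defaults: h² = 0.30 (the studied body-composition traits have no
published components; 0.25–0.35 is the field's range), maternal and
sire×flock shares 0.05 each, trait mean/SD 40/7.6 kg (post-weaning-weight
like). ρ defaults to 0.2: at desk scale the ancestral LD shared between
breeds cannot decay within realistic divergence times the way 50k-chip
marker-QTL phase does across real breeds, so the across-breed QTL
correlation carries that signal decay instead.

The mating design produces paternal half-sib families (sizes 10–30,
dams sampled without replacement within family): an expanded research-ewe
generation (purebred daughters of males *outside* the breeding sire pool),
purebred focal-breed progeny by the sire pool, F1 crossbreds (other-breed
sires × focal ewes), optional three-way crosses via F1 dams, and
progeny-tested validation sires generated as purebred *sons* of the sire
pool. This reproduces the study system's relatedness asymmetry — the
reference's paternal haplotypes are more related to the validation sires
than the maternal ones (simulated gametic means ≈ 0.010 vs ≈ 0.001) —
without any validation animal being a parent of a reference animal.
Validation EBVs are simulated at per-sire accuracies drawn uniformly
between the breed's reliability floor (0.64 for the White-Suffolk analog,
0.70 otherwise) and 0.98; the floor is interpreted as the correlation r
between EBV and true breeding value, the scale on which sheep-industry
accuracies are reported, not r².

Phenotypes add fixed effects (birth/rearing type, sex, a 0.04·SD/day age
slope, contemporary-group effects at 0.4 SD), maternal and sire×flock
draws and residual noise so the variance shares hit the configured
ratios; the noise-free limit (h² = 1, no fixed effects) returns exactly
μ + TBV. All draws descend from one seed through salted, order-insensitive
`SeedSequence` streams; identical configuration + seed gives bit-identical
populations, phenotypes and EBVs.

What the generator does *not* emulate: mutation, selection during
divergence or within the design, genotype-by-environment beyond
sire×flock, multi-trait covariance, coalescent-exact LD, and Merino
strain substructure. Passing tests therefore show that the pipeline's
estimators and comparisons behave correctly under the assumed additive
multi-breed architecture — not that real sheep data would give the same
absolute accuracies.

## The scenario study and its scale

The default scenario keeps the real design's ratios at roughly 1/5 scale:
purebred focal references of 200/400/600 (vs 1000/2000/3000), a
400-animal F1 crossbred reference whose 2×400×0.5 = 400 focal haplotypes
match the smallest purebred reference, validation groups of 35/11/14/28
sires (1/5 of the published 175/54/72/140), ~1650 simulated loci and
3 Morgans, both GRM flavors, and 10 replicate seeds in the tests (5 in
the acceptance script). These sizes were chosen so the full study runs in
minutes on one CPU while preserving the qualitative comparisons: accuracy
rising with purebred reference size, crossbred-only references trailing
purebred ones of equal focal-haplotype count, across-breed prediction
near zero when the across-breed QTL correlation is low (the scenario
variant with ρ = 0.05 realizes the stated condition), and G1/G2 parity.
Absolute accuracies are higher than the published ones because desk-scale
genomes have far fewer independent segments (Me ≈ 85 here vs thousands);
the comparisons, not the absolute values, are the object of study.

## Numerical conventions

Missing genotype calls are int8 −1 (float NaN after imputation); allele
frequencies entering a GRM are clipped to (ε, 1−ε) with ε = 1/(4n) only
in the pipeline path, since the constructors reject monomorphic
frequencies outright; duplicate-pair removal keeps the first-indexed
sample; compact letter displays are built from the maximal cliques of the
pairwise non-significance graph (both display directions guaranteed,
possibly with extra letters); Fisher's z is the default accuracy
comparison, with Steiger's dependent-correlation variant available when
two predictors share the same validation animals.
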