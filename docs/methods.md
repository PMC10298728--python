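# Methods

## Tetrasomic inheritance simulator

Gametes are drawn per locus independently (loci are unlinked; no linkage
map or LD is simulated). With probability 1 − α the gamete receives 2 of
the parent's 4 allele copies without replacement, all C(4,2) = 6 pairs
equiprobable (random bivalent pairing); with probability α it receives two
copies of one uniformly chosen parental allele (double reduction). α
defaults to 0; it exists so the property tests can exercise the full
sampling law, not because the emulated study modelled double reduction.

Every founder allele copy carries a globally unique integer label, so IBD
is exact rather than estimated: the realized inbreeding coefficient F of
an individual is the fraction of the 6 within-individual allele pairs per
locus sharing a label, averaged over loci, and the realized co-ancestry θ
of two individuals is the sharing fraction over the 16 cross pairs.
Closed-form anchors used in tests: E[F] = 1/6 for the selfed offspring of
a non-inbred tetrasomic parent at α = 0; θ(parent, selfed child) = 1/4 and
θ(parent, outcross child) = 1/8 *exactly*, because each child allele is a
copy of one labelled parental allele.

Founders are drawn in Hardy–Weinberg-like independence: per-locus allele
frequency uniform on [maf_min, 1 − maf_min] (default 1%), 4 independent
Bernoulli copies per founder. Non-segregating loci are resampled; the
*realized* sample MAF of a kept locus may still fall below maf_min.

## Synthetic study and its limits

The default study configuration mirrors the emulated trial: 4 founder
cultivars genotyped at 2000 SNPs, one selfed (S1) family per founder, two
F1 families sharing founder P1 as the common female parent (half-sibs),
and 9 incomplete blocks each carrying one plot of every check plus up to
100 unreplicated test plots; one plot is one phenotype record. Default
family sizes of 100 give 600 test entries in 900 available plots, the
trial's scale.

A plot value is

    intercept + block effect + Σ dosage·effect − c_ID·F_realized + ε

with ε Gaussian. Ten tuber traits are generated: five tuber-weight size
classes plus the total (grams per 4-plant plot, total ≈ 2800 g with
plot-level h² ≈ 0.4), two 1–9 uniformity scores, tuber eye depth, and
reducing sugars. The inbreeding-depression coefficient c_ID is the
directional-dominance proxy: a linear penalty on realized IBD
homozygosity, calibrated per trait as (intended mean drop at F = 1/6) × 6
— the total-weight drop is set to ~75% of the parental mean, the small-
tuber class and reducing sugars get *negative* penalties (they increase
under inbreeding), and shape uniformity is left nearly unaffected, echoing
the qualitative pattern of the emulated trial. Additive marker effects are
i.i.d. normal, scaled so the founder-population genetic variance hits each
trait's target, and mean-centred against the founder allele frequencies so
the founder mean sits at the intercept.

What the generator does **not** emulate: linkage and LD between SNPs,
mixed bivalent/quadrivalent pairing or preferential pairing, genotyping
error and missingness patterns, dominance/epistatic trait architecture
beyond the single homozygosity penalty, spatial field trends within
blocks, and genotype × environment interaction. Tests passing on this
material therefore validate the *machinery* (adjustment algebra,
relationship scaling, estimation, validation protocol), not the field
performance of any real cultivar set.

## Augmented-design analysis

CF_j is the block-j check mean minus the grand check mean (the printed
formula's "(l/g)" read as 1/g, under which it reduces to exactly this);
CFs sum to zero, so adjusted check means are block-free. A uniform shift k
of one block's plots is absorbed by its CF up to a k/r shift of the grand
mean common to every adjusted value, leaving all comparisons invariant.

The error term is the checks × blocks interaction mean square with
(g−1)(r−1) df; the design-validity rule r > 10/(c−1) + 1 keeps that df
above 10. LSDs use Student t at that df with the classical standard-error
cases (two checks; two tests in the same block; two tests in different
blocks; test vs check).

Generation contrasts compare adjusted group means (S0 = checks, S1, F1).
Each adjusted group mean is an exact linear combination of plot values —
+1 on a test's own plot, −1/g on its block's check plots, +1/(gr) on all
check plots; 1/r on a check's plots — so the contrast variance is
MSE·‖c_A − c_B‖². This accounts for the error injected by the adjustment
itself and for unequal, unevenly blocked groups; a 200-trial null
simulation in the test suite confirms ~5% type-I error. Also reported:
proportional inbreeding depression 1 − mean(S1)/mean(S0), per-family
mid-parent and best-parent heterosis, and the fraction of F1 entries
exceeding the best parent. Whether a selfed family whose parent was
dropped from the checks belongs in the S0-vs-S1 contrast is left to the
caller (`s1_families` filter; default: include all).

## Relationship matrices

`full_tetraploid`: W = X − 4p, G = WWᵀ/Σ 4p(1−p). Since Var(dosage) =
4p(1−p)(1+3F), the expected diagonal is 1 + 3F (1.5 for S1) and the
parent–selfed-offspring entry 4θ = 1. `pseudodiploid` halves dosages onto
0–2 and applies the diploid form with denominator Σ 2p(1−p); it is kept as
the deliberately mis-scaled contrast, not a recommendation. Loci are
filtered at sample MAF ≥ 1% by default (configurable; the emulated study
does not state whether it filtered on the analyzed sample). Missing
dosages are mean-imputed per locus before construction. An optional PSD
repair clamps negative eigenvalues at zero, and an optional blend
(1−β)G + βI (β = 0.01 customary) provides invertibility; both are off by
default and recorded in the GRM metadata.

## GBLUP

REML: G is eigendecomposed once; with ỹ = Uᵀy, x̃ = Uᵀ1 and v = λd + 1 the
profiled restricted log-likelihood is
−½[Σ log v + log(x̃ᵀV⁻¹x̃) + (n−1) log(σ̂²e)], evaluated in O(n) per λ. A
81-point log grid over [1e−4, 1e4] brackets the optimum; golden-section
search refines it to 1e−8 relative. Optima at the grid edge (or a flat
likelihood, e.g. G = I where only σ²g + σ²e is identified) are flagged
`boundary_` and the edge value returned. Degenerate inputs rejected:
constant y, n < 3, asymmetric or indefinite K.

Gibbs: the spectral basis makes the genetic-value full conditional a
product of independent normals; the intercept is normal; both variances
are scaled-inverse-χ² with prior df 5 and prior scales var(y)/2 each
(configurable — the emulated analysis does not state its priors).
Defaults mirror the study's run length (15,000 burn-in + 15,000 kept);
tests use 500 + 1500. Reported GEBVs are the Rao-Blackwellised posterior
mean (average of full-conditional means), which has far smaller
Monte-Carlo error than averaging draws at short chain lengths; chains are
seed-reproducible, divergent variance draws abort with diagnostics, and
effective sample sizes (arviz) accompany the scalar posteriors. The
cross-method check compares Gibbs GEBVs against the BLUP evaluated at the
matched posterior-mean variance ratio — at small n the REML ratio itself
is noisy (often at the boundary), so comparing at matched variances is
what isolates sampler correctness.

Predictions for unphenotyped individuals use
G_test,train (G_train,train + (σ²e/σ²g)I)⁻¹(y_train − μ̂), proven in the
tests to equal Henderson's mixed-model-equation joint BLUP with the test
phenotypes masked. Phenotypes fed to GBLUP are the block-adjusted Y′ (the
augmented design leaves test entries unreplicated, so raw values would
carry block effects); no trait standardisation is applied.

## Cross-validation

Within-family accuracy: 50 random partitions, 70% training, Pearson
correlation of adjusted phenotype vs predicted GEBV in the 30% held out;
every per-repetition value is retained. Cross-family cells are single
whole-family fits (training family → testing family), matching the fixed
train/test identities of a family-scheme table; the protocol for such
cells is ambiguous in the emulated study, and the single-fit reading was
chosen because it preserves the fixed set identities. Partitions are
drawn over sorted ids, making every accuracy invariant to input ordering.
Zero-variance observations or predictions yield a missing cell with a
logged warning, never a silent drop. Relatedness classes come from the
pedigree: same family full-sib, shared parent half-sib, otherwise
unrelated.

## Problem sizes used in checks

The verification runs use sizes chosen to make Monte-Carlo error small
relative to each effect: 20,000 gametes per dosage × α cell; 10,000
selfed offspring at 300 loci for realized F; 200 founders × 400 loci with
true-frequency centring for the GRM scaling means; n = 300 individuals ×
1000 loci × 50 replicates per heritability level for REML recovery and
accuracy monotonicity; 30 replicate six-family studies (families of 50 at
300 loci) for the half-sib vs unrelated training comparison. The demo
pipeline uses 4 founders, 300 loci and families of 40.

## Known limitations

Single-trait, single-environment, additive-kernel GBLUP only (no
dominance/digenic kernels, no pedigree A or H matrices). The ANOVA
recovers no inter-block information and fits no spatial trend. VCF input
is restricted to biallelic records with 4-allele GTs or a DS field.
Simulated founders are unrelated and non-inbred by construction, so
scenarios with pre-inbred or related parents require user-supplied
genotypes.
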