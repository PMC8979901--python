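# Methods

## The evaluation problem

`ssgeval` implements a single-step genomic evaluation for a quantitative
trait — withers height, in cm — in a reference population assembled from
several related horse breeds.  The defining feature of the single-step
(ssGBLUP) setting is that only a small genotyped cohort exists inside a
much larger pedigree: breeding values are wanted for *all* animals, and
genomic and pedigree information must be combined in one model rather
than in separate analyses.

## Relationship matrices

* **A** (numerator relationship matrix) is built by the tabular method:
  `a(i,i) = 1 + a(s,d)/2`, `a(i,j) = (a(j,s) + a(j,d))/2` with unknown
  parents contributing zero.  Its inverse is built directly by
  Henderson's rules with inbreeding, the Mendelian-sampling variance of
  animal *i* being `d_i = 0.5 − 0.25(F_s + F_d)` with the inbreeding
  coefficients taken from the tabular diagonal.
* **G** is VanRaden's method 1, `ZZ′ / (2Σp(1−p))` with calls centred by
  twice the allele frequency observed in the genotyped sample.  Using
  observed rather than base-population frequencies is a known source of
  scale differences between pedigree-based and marker-based variance
  estimates; the package exposes `freq_source="supplied"` for callers
  who have external frequencies.
* **G is blended** with the pedigree sub-matrix of the genotyped animals,
  `G* = wG + (1−w)A22`, default `w = 0.95`, which guarantees positive
  definiteness when the marker count is below the cohort size or animals
  are duplicated.  No additional scale tuning of G to A22 is applied by
  default.
* **H** is assembled in the standard block form (non-genotyped block
  corrected through `A12 A22⁻¹ (G−A22) A22⁻¹ A21`), and its inverse by
  the sparse correction `H⁻¹ = A⁻¹ + blockdiag(0, G⁻¹ − A22⁻¹)`.  The
  Cholesky factor of H drives the transformed animal model; if the plain
  factorisation fails, `1e-8·I` is added once (logged) — a deliberately
  small jitter, because aggressive regularisation would distort
  prediction error variances.

## The animal model and its sampler

The model is `y = Xb + Za + e` with `a ~ N(0, H σ²ₐ)` and
`e ~ N(0, I σ²ₑ)`; X holds the intercept and age-class effects (five
half-open age bins, `[0,3) [3,4) [4,5) [5,6) [6,∞)`, the first *present*
class acting as reference).  With `L L′ = H` the equivalent model
`y = Xb + (ZL)cₐ + e`, `cₐ ~ N(0, I σ²ₐ)`, has independent random
effects.

The Gibbs sampler works in a doubly collapsed space:

1. the fixed effects are integrated out by projecting onto an orthonormal
   basis of `col(X)⊥` (the REML transformation), and
2. a one-off SVD `K′ZL = U diag(s) V′` reduces the random effect to its
   data-informed coordinates `w = V′cₐ`.

The chain state is `(w, σ²ₐ, σ²ₑ)`; all conditionals are exact
(independent Gaussians for `w`, scaled-inverse-χ² for the variances with
`df = ν + rank` and `df = ν + (n − p)` respectively) and each sweep
costs O(rank).  The prior-only complement of `cₐ` and the fixed effects
are redrawn from their conditionals only when a sample is stored, which
reconstructs the full joint posterior without letting the unidentified
directions slow the variance chain.  This removes the two classic slow
modes of animal-model MCMC — the intercept vs. mean-breeding-value
random walk, and the feedback of prior-only random-effect coordinates on
σ²ₐ.

Priors are weakly informative scaled-inverse-χ² with 5 degrees of
freedom and scale set to half the phenotypic variance for both
components.  Chain defaults are 30,000 sweeps, 5,000 burn-in, thinning 5;
because the collapsed sweeps are nearly independent, far shorter chains
(2,000–6,000) are adequate in practice and are what the validation suite
uses.  Convergence is summarised by effective sample sizes (Geyer's
initial positive sequence) for σ²ₐ, σ²ₑ and h².

`rao_blackwell=True` replaces the posterior-mean point estimates of `b`
and the breeding values by averages of their analytic conditional means
(the draws still provide prediction error variances).  This makes the
fixed-variance sampler agree with the deterministic mixed-model-equation
solver to numerical precision, so the cross-check between the two code
paths tests the algebra rather than Monte-Carlo noise.

Reliabilities are `r² = 1 − PEV/σ²ₐ`, clipped into [0,1] with a logged
count of clips; `solve_mme` provides both the deterministic cross-check
and the classical pedigree BLUP comparator (`K = A`).

## GWAS

Association uses a mixed linear model with a leave-one-chromosome-out
GRM: for SNPs on chromosome *c* the polygenic covariance is built from
all other autosomes, so the tested SNP never contributes to its own null
model.  Variance components are re-estimated once per left-out
chromosome by REML on the GRM's eigenbasis (one eigendecomposition and a
bounded 1-D optimisation of the profiled restricted likelihood over the
variance ratio, `log γ ∈ [−12, 12]`; hitting the bounds sets a boundary
flag, and a flat eigenvalue spectrum — a GRM proportional to I — returns
an even variance split with the flag set).  Each SNP then gets a 1-df
Wald χ² from the rotated weighted regression, with conditioning SNPs
appended to the fixed effects and excluded from testing.  Significance
thresholds are Bonferroni at family-wise 0.05 and 0.01.

Variance partitioning across marker sets uses Haseman–Elston regression
of the off-diagonal phenotypic cross-products on the stacked GRM
off-diagonals — closed-form and stable at the sample sizes this package
targets — with grouped-jackknife standard errors (20 groups by default)
and an optional EM-REML refinement.  Full multi-component REML is
deliberately not the default: with 32 components and a few hundred
animals it is fragile.

## The synthetic-data generator

The generator emulates the structure of a multi-breed mare reference
population:

* **Pedigree** — five breeds of very unequal size (defaults proportional
  to 982/444/98/416/173), founder counts 2.5× the final cohort shrinking
  linearly over three ancestral generations (pedigree ≈ 6–7× the
  genotyped cohort), sire families drawn from a long-tailed mixture
  (geometric with mean ≈ 2.5 plus a 3% admixture of heavily used sires
  with 20–60 offspring, giving family sizes from 1 into the dozens with
  mean ≈ 3.5), dams reused at most three times and mostly once, and a
  configurable fraction of sires serving more than one breed.
* **Genotypes** — founder haplotypes from breed-specific allele
  frequencies (Balding–Nichols around a shared ancestral frequency with
  the divergence parameter as Fst), then gene dropping with Poisson
  crossovers on a uniform map of 1 Morgan per chromosome (31 autosomes).
  Founder haplotypes carry no linkage disequilibrium; LD exists only
  through recent co-ancestry.  QTL markers are kept segregating in every
  breed (frequencies clipped to [0.25, 0.75]).
* **Phenotypes** — `height = 167.6 + age-class effect + QTL effects +
  polygenic value + N(0, σ²_env)` with a total SD of 3.5 cm.  Each
  configured QTL's effect is scaled to its variance fraction using the
  realised dosage variance in the phenotyped cohort, and the summed QTL
  contribution is rescaled once so that linkage-induced covariance
  between causal loci cannot shift the realised genetic share; the
  environmental SD fills the variance not claimed by QTLs and polygene.
  The polygenic value is simulated down the pedigree (founder draw plus
  Mendelian sampling, inbreeding ignored in the sampling variance —
  founder-rich shallow pedigrees keep F negligible), *not* from the
  markers, so marker-based and pedigree-based heritability can
  legitimately differ, as they do in real stature data.  Ages at
  measurement are drawn so all five age classes occur.

What the generator does **not** emulate: founder LD and realistic LD
decay, genotyping error and array intensity artefacts, selection across
generations, dominance/epistasis, and heterogeneous genetic maps.
Passing tests therefore demonstrate the correctness of the estimation
machinery under the stated generative model, not performance on real
array data.

## Marker QC and imputation

QC removes, in a fixed order with each marker attributed to its first
failure: duplicate `(chrom, bp)` positions (lexicographically first
`snp_id` kept), call rate < 0.90, MAF < 0.01, and a 1-df χ²
Hardy–Weinberg test at p < 0.001 (pooled across breeds; monomorphic
markers are in trivial equilibrium).  Array-intensity (GenCall-score)
filtering needs raw intensities and is out of scope; the simulator's
missing-call rate stands in for its effect.  Imputation is seeded
allele-frequency sampling, `Binomial(2, p̂)` per missing call — it
completes the matrices for relationship building but carries no linkage
information, a documented fidelity gap relative to haplotype-based
imputation of real data.

## Validation problem sizes

The acceptance suite runs every check end-to-end at sizes chosen so the
whole suite completes comfortably on one CPU:

* matrix identities on 50 random pedigrees of 15–500 animals;
* the gene-dropping kinship oracle at 200 animals × 100,000 replicates;
* sampler-vs-MME agreement on a two-breed cohort of 300 mares;
* heritability recovery (h² = 0.4 from 155 marker QTLs) on ten cohorts
  of 2,000 genotyped+phenotyped females over 1,400 founders, fit with
  the unblended G (the marker panel exceeds the cohort size, so G is
  full rank and the recovery target is not shrunk by blending);
* GWAS power/specificity on ten five-breed cohorts of ≈600 mares with
  31 × 60 markers and a 20%-variance QTL on chromosome 3;
* variance partitioning on cohorts of 600 with a 3-SNP component at 22%;
* reliability structure on twenty cohorts of 260 daughters.

## Known limitations

* Dense matrices throughout: the implementation targets cohorts up to a
  few thousand genotyped animals and pedigrees in the tens of thousands;
  it does not implement APY or sparse H⁻¹ approximations.
* No metafounders or unknown-parent groups; unknown parents are base
  animals.
* The HE partitioner assumes components disjoint in markers and reports
  shares of the fixed-effect-adjusted phenotypic variance.
* Single records per animal; no repeated measures, no multi-trait
  models, no dominance.
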