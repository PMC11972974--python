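# Methods

## The problem and the model

A consortium GWAS summary and a target cohort share `n_c` individuals.
A PRS trained on the consortium weights and evaluated on the target is
then partly an in-sample prediction for those individuals: their
phenotype noise entered the per-variant effect estimates, so their
apparent discrimination (AUROC, OR per SD) is inflated.  The inflation
lives overwhelmingly in the weakly-associated variants — each null
variant's estimated effect contains a component proportional to the
overlap samples' phenotype residuals — which is why it is largest for
genome-wide weight vectors and why progressively excluding associated
variants exposes it (see Diagnostics below).

`oaprs` treats the consortium summary as a fixed-effect meta-analysis of
the overlap cohort and the remaining ("non-overlap") cohort and inverts
it per variant:

* **IVW**: `σ_s² = 1/(1/σ_all² − 1/σ_o²)`,
  `b_s = σ_s²(b_all/σ_all² − b_o/σ_o²)`.  The inversion is exact when the
  consortium really is an IVW meta that included the overlap summary.
  It is *undefined* when the overlap carries at least as much precision
  as the consortium (`1/σ_all² − 1/σ_o² ≤ ε`, default ε = 1e-12);
  such variants are flagged `dropped_unstable` and excluded rather than
  floored, because a floored variance would manufacture arbitrarily
  extreme effect estimates (visible as outlier markers when the two
  input GWAS have similar SEs).
* **Z-score**: the sample-size-weighted meta
  `z_all = (√n_o z_o + √n_s z_s)/√(n_o + n_s)` is inverted as
  `z_s = (√n_all z_all − √n_o z_o)/√n_s` with `n_s = n_all − n_o`.
  This weighting is the only one under which meta∘inverse is an exact
  identity, which is the design requirement.  The adjusted Z is mapped
  back to effect-size scale with `se = 1/√(2·maf·(1−maf)·n_s)`,
  `beta = z·se`, valid for a phenotype standardized to mean 0, SD 1 and
  HWE dosage variance `2·maf·(1−maf)`.  The MAF is taken from the
  consortium table by default (`maf_source="overlap"` switches to the
  overlap table; a cohort-specific frequency gives more precise betas).
* **De-correlation** (comparator): with
  `ρ = n_c/√(n_all·n_o)·cor(Y₁,Y₂)` the whitening
  `ζ = (z_all − ρ·z_o)/√(1−ρ²)` makes the consortium statistic
  uncorrelated with the overlap statistic under bivariate normality and
  preserves unit variance.  Unlike the meta-inversions it rescales the
  statistic rather than removing the samples, so `n` is left at `n_all`.
  Estimating ρ from LD-score regression when the overlap is unknown is
  out of scope; `n_c` and `cor_y` must be supplied.

Per-variant sample sizes are used when present; `n_s = n_all − n_o` with
no case/control effective-size correction.  P values throughout are
two-sided normal tails of Z, clipped into (1e-300, 1].

## Summary-statistics handling

Tables are tab-delimited with header synonyms recognized for the common
dialects; EAF > 0.5 is folded to MAF at read time.  Validation drops rows
with duplicate ids, non-positive SE, or a Z inconsistent with beta/SE
(relative tolerance 1e-6), and recomputes P from Z (with a logged
warning) when the two disagree — the Z chain is the computational
backbone.  Harmonization joins on variant id, flips records whose
effect/other alleles are swapped (negating beta and Z; a folded MAF is
numerically invariant under allele complementation), drops incompatible
allele sets, and drops strand-ambiguous palindromic variants (A/T, C/G)
outright — the conservative, countable convention.  Consortium-only
variants pass through unadjusted; writing uses 10 significant digits so
a round trip stays within the validation tolerances.

## Simulator

The generator emulates a biobank overlap-injection design at desk scale:

| parameter | default | meaning |
| --- | --- | --- |
| `n_variants` / `n_causal` | 2000 / 50 | biallelic variants; sparse causal set |
| `maf_range` | (0.05, 0.5) | per-variant allele frequency, uniform |
| `h2` | 0.5 | liability-scale heritability |
| `prevalence` | 0.3 | case fraction (liability threshold) |
| `n_train` / `n_target` | 8000 / 2000 | base training and target partitions |
| `overlap_fraction` | 0.3 | fraction of target merged into training |

Genotypes are Binomial(2, p) under HWE, linkage equilibrium by default.
Causal effects are Normal(0, h2/n_causal) on standardized dosages; the
genetic score is rescaled to variance exactly h2, noise is
Normal(0, 1−h2), and cases are the top `prevalence` quantile of
liability.  Overlap samples are drawn uniformly from the target (or as
explicit case/control counts).  The optional block-LD mode builds blocks
by haplotype copying: each non-tag variant copies the tag's haplotype
allele with probability `c = ld_r2^(1/4)` and resamples otherwise, giving
pairwise dosage correlation `c` (tag–other) and `c²` (other–other), so the
weakest pair in a block sits near the requested `ld_r2`.  This was chosen
over a Gaussian-copula construction because the copy probability controls
the dosage correlation directly and reaches r² = 0.9, which thresholded
copulas cannot do reliably for Bernoulli marginals.

The GWAS engine is per-variant simple linear regression of the phenotype
(standardized to mean 0, SD 1 within the analyzed subset) on dosage.
Linear-on-binary was chosen over logistic deliberately: it matches the
scaling assumption of the Z-to-beta back-transformation, makes the
full-sample statistic very nearly the exact meta of its disjoint
partitions (the enabling property for inversion; observed z-correlation
> 0.999 at the default sizes), and is orders of magnitude faster.  A
logistic score-test engine (`engine="logistic"`) exists as a realism
check; the two agree at r > 0.99 on the default design.  Monomorphic
variants are emitted with z = 0 and a missing SE.

What the simulator does **not** emulate: realistic LD from reference
panels, imputation noise, relatedness, population structure, covariates,
or case/control ascertainment.  Passing tests therefore demonstrate the
algebra and the overfitting/adjustment phenomena under clean conditions,
not performance on any real cohort.

## PRS construction and evaluation

Clumping is greedy: visit variants by ascending P (ties broken by id),
keep a variant unless r² ≥ 0.1 with an already-kept variant within 250 kb
(LD measured on the supplied reference genotypes; a full correlation
matrix is precomputed below 5000 variants, per-candidate products above).
Thresholding keeps P ≤ p_max, with p_max = 0 defined as the empty set.
The practical pipeline selects the threshold from the grid
{5e-8, 1e-5, 1e-3, 0.01, 0.05, 0.1, 0.5, 1} by AUROC on the total target
set.  The simulation experiments instead score the genome-wide vector
(all clumped variants, p ≤ 1): they emulate genome-wide constructors, and
at this design's strong per-variant signal a best-threshold search
concentrates on the causal variants and hides the overlap inflation the
experiments are designed to measure.

AUROC is the exact Mann–Whitney rank statistic (P(case > control) + ½
P(tie)) — no ROC binning.  OR per SD is the exponentiated coefficient of
the standardized score in a logistic model fitted by Newton IRLS to 1e-8;
separation and non-convergence return a flagged result (|log OR| > 15 is
treated as separation).  Evaluation reports total / overlap / non-overlap
target groups; a group with one phenotype class is marked not evaluable.

## Diagnostics

The diagnostic asks: after excluding every variant that shows association
in either the (adjusted) consortium summary or the target's own GWAS,
does the PRS built from the survivors still discriminate on the overlap
samples?  Stage 1 removes variants with P < `p_high` (default 1e-4) in
either table plus their LD neighbours (r² ≥ 0.1 within the window);
stage 2 keeps only variants with P ≥ threshold in both tables, over the
grid {0, 0.01, 0.05, 0.1, 0.2, 0.5}, where threshold 0 means stage 1
only.  Weights are the surviving summary betas, deliberately not
re-fitted — the diagnostic probes residual signal and a re-fit would mask
it.  The kept-variant count is non-increasing along the threshold grid.
A contaminated summary holds overlap-group AUROC well above 0.5 (≈0.7 at
threshold 0.05 under the default design); an adjusted one decays to
chance.  The procedure is a visual heuristic; no formal test of
"trajectory = 0.5" is attempted.

## Reproducibility and numerics

All experiment seeds derive from a master seed by SHA-256 hashing of
labelled coordinates (`derive_seed`), kept below 2³¹; grid runs are
reproducible cell-by-cell.  The acceptance experiments average five
replicates of the default design; the monotonicity curve uses overlap
fractions {0, 0.1, 0.3, 0.6} at the 80:20 split (at fraction 0 the total
group stands in for the non-existent overlap group).  The null-calibration
experiment runs h2 = 0 twice: an uncontaminated cell for the unadjusted
PRS and a contaminated cell for the adjusted PRS, because overlap
overfitting does not vanish at h2 = 0 — an unadjusted genome-wide PRS is
*expected* to exceed chance on overlap samples even under the null, and
the calibration claim is that no stage manufactures signal where none
should remain.

Known limitations: the inversion is exact only insofar as the consortium
behaved like a fixed-effect meta-analysis that used the same overlap
summary; mixed meta schemes, genomic-control corrections, or covariate
mismatches between the cohorts break exactness (the Z method degrades
most gracefully).  Binary-trait effective sample sizes, multi-cohort
subtraction, VCF-encoded summaries and genome-build liftover are out of
scope.
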