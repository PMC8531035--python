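# Methods

## Scope and data model

`targetmr` implements a drug-target Mendelian randomization (MR)
prioritization workflow on GWAS *summary statistics*: per-variant effect
estimates (β, SE, p, effect-allele frequency, N) for quantitative exposures
on the per-SD scale and binary outcomes on the log-odds scale, plus an LD
reference (dosage panel or precomputed signed correlation matrix), gene
annotation with druggable flags, a tissue × gene normalized-expression (NX)
matrix, and free-text drug-annotation tables. Coordinates are 1-based
inclusive (GRCh37 convention). Variants are matched across datasets by
(chromosome, position, allele set), never by rsid, because rsid versions
drift between consortium releases.

## Harmonization

Outcome effects are aligned to exposure effect alleles: allele swaps flip
the sign and complement the frequency; strand flips (A↔T, C↔G complements)
are reconciled first. Palindromic variants (A/T, C/G) cannot be
strand-resolved from alleles: by default they are dropped when MAF ≥ 0.3 in
either dataset and aligned by comparing which allele is minor below that;
a `drop_all` mode removes every palindrome instead (the conservative choice
when the two datasets' frequencies are not comparable). Harmonization is
involution-safe — re-harmonizing an already-harmonized pair is a no-op —
and every dropped record is counted and logged, never silent.

## Reference-panel QC and LD

The LD panel (default 5000 individuals, emulating a random biobank subset)
is filtered with a tiered MAF/quality rule: variants need MAF ≥ 0.001 and
imputation quality ≥ 0.3, and lower-frequency variants need progressively
higher genotype certainty (MAF < 0.005 → gprob ≥ 0.9; < 0.01 → ≥ 0.8;
< 0.03 → ≥ 0.6). LD is the Pearson correlation of dosage columns, signed
relative to effect alleles; missing dosages are mean-imputed per variant —
deterministic and standard for reference panels.

## Instrument selection

Genome-wide instruments: exposure p ≤ 1e-6, MAF > 0.01. Gene-centric (cis)
instruments: p ≤ 1e-4 within the gene body ± 50 kb. Both are thinned by
greedy LD clumping — scan candidates by ascending p (ties broken by
position) and keep a variant iff r² < 0.4 against everything already kept.
Clumping is deterministic and invariant to input row order. The relaxed cis
threshold trades some winner's-curse bias for coverage of targets without
genome-wide-significant lipid signals; residual correlation below the
clumping threshold is handled by the GLS error model, not ignored.
`grid_search_calibration` reproduces the window × r² sensitivity analysis
used to justify (50 kb, 0.4) on positive-control genes; its "consistency"
metric — fraction of controls with the expected effect direction plus
estimate stability — is reported for inspection, never optimized over
automatically.

## Estimation

With instrument effects βₓ (exposure) and β_y (outcome), the GLS estimator
solves β_y = Xθ + ε, ε ~ N(0, Σ), Σ = diag(SE_y)·R·diag(SE_y):

* IVW: X = βₓ (through the origin), 1 parameter;
* Egger: X = [1, βₓ] after orienting every βₓ ≥ 0 (β_y sign-flipped in
  step), so the intercept measures directional pleiotropy.

Cochran's Q is the whitened residual sum of squares with df = n − k;
per-variant contributions are squared whitened residuals (exact shares
under identity LD; under general LD the triangular whitening assigns shared
misfit to the later variant, which is adequate for ranking outliers).
Random-effects variants multiply all variances by max(1, Q/df)
(multiplicative overdispersion). A single instrument reduces exactly to the
Wald ratio β_y/βₓ with the first-order delta SE.

**Model selection** follows the Rücker-type sequence: start from
fixed-effect IVW; if its Q is significant (α = 0.05) *and* the drop
Q_IVW − Q_Egger exceeds the χ²(1) critical value, heterogeneity is
attributed to directional pleiotropy and the Egger family is used (≥ 3
variants required); within the family, random effects are used iff the
family's own Q p-value < α. Gating the Egger comparison on observed
heterogeneity matters: an ungated Q-difference rule selects Egger in ~6% of
clean-null replicates, and the selection-conditioned bias of those fits
drags 95% CI coverage below 90%.

**Outlier pruning** removes one variant per iteration *only while* the
selected model's global Q p-value < 0.001: a high-leverage variant (hat
leverage > 3× mean) with the largest Q contribution if one exists,
otherwise the largest contributor outright; the model is re-selected after
each removal, with floors of 1 variant (IVW) / 3 (Egger). Pruning is gated
on significant heterogeneity so that a dominant but *consistent* instrument
(the typical cis lead variant) is never discarded merely for being strong.

**Multivariable MR** stacks the per-exposure βₓ vectors as design columns
(no intercept) in the same GLS; a condition number above 1e8 raises a
collinearity error. The joint Q is reported as residual-pleiotropy
evidence.

Numerical choices: Σ is factorized by Cholesky with no regularization when
it succeeds (so oracle identities hold to machine precision); on failure a
ridge on R's diagonal escalates 1e-8 → 1e-4 before a conditioning error.
P-values are two-sided normal (no small-sample t correction). Uncertainty
in βₓ is ignored (first-order two-sample practice); this attenuates
estimates under weak instruments and costs 1–3 points of CI coverage at
strong θ — documented, not corrected.

## Colocalization

Per-variant evidence is Wakefield's log approximate Bayes factor,
labf = ½(log(1−r) + r·z²) with r = W²/(W² + SE²). Prior effect SDs are the
conventional defaults W = 0.15 (per-SD quantitative) and 0.2 (log-odds
binary). The five hypothesis sums (none / exposure-only / outcome-only /
distinct / shared causal variant) are accumulated with log-sum-exp —
labf can exceed 700, so linear-space sums would overflow — with priors
p1 = p2 = 1e-4, p12 = 1e-5; the H3 cross-term uses a log-space difference
that degrades gracefully to PP3 = 0 for single-variant regions.
Colocalization is declared at PP4 strictly above 0.8.

Regions with several exposure signals are first decomposed by a COJO-style
stepwise conditional analysis on z-scores with the reference LD: repeatedly
add the variant with the smallest conditional p < 5e-8, skipping candidates
with r² > 0.9 against selected leads; conditional effects come from the
joint system R⁻¹z (a summary-statistic simplification without per-variant
sample-size adjustment). Each signal is then colocalized separately with
both traits' statistics conditioned on the *other* leads; with zero or one
signal, marginal statistics are used. The single-causal-variant assumption
within each conditional slice is inherited from the hypothesis framework
and can yield false negatives in regions where the decomposition is
imperfect.

## Tissue specificity

Both metrics are computed on log2(NX + 1) by default (raw-scale variants
are exposed): tau = Σ(1 − x̂ᵢ)/(n − 1) with x̂ᵢ = xᵢ/max(x), ranging 0
(housekeeping) to 1 (single-tissue); z-scores standardize the log profile
across tissues, and tissues with z > 1 (strict) are reported as "top
tissues". Tau is exactly scale-invariant pre-log; after the log transform
the invariance is approximate and degrades for dimly expressed genes (the
deviation decays only logarithmically in expression, ~0.03 for 1.33-fold
and ~0.06–0.07 for 2-fold rescaling of typical graded profiles), which is
why the raw variant is kept alongside. A flat profile yields tau = 0 with
no top tissue; an all-zero profile is an error, not a zero.

## Prioritization

Estimates arrive per SD *increase* of each lipid and are recoded to the
therapeutic direction — lower LDL-C/TG, higher HDL-C — so
therapeutic OR < 1 always reads "beneficial". Replication concordance
counts, among replication-significant estimates (p < 0.05, matched by gene
× lipid), those whose therapeutic OR lies on the same side of 1 as
discovery; the denominator is estimate-level, not target-level. Quartile
summaries use linear-interpolation quantiles of per-SD-increase ORs among
significant estimates (groups below 4 are skipped). The discovery p-value
batch is compared against Uniform(0,1) with a two-sided KS test as a bulk
false-positive check. Drug-annotation matching is case-insensitive stem
matching (lipo/lipid/ldl/hdl/cholest/triglyceride by default) as substrings
(catches "hyperlipidaemia") or token prefixes; adverse-event records with
zero affected participants are excluded. The phenome scan reports, per gene
× phenotype, the minimum p among variants in the gene ± 50 kb window
(inclusive bounds) after removing high-MAF palindromes, flagged at 5e-8.

## Synthetic data

The generator emulates the statistical structure of consortium GWAS
without any downloads:

* **Genotypes**: latent AR(1) Gaussians (corr ρ^|i−j|, default ρ = 0.8 per
  5 kb step) dichotomized at MAF-implied thresholds and summed over two
  haplotypes. The panel LD is the empirical dosage correlation; the
  dichotomized correlation is validated against its numeric-integration
  value.
* **Two-sample GWAS**: disjoint cohorts for exposure and outcome by
  construction. Exposure phenotypes are unit-variance with correlated
  residuals across the three lipids; marginal OLS per variant. The binary
  outcome (case fraction 0.3) follows a logistic liability with per-variant
  direct effects; marginal effects use a one-step score approximation
  (validated against full per-variant logistic fits to within 2% for
  |β| < 0.3).
* **The bundled study**: 11 gene regions × 30 variants, each region's lead
  explaining ~1.4% of its lipid's variance (the scale of major lipid loci
  at drugged targets), with target→disease slopes of 0.5–1.2 in magnitude
  chosen to produce per-gene ORs in the range real drug-target analyses
  report. Controls are planted: a positive control that replicates and
  colocalizes, a target whose disease effect reverses in replication, a
  region whose outcome signal sits on a distinct variant (PP3 control), a
  null target, and a non-druggable gene that must never be reported.
  Discovery cohorts are 20k/20k; replication pairs a smaller exposure GWAS
  (8k) with a larger outcome GWAS (30k), the usual shape of a biomarker
  panel replicated against a biobank. These sizes are scaled down from
  consortium scale to keep the full pipeline under ~5 s; effect sizes were
  scaled up accordingly so that power at desk scale mirrors power at full
  scale.
* **Summary-level route**: for replicate-heavy calibration studies,
  estimates are drawn directly from their asymptotic law
  (β̂ ~ N(R·β_joint, SE²·R)) — exact in the large-n limit and orders of
  magnitude faster. Directional pleiotropy is applied relative to the
  exposure-raising allele, since a fixed intercept under random allele
  orientation averages out and is not directional at all.

What the generator does **not** emulate: real-genome LD maps and allele
frequencies, population stratification, sample overlap between exposure
and outcome GWAS, imputation artifacts, and rsid/strand messiness beyond
planted palindromes. Passing tests therefore demonstrate statistical
correctness of the machinery under a faithful two-sample structure, not
robustness to every real-data pathology.

## Verification approach

Estimators are checked against independent oracles: closed-form IVW under
identity LD (to 1e-10), the Wald ratio for single instruments (machine
precision), brute-force greedy clumping, enumeration over causal-variant
assignments for ≤ 6-variant colocalization (to 1e-9), quadrature for the
ABF, and Monte-Carlo resampling for the delta-method SE (compared on the
16–84% interquantile half-width, since the ratio of normals has no finite
variance). Calibration studies (seeded) verify ~95% CI coverage across a
θ × n_snps grid, uniformity of null p-values after model selection, ≥ 90%
PP4 > 0.8 under shared-causal simulations, and PP3 modality under
distinct-causal simulations. CI coverage runs at 92.5–95%: slightly below
nominal by design, because the error model ignores exposure-side noise.

## Known limitations

* Weak-instrument attenuation is documented, not corrected (no modified
  weights, no Steiger filtering); no weighted-median/mode or MR-PRESSO
  estimators — the model-selection framework is the pleiotropy defence.
* The stepwise conditional decomposition is a simplification of joint
  conditional analysis (no per-variant N adjustment) and inherits the
  single-causal-variant assumption per slice.
* MVMR with highly correlated exposures can be imprecise; the collinearity
  guard raises an error rather than silently regularizing.
* Expression scoring consumes a consensus NX matrix as given; building
  that consensus across transcriptomics datasets is upstream of this
  package.
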