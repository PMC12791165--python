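# Methods

`npqmap` implements the full analysis chain used to map the genetic basis of
non-photochemical quenching (NPQ) and photoprotection in a field-grown
diversity panel: kinetic trait extraction from chlorophyll-fluorescence
traces, spatially corrected mixed-model adjusted means, genome- and
transcriptome-wide association, and ensemble candidate-gene calling.  This
note records the models, the parameters that matter, the numerical choices,
and what the synthetic study does and does not emulate.

## Fluorescence traits

Each leaf disc yields a dark-adapted reference (Fo, Fm), then pulse
measurements (F, Fm′) over 10 min of 2000 µmol m⁻² s⁻¹ actinic light and
12 min of darkness.  Derived series:

* NPQ(t) = (Fm − Fm′)/Fm′, ΦPSII(t) = (Fm′ − F)/Fm′, Fv/Fm = (Fm − Fo)/Fm.
* In darkness the steady-state F relaxes to Fo′, so the measured dark-phase
  ΦPSII equals the light-adapted maximum efficiency Fv′/Fm′.  We rely on
  this identity rather than an Fo′ estimate: with the Oxborough–Baker
  correction Fo′ = Fo/(Fv/Fm + Fo/Fm′) the "observed" Fv′/Fm′ is an exact
  algebraic function of NPQ and the photoprotection index would be
  identically 1, carrying no information.

Three exponential models are fitted per disc:

* induction (light): y = aNPQi (1 − e^(−kInd t))
* relaxation (dark): y = aNPQr e^(−kRel t) + bNPQ
* ΦPSII recovery (dark): y = aΦPSII (1 − e^(−kRec t)) + bΦPSII

Rates are in min⁻¹; dark-phase time is re-zeroed at lights-off.  The fits
use variable projection: for fixed k the linear coefficients solve 1×1 or
2×2 normal equations in closed form, so the nonlinear problem reduces to a
deterministic 1-D search over k (45-point log-grid on [0.01, 40] followed by
bounded refinement; search bounds [1e−3, 50]).  There are no random
restarts; noiseless traces are recovered to relative error below 1e−6.  A
fit is flagged unconverged when the amplitude is indistinguishable from
zero (|a| < 1e−4 × series scale, making k unidentifiable) or k lands on a
search bound.

Derived traits: max NPQ (largest light-phase NPQ), initial slopes (OLS over
the first 60 s; induction anchored at (0, 0) since NPQ is definitionally
zero at lights-on — the dark phase has three samples inside the window and
no anchor), NPQf (observed NPQ at the final dark point, not the fitted
curve), and the photoprotection index

PI = Fv′/Fm′_f / [1 − (1−φ)(1+NPQf) / (φ + (1−φ)(1+NPQf))],  φ = Fv/Fm,

where Fv′/Fm′_f is the measured final dark ΦPSII.  PI = 1 means residual
NPQ explains the whole drop in efficiency; PI < 1 indicates
photoinhibition.  The typeset form of this expression is ambiguous; the
parse above is the only one consistent with PI ≈ 0.82 at the published
φ = 0.75 and NPQf = 0.89.

QC replaces visual curve inspection with reproducible rules: discs with
Fv/Fm < 0.65 (strictly below) are dropped; discs with any unconverged fit or
fit R² < 0.8 (configurable) lose all traits.

## Mixed models, BLUPs and heritability

Per-disc traits are averaged per plot (the design models plot-level
row/column structure) and fitted by REML:

* per year: y = 1µ + Z₁g + Z₂s + Z₃b + e
* joint: y = 1µ + Xt + Z₁g + Z₂s + Z₃b + Z₄gt + e

with random genotype g, set s, block-within-set b, genotype-by-environment
gt, fixed environment t, and residual e either independent or AR1×AR1 over
field rows and columns (separable first-order autoregressive correlation;
one field per environment, shared ρ parameters).  The structure is chosen
by AIC by default.  The likelihood is profiled over log-variances and
atanh-correlations with L-BFGS-B (numeric gradients, relative tolerance
1e−10, variance floor 1e−8 × var(y)); the response is centered internally
so estimates are exactly shift-invariant.  BLUPs, their prediction error
variances (PEV) and conditional residuals come from the converged
components; boundary variance estimates are reported, not errors.

Outliers follow the median/re-scaled-MAD residual rule: standardized by
1.4826×MAD, two-sided normal p-values under Bonferroni–Holm control at
α = 0.05; the model is refit once without flagged plots (single pass, by
design).  Two robustness guards: if the rule flags more than 20% of
observations the flags are ignored with a warning (a normal-tail rule
flagging that much signals a collapsed MAD, not outliers), and if the
refit becomes infeasible (e.g., removal empties an environment) the
original fit is kept with a warning.

Generalized heritability is reported exactly as printed in the source
protocol, H² = 1 − mean(PEV)/σ²g.  Note the Cullis formulation uses the
mean variance of a BLUP difference over 2σ²g; the two differ slightly, and
we deliberately implement the printed form.  H² is reported as 0 (flagged)
when σ²g sits at its boundary.

Trait correlations are Pearson on accession-matched BLUPs with Holm
step-down adjustment across pairs.  The Multi-trait Score is the sum of
panel-standardized (z-scored) joint-model adjusted means of max NPQ, NPQ
relaxation k and PI, ranked descending.

## GWAS

Genotypes (biallelic dosages from VCF; missing calls mean-imputed with a
warning) are filtered to minor allele count ≥ 20 and LD-pruned with plink
`--indep-pairwise 50 10 0.9` semantics (windows of 50 SNPs advanced by 10;
within a window the higher-r² pair member with the smaller MAF is removed
until no pair exceeds 0.9).  Kinship is the centered cross-product matrix
normalized to mean diagonal 1; five principal components are computed from
the pruned dosages and the count actually used per trait (0–5) is chosen by
BIC on the null covariate model.

The univariate scan is the Q+K linear mixed model y = Wα + xβ + u + ε,
u ~ N(0, σ²g K).  The variance ratio λ = σ²g/σ²ε is estimated once per
trait by 1-D profile REML on the eigendecomposition of K under the no-SNP
null; each SNP is then tested by an exact F (Wald) test in the whitened,
covariate-projected regression.  With K = I the procedure is numerically
identical to per-SNP OLS F-tests (verified to 1e−8).  Benjamini–Hochberg
FDR-adjusted p-values are appended.

The combined-trait scan (CT1–CT4) whitens each member trait with its own
null-model λ, forms per-SNP Wald z-scores, and combines them through the
inverse of the null trait-residual correlation matrix into a χ² statistic
with one degree of freedom per trait.  This fixed-variance-component,
z-combination approach approximates a full multivariate mixed model; its
null calibration is verified by simulation (uniform p under permutation).
Responses are checked for collinearity on the correlation scale, so
combos with duplicated or constant members are rejected.

## LD blocks

Blocks follow the D′-confidence-interval method: for every same-chromosome
pair within 500 kb with pairwise r² > 0.2 (and MAF ≥ 0.001), haplotype
frequencies are estimated by EM on unphased genotype counts; a 90% interval
on |D′| comes from the composite (HWE random-union) likelihood profiled on
a |D′| grid of step 0.001 with allele frequencies fixed, read off as the
central 90% of the normalized likelihood.  Strong LD: lower bound > 0.70
and upper bound ≥ 0.98; strong recombination: upper bound < 0.90; pairs
failing the r² prefilter are uninformative.  A candidate block is a
strong-LD pair spanning ≤ 500 kb whose enclosed informative pairs are at
least 95% strong LD (the method's published default; the protocol names
only the CI bounds); candidates are accepted longest-first without sharing
SNPs.

## TWAS

Genes expressed (abundance > 0, configurable) in fewer than half of the
lines are removed.  Ten hidden expression factors are estimated by
Bayesian factor analysis with automatic relevance determination — an EM
iteration on probabilistic PCA with ARD priors on loading columns,
deterministic PCA initialization — standing in for PEER-style latent
confounders; a plain PCA fallback is selectable and is used automatically
on non-convergence.  Per gene, the trait is regressed on abundance with the
10 factors and 5 genotype PCs as covariates; covariates are projected out
once (rank-aware SVD projection, so exactly collinear columns are inert)
and the per-gene test is then a simple regression numerically identical to
the full OLS fit.  Bonferroni-adjusted p-values are reported for reference;
ranking uses raw p (the adjustment is monotone).  The combined-trait TWAS
is a multivariate-response linear model tested with Pillai's trace, which
is exact (Hotelling) for the single-degree-of-freedom expression term and
reduces to the univariate GLM for one-trait combos.

The trait side of TWAS is field-trial adjusted means while expression comes
from controlled-environment-grown lines; the module joins on accession id
and inherits that asymmetry.

## Ensemble candidate calling

Per trait there are 15 analysis cells: GWAS × {2017, 2019, joint} and
{TWAS, FCT} × {GP, 3L} × {2017, 2019, joint}.  Combined-trait sets CT1–CT4
are additional trait columns with the same 15 cells.

* GWAS cell: all genes overlapping LD blocks containing the top 0.05% of
  SNPs by p; SNPs in no block contribute their nearest gene (same
  chromosome, minimum boundary distance, ties to the lower start
  coordinate).  Genes in several top blocks count once.
* TWAS cell: top 1% of genes by p.
* FCT cell: the nearest gene is assigned to the top 10% of GWAS SNPs; each
  gene's minimum assigned SNP p is combined with that tissue's TWAS p by
  Fisher's method (X = −2Σln p ~ χ²₂ₖ; zero p clamped to the smallest
  positive float with a warning); the cell is the top 1% by combined p.
  Genes with no assigned top SNP, or absent from the filtered expression
  set, are excluded from FCT.

Top-fraction counts use ceilings; ties break lexicographically on
(p, chromosome, position).  A gene is a candidate when it appears in ≥ 8
cells for one trait or in ≥ 1 cell of ≥ 10 distinct trait columns; an
externally curated list can be merged with a `manual-annotation` tag (the
package never generates one).

## Synthetic study

The generators emulate the real screen's structure: an augmented block
design (replicated checks connecting incomplete blocks on a row×column
grid; the real trial used 960 plots, 40×24, 16 blocks, 861 accessions),
exponential trace kinetics with accession-level genetic variation,
genotype-by-year interaction, set/block effects and AR1×AR1 spatial
residuals (Kronecker-structured Cholesky on the full grid — exact and
fast), haplotype-block genotypes, and log-normal-scale expression with
hidden factors.  Default kinetic means mirror the published joint-model
panel means (e.g., aNPQi 2.8, kInd 0.58, kRel 5.09, NPQf ≈ 0.89, Fv/Fm
0.75); genetic SDs are set so adjusted-mean ranges across a ~900-accession
panel match the published ranges; genotype-by-year SD equals the genetic SD
(matching the published moderate between-year correlations), and plot
residual SD is 1.2× the genetic SD.

Genotypes use *nested* haplotypes within blocks: one uniform draw per
haplotype against decreasing per-SNP allele frequencies, so derived-allele
carrier sets are nested, no recombinant gametes exist and |D′| = 1 within
blocks while r² varies — direct control for the Gabriel-block tests;
blocks are mutually independent.  This was chosen over coalescent
simulation precisely for that D′ control.  One gene is annotated over each
block's span; additional marker-free genes are scattered into the
inter-block gaps so the gene universe is larger than the block count.

Planted truth: causal SNPs (block centers, evenly spaced across the
genome) and causal transcripts (the same blocks' genes) inject additive
effects into the accession-level kinetic parameters; a causal gene's
expression tracks the same per-accession latent that shifts the trait, in
both tissues.  The dark-phase sampling grid (20 s, 40 s, 1–4 min, then
7, 10, 12 min, the final point pinned at 12 min where NPQf and PI are
defined) leaves the fast relaxation/recovery rate constants (k ≈ 5 min⁻¹)
weakly identified per disc — their estimates are noisy and heavy-tailed,
which is why those traits show the lowest heritability, as in the real
screen.

The default demonstration scale is 200 accessions, 2000 SNPs, ~700 genes,
75% of accessions with expression, and per-allele/per-latent-SD effects of
1.5/2.0 genetic SDs; the end-to-end recovery benchmark uses 120 accessions
and 1200 SNPs with independent-residual mixed-model fits so that 20
replicates run on a single CPU in minutes.  Effects that large are needed
for detectability at this panel size (the real screen had 861 accessions,
450k SNPs and 20k+ genes); the thresholds themselves (0.05%/1%/1%, ≥ 8
analyses, ≥ 10 traits) are never changed.

Because the 14 trait columns are genuinely correlated (they derive from 9
kinetic parameters), a null gene that chances into one trait's top sets
tends to enter correlated columns too — the ≥10-trait rule deliberately
exploits this covariance.  The planted-truth benchmark therefore scores
false candidates against a *permutation oracle*: the TWAS and candidate
stages are re-run with expression line labels permuted (gene-trait links
broken, trait-trait and gene-gene correlation intact), and the observed
false count is compared with the permuted count by an exact binomial test.
An independence-based (Poisson-binomial over cells) expectation would
understate the chance-overlap rate.

What the synthetic data does *not* emulate: realistic population structure
or coalescent genealogies, imputation error, weather covariates, linkage
between blocks, non-additive effects, or expression measured under field
conditions.  Passing the planted-truth tests therefore shows the machinery
is correct and calibrated, not that the real screen's power or candidate
lists would be reproduced.

## Numerical and degenerate-input conventions

* All randomness flows from one root seed through named substreams; equal
  config + seed reproduces byte-identical outputs.
* Zero-variance SNPs: p = 1 (flagged) in GWAS, ignored with a warning in
  kinship; rank-deficient gene designs are skipped and logged in TWAS.
* MAD = 0 → no outliers, with a warning; empty QC input → empty output with
  a warning; accessions whose plots lose every disc to QC drop out of that
  model-year and the genotype/kinship matrices are subset accordingly.
* Accessions absent from one year are predicted (missing-at-random) by the
  joint model through the usual BLUP machinery.

## Known limitations

* The REML engine is dense (O(n³) per likelihood evaluation); it is meant
  for trial-scale data (≤ a few thousand plots), not biobank scale.
* The multivariate GWAS is a calibrated approximation, not a full mvLMM
  likelihood maximization.
* FCT uses the minimum assigned-SNP p per gene; other aggregations are
  possible and would change borderline cells.
* The "10 or more traits" rule counts the 14 single traits plus CT1–CT4 as
  18 columns; the registry is configurable.
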