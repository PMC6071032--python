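# Methods

## The model

Both modalities are modelled as linear mixtures of statistically
independent sources:

    X_d = A_d S_d,   S_d = W_d X_d,   A_d = W_d^{-1},   d = 1, 2

where `X_1` is a subjects × voxels gray-matter-concentration (GMC)
matrix, `X_2` a subjects × SNPs minor-allele dosage matrix (centred,
unit-variance columns), `S_d` the component matrices and `A_d` the
subject loading matrices.  Estimation maximises three objectives in an
interleaved loop:

* **F1 (Infomax, modality 1).**  Natural-gradient ascent on the output
  entropy of the logistic-transformed unmixed signal,
  `Y = 1/(1 + e^-U)`, `U = W X + W_0`, with update
  `W <- W + lr (I + (1 - 2Y) U^T / B) W` over batches of B samples
  (voxels).  The logistic nonlinearity targets the super-Gaussian
  (sparse) sources both modalities carry.
* **F2 (Infomax + reference, modality 2).**  The same update weighted by
  `lambda`, plus a `(1 - lambda)`-weighted gradient on
  `-|| |s~| - r~ ||^2`, where `r~` is a nonnegative unit-norm reference
  vector over one candidate gene's SNP positions and `s~` is the
  constrained component's weight vector restricted to those positions,
  absolute-valued and unit-normalised.  The normalisation Jacobian is
  kept in full (including the radial term, which keeps the update
  tangent to the unit sphere).  For each reference the constrained
  component is re-chosen every epoch as the one whose `|s~|` correlates
  best with `r~`.
* **F3 (loading-correlation enhancement).**  Once per epoch, gradient
  ascent on `Corr^2(A_1i, A_2j)` for at most `max_pairs_f3` loading
  pairs with `|r| >=` 0.1, using the analytic gradient
  `2 r (v_hat - r u_hat) / ||u||`, applied with a step scaled by `||u||`
  so the relative update is scale-free; the unmixing matrices are
  re-derived from the updated loadings (`W = (K A)^{-1}` in the
  whitened space).

Both modalities are PCA-whitened to their component counts before
estimation; loadings are reported in the original subject space.  Each
component's sign is fixed by making its largest-|weight| element
positive.

### Optimiser choices

* Learning rates default to 0.01 per modality, annealed by 0.9 whenever
  the epoch's entropy proxy decreases, and halved (with the previous
  weights restored) on divergence.
* The F3 rate (default 0.02) is multiplied by the current
  modality-2 annealing factor, so the cross-modality coupling fades as
  the decomposition converges and the total enhancement stays bounded.
  Without this the enhancement step never lets the loop meet its
  convergence tolerance and can push null pairs upward without limit.
* The reference gradient is evaluated on the full reduced data and
  scaled by the batch fraction, so one epoch applies one aggregate
  `lr (1 - lambda)` reference step.
* `lambda` defaults to **0.98**.  The reference penalty literally pulls
  the component's absolute normalised weights toward the reference
  profile; when the underlying component is sparse (a few strong loci
  inside a 52-SNP gene), values of `lambda` at or below 0.95 visibly
  flatten it and degrade loading recovery.  At 0.98 the constrained
  component still accumulates at least as much reference-locus weight
  mass as any unconstrained component while recovery is unaffected.
* Convergence: mean |ΔW| < 1e-6 in both modalities; at most 512 epochs;
  batch size 256.

## Genotype QC

Missingness filtering alternates SNP-level and sample-level passes at
5% until stable.  MAF filtering is strict (`> 0.05`).  LD pruning is
greedy within 50-SNP windows sliding by 5, per chromosome: while any
retained pair has dosage r² > 0.5, the lower-MAF member of the worst
pair is dropped (tie: later position).  Relatedness uses a
method-of-moments IBD estimate (PI-HAT = P(IBD=2) + P(IBD=1)/2 from
genome-wide IBS counts and sample allele frequencies); pairs above 0.18
are grouped into families and only the first member of each family is
kept.  Two numerical choices matter at small panel sizes:

* the z estimates are combined **unclipped** — clipping each component
  at zero before combining biases the null upward by several hundredths
  on panels of a few thousand SNPs;
* a pair must also exceed an adaptive noise floor, median + 4×(1.4826
  MAD) of the all-pairs statistic.  The estimator's sampling sd scales
  as ~1/sqrt(effective markers); at a few thousand markers a fixed 0.18
  cutoff sits only ~2.5 sd into the null, and spurious pairs chain
  entire cohorts into one pseudo-family.  On realistically sized panels
  (hundreds of thousands of markers) the floor falls below the cutoff
  and has no effect.

Population structure is summarised by classical MDS (double-centred
eigendecomposition) of the mean-allele-sharing distance matrix; the top
10 factors are offered as optional association adjusters (they are not
regressed from the data).

## GMC preprocessing

Voxel matrices are flattened in C order over the mask.  Each voxel is
residualised by OLS on [intercept, age, sex, site dummies]; L site
levels contribute L − 1 dummies (50 sites → 49 columns).  The fitted
intercept is added back by default so values remain on a
concentration-like scale; the decomposition centres its input, so this
choice only affects interpretability of exported maps (a flag disables
it).  Residuals are orthogonal to every design column to machine
precision, and the operation is idempotent.

## Component post-processing

The maximally correlated loading pair is selected from the full
n1 × n2 correlation table, with two-tailed p from the t transform at
df = n − 2; the table is retained so the Bonferroni family is the pair
family, not the marker count.  Component maps are z-scored (reporting
threshold |Z| ≥ 2.5).  Top SNPs are selected by maximum-likelihood
logistic fit to the component's weights (SD = scale·π/√3), keeping
weights more than 4.25 fitted SDs from the fitted location; restricted
loadings are the selected weights multiplied into the (mean-imputed)
genotypes of those SNPs.

## Validation

* **Permutation.**  Rows of modality 2 are shuffled, the full
  decomposition is rerun (per-permutation seed derived from the master
  seed), and the max-pair |r| recorded; the exceedance ratio is
  #(null ≥ |observed|)/n_perm with the observed run excluded.  A
  labelled fast mode only re-correlates the fixed observed loadings;
  it is an approximation used for calibration studies, never for the
  headline ratio.
* **K-fold.**  Subjects are partitioned into k folds; the decomposition
  is rerun on each 90% complement; components are matched to the
  full-run components by max |weight-vector correlation| and the
  matched pair is declared replicated when significant at 0.05 after
  pair-family Bonferroni.
* **Influence.**  For the simple regression of one loading on the
  other: hat values, externally studentized residuals, and Cook's
  distances (all standard formulas, cross-checked against a delete-one
  refit oracle to 1e-10).  A subject is flagged when Cook's D > 4/n
  **and** leverage > 3p/n.  The leverage gate is deliberate: with
  Gaussian loading noise, a pure 4/n rule flags dozens of
  ordinary-leverage subjects whose residuals happen to be large; those
  are discrepant but not influential in the leverage sense this
  analysis targets (subjects at the extremes of the genetic profile).
  Both thresholds are exposed.

## Clinical associations

Per measure, OLS of score on [intercept, covariate (+ optional
adjusters)] over complete cases; the covariate F equals the squared t
of its coefficient (df1 = 1).  Bonferroni family defaults to the
7-measure battery.  Direction metadata (timed tests and the motor score
are higher-is-worse; symbol-digit and Stroop counts are
higher-is-better) maps the effect sign to a protective/deleterious
call; flipping a measure's metadata flips the call and nothing else.

## The synthetic cohort

The generator emulates the statistical structure of a multi-site
prodromal Huntington's cohort, not its physiology:

* **Genotypes.**  Per-SNP MAF ~ U(0.1, 0.5); latent Gaussians with
  equicorrelated LD blocks (size 10, latent rho 0.7) thresholded at
  Hardy-Weinberg quantiles; 0.2% missingness; 3 near-duplicate subject
  pairs (latent copy + 5% perturbation) standing in for relatives.
* **Components.**  SNP components are sparse Laplace weight vectors;
  the coupled component carries ten dominant loci (|weight| ~ U(6, 8)
  before normalisation), four inside the 52-SNP NTRK2-analogue
  reference gene and six outside all nine reference genes, each in its
  own LD block.  GMC components are pairs of compact Gaussian blobs
  (sigma 1.5–2.5 voxels) with component-disjoint centres on an
  ellipsoid-masked grid — larger overlapping blobs make the spatial
  sources correlated and cap recovery.
* **Coupling.**  The preset embeds one coupled pair at r = 0.17 carried
  by 28 tail subjects whose SNP loadings sit 2.2–4 SD from the mean
  (the bulk is truncated at 0.82× the lower bound, so after
  standardisation the planted tails are exactly the subjects with
  |z| ≥ 2).  The GMC loading is c·(x restricted to tails) + e with e
  orthogonalised jointly against the bulk- and tail-restricted SNP
  loading and c solved in closed form, making the realised full-sample
  correlation exactly rho and the bulk-only correlation ~0 by
  construction.
* **Signal strength.**  The SNP-side signal enters the latent Gaussians
  before thresholding with a total variance budget of 400 (mean per-SNP
  fraction 0.08 at 5,000 SNPs), distributed proportionally to squared
  component weights and capped at 0.85 per SNP.  The budget is the
  level at which ICA loading recovery stays at correlation ~0.95–0.98
  with the planted loadings while the diffuse component signal does not
  masquerade as genome-wide relatedness.  It is a total, not a per-SNP
  rate, so reduced panels keep comparable detectability.  The GMC side
  uses additive noise sd 0.02 against component amplitude 8.
* **Confounds and clinical scores.**  Age, sex and per-site offsets are
  added linearly to the voxel data (removable exactly by the nuisance
  regression).  Seven clinical scores are linear in the coupled GMC
  loading with per-measure effects sized to an F-statistic near the
  preset target (5.5; noise orthogonalised so the planted effect is
  exact before missingness), 5.7% per-measure missingness, directions
  as in the real battery.  CAG repeats are drawn from N(42.5, 2.5²)
  truncated at ≥ 36.

What passing tests on this cohort do **not** show: robustness to
nonlinear site effects, scanner artifacts, genotyping batch structure,
realistic LD decay or allele-frequency spectra, or non-Gaussian voxel
noise.  The generator's study-condition facts (715 subjects, 50 sites,
rho = 0.17, 28 tail subjects, CAG moments) are fixed by the preset; the
signal/noise parameters above are generator design choices documented
here and held fixed across all analyses.

## Problem sizes and runtime

The validation studies run at desk scale on one CPU: the full preset is
715 × 5,000 SNPs × 8,000 voxels (~10 s per end-to-end run), the
permutation study uses a 2,000 × 2,000 reduction with 100 full reruns
(~4 minutes), and the unit suites use cohorts of 120–400 subjects.
These sizes were chosen so the whole suite reruns comfortably on a
laptop while keeping every statistical claim at the preset's full
subject count, which is what the claims depend on.

## Known limitations

* The reference constraint assumes the candidate-gene prior is profile-
  shaped (uniform over the gene's SNPs by default); when the true
  component is much sparser than the prior, small `1 - lambda` weights
  are required.
* The relatedness estimator approximates PLINK's genome-wide IBD
  method of moments; exact PLINK parity (allele-frequency small-sample
  corrections, per-pair frequency recomputation) is out of scope.
* The permutation test reruns the decomposition with a derived seed per
  permutation; with annealing and batch shuffling the null therefore
  includes optimiser variability, which is intended (the observed run
  includes it too).
* Whether LD pruning should span chromosomes is treated as per-
  chromosome (windows never cross a chromosome boundary).
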