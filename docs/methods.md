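# Methods

## Model

`brainvc` fits a Bayesian variance-components regression for a standardized
phenotype on a massive set of standardized imaging-derived features (IDFs),
designed for the regime where the feature count B far exceeds the
participant count n (brain-wide association studies typically have
B/n of 5–10 or more). For phenotype vector Y (length n) and feature matrix
X (n × B), the generative model is

    Y = X β + ε,        ε ~ N(0, (1 − h²) I_n)
    β ~ N(0, h² Ψ)

with Y and the columns of X standardized, so the total phenotype variance
is 1 and h² ∈ (0, 1) is the fraction of variance explained (FVE) by all
features jointly — the imaging analogue of SNP heritability. The diagonal
matrix Ψ allocates the total prior variance h² across features through a
softmax of annotation scores: for a B × M annotation matrix Z with rows
z_k and weight vector α,

    Ψ_kk = exp(z_kᵀ α) / Σ_j exp(z_jᵀ α),

so Σ_k Ψ_kk = 1 and the sum of the prior effect variances is exactly h².
With α = 0 every feature gets h²/B — the homoscedastic GCTA model. A
positive weight α_m means each feature carrying annotation m explains
exp(α_m) times as much variance, on average, as one that does not (the
*enrichment ratio*). Hyperpriors: h² ~ Beta(a, d) (default a = d = 1,
uniform) and α ~ N(0, σ_α² I) (default σ_α² = 100, diffuse).

### Assumptions

- Effects are a priori independent across features given Ψ; the Monte
  Carlo harness (below) probes violations of exactly this assumption.
- Noise is homoscedastic Gaussian; covariate structure must be removed
  beforehand by residualization (`features.residualize`).
- Annotations act on the *variance* of effects, not their sign or mean.

## Inference

Because B ≫ n, β is integrated out analytically; the collapsed likelihood
is the n-dimensional Gaussian

    Y | h², α ~ N(0, V),   V = h² X Ψ Xᵀ + (1 − h²) I_n.

The sampler is random-walk Metropolis on the collapsed posterior
p(h², α | Y): proposals on logit(h²) (with Jacobian) and on α, accepted
against the marginal likelihood plus priors. This was chosen over
Metropolis-within-Gibbs conditioning on β, which mixes poorly because β
and h² are strongly coupled a posteriori. β itself is drawn *exactly* from
its Gaussian conditional posterior once per collected iteration using a
perturbation (Matheron) construction that needs only an n × n solve —
draw u ~ N(0, h²Ψ), δ ~ N(0, (1−h²)I), solve V w = Y − (Xu + δ), return
u + h² Ψ Xᵀ w — never forming a B × B matrix (mandatory at B ≈ 6 × 10⁴).
The per-iteration statistic R̂² = var(Xβ)/var(Y) is recorded as the
empirical variance explained, which should track h² when the model fits.

α updates default to a *hybrid* scheme: one joint Gaussian random-walk
proposal plus one single-coordinate proposal per iteration (a valid
random-scan kernel). A full componentwise sweep (available via
`McmcConfig.alpha_update`) costs M marginal-likelihood factorizations per
iteration, i.e. O(M n³); the hybrid gets comparable per-coordinate mixing
at three factorizations per iteration. Proposal scales adapt during
burn-in by Robbins–Monro on the log scale (targets: 44% acceptance for
scalar updates, 30% for the joint block) and are frozen afterwards, so the
post-burn-in chain is a fixed Markov kernel. Proposals with h² outside
(10⁻⁸, 1 − 10⁻⁸) are rejected, not clamped, keeping the stationary
distribution exact on the open interval.

Default schedule (the real-data convention): 10,000 iterations per chain,
3,000 burn-in, thinning 10, six independent chains with per-chain seeds
`seed + chain`. Chains are pooled by intermixing before summarization;
intervals are equal-tailed 95% percentile intervals with linear
interpolation between order statistics (recorded because conventions
differ). Enrichment intervals exponentiate the α interval endpoints,
exact for percentile intervals under a monotone transform.

### Numerical strategy for the likelihood

`MarginalLikelihood` groups features by their unique annotation rows.
Binary network annotations give at most M + 1 groups, so
X Ψ Xᵀ = Σ_g ψ_g (X_g X_gᵀ) with per-group Gram matrices precomputed once;
each evaluation then costs O(G n² + n³) instead of O(n² B). With a single
group (no annotations) Ψ does not depend on α, so X Xᵀ/B is
eigendecomposed once and each evaluation is O(n). Otherwise a dense
O(n² B) build is used. V is always formed explicitly as n × n; no
B-dimensional formulation is provided for B < n (known limitation — the
intended regime is B ≫ n).

### Identifiability of α

The marginal likelihood constrains each α_m only from above: as
α_m → −∞ the annotated group's variance share vanishes and the likelihood
plateaus, so the depletion direction is flat and the posterior tail there
follows the prior. Two consequences shaped the defaults of the Monte
Carlo harness (the `PriorSpec` default stays diffuse for large-n data
analysis):

1. **A baseline category is needed.** If every feature is annotated by
   exactly one of M one-hot annotations, the softmax is invariant to
   adding a constant to α and individual weights are identified only
   through the prior. The simulated annotation matrices therefore leave
   10% of features unannotated (ten disjoint annotations of 9% each),
   analogous to the dominant between-network/unlabeled edges of real
   connectivity data.
2. **The harness uses a weakly-informative α prior** (σ_α² = 4). Under a
   very diffuse prior the α posterior mean is dominated by excursions into
   the flat region, and large positive excursions concentrate the softmax
   onto one group, destabilizing h². Accurate recovery of a depletion
   weight like −1.13 is impossible under a flat prior at any sample size.

## Preprocessing (`features`)

Edge features are Fisher z-transformed correlations, vectorized from the
upper triangle in row-major (i < j) order over the declared node order
(the ordering is a package convention; edge IDs are "A-B" strings).
Correlations within 10⁻⁷ of ±1 are clipped with a warning. Within-network
annotations mark edges whose two endpoints share a network label, with a
"None–None" column for edges between unlabeled nodes. Residualization is
ordinary least squares per column on an intercept plus covariates
(categorical covariates must be indicator-coded); standardization uses the
n − 1 denominator and stores the training moments so held-out cohorts can
be transformed either with their own moments (default, mirroring
independent processing of a second study) or the training moments.

## Monte Carlo validation harness (`simulate`)

The generator reproduces the validation design: standardized X (iid,
equicorrelated, or block-correlated columns), ten disjoint binary
annotations with weights α₁ = −1.13 (depleted) and α₂ = 0.38 (enriched),
effects drawn with marginal variances h² Ψ_kk and AR(1) cross-feature
correlation ρ^|k−k'|, and Y = Xβ + ε with noise variance 1 − h², then
standardized. Note the AR(1) covariance uses the square-root form
h² √(Ψ_kk Ψ_k'k') ρ^|k−k'|, so its diagonal equals the model's prior
variance and ρ = 0 reproduces the model prior exactly. Annotated features
are contiguous in feature order, so AR(1)-correlated effects mimic
network-adjacent edges having similar effects. True effect vectors are
reported on the standardized-Y scale so coverage compares like with like.

Two drivers:

- `run_grid_experiment` sweeps ρ × h², scoring pooled and per-chain CI
  coverage of (h², α₁, α₂), per-feature β coverage, and the R̂²–ĥ²
  alignment. Default dimensions are desk-scaled to n = 600, B = 3000
  (preserving the ~1:5 participants-to-features ratio of the full-scale
  design; any dimensions can be requested). The default design is
  block-correlated (blocks of 50, within-block r = 0.5): connectivity
  edges sharing a node are substantially correlated in real data, and that
  correlation is what makes h² well identified — with iid columns at
  n = 600 the h² posterior is much wider.
- `train_test_shrinkage_experiment` repeats the train/test design under
  the no-annotation prior: per split, fresh β ~ N(0, h²/B I) with
  h² = 0.32, fit on n_train = 1500, score the held-out n_test = 300 by the
  squared correlation of X_ts β̂ with Y_ts. The in-sample posterior median
  clusters near the truth while the out-of-sample value is systematically
  smaller (estimation noise in β̂).

`simulation_based_calibration` closes the loop on sampler correctness:
parameters drawn from the prior, data from the model (no post-hoc
standardization, so generative and inferential models coincide), and the
rank of each true parameter among thinned posterior draws must be uniform;
a chi-square test on binned ranks is reported per parameter. The test
suite includes a negative control in which a deliberately doubled
log-likelihood breaks uniformity.

### What the generator does and does not emulate

It reproduces the dimensional regime, the annotation structure, the
effect prior and its AR(1) violation, and (optionally) blockwise column
correlation. It does not reproduce the eigenstructure of real
connectivity matrices, site/scanner structure, non-Gaussian phenotypes,
or motion artifacts — so passing recovery here demonstrates correctness
of the inference machinery under the model and controlled violations of
the effect prior, not robustness to everything real data can do. Bias
magnitudes under ρ ≥ 0.6 depend on the real design matrix and are checked
only directionally.

## Problem sizes and tolerances

Test-suite recovery runs use n = 600, B = 3000 with five independent
replicate datasets per h² setting (one 2,500-iteration chain each —
replicates, not extra chains, are what frequentist coverage counts need,
since chains within a replicate share one posterior); the reproduction
script (`scripts/acceptance.py`) runs the grid at the same dimensions
with two chains of 4,000 iterations per setting and the shrinkage
experiment at its stated dimensions — the package's chosen desk-scale
conditions. Chain length matters for calibration: short chains
under-disperse ĥ², which narrows the per-feature β intervals and
depresses measured coverage. Oracle
equivalences (dense-formula likelihood, explicit joint marginalization,
conditional-β moments) are asserted at 10⁻⁸; Monte Carlo checks use
3–5 standard-error bands.

## Known limitations

- No B < n formulation of the marginal likelihood.
- No REML/maximum-likelihood estimator; inference is Bayesian only.
- One variance component: no disjoint multi-component partitioning.
- No variational approximation, parallel tempering or HMC.
- Single-annotation reports are nominal; no multiplicity correction
  across annotations entered one at a time.
- The α posterior is heavy-tailed toward depletion by construction;
  posterior means of strongly negative weights are prior-sensitive.
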