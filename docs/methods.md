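# Methods

This note documents the statistical models, numerical choices and known
limitations of `landgen`. It is written for users who want to know exactly
what is computed, not just how to call it.

## Haploid diversity statistics

All statistics operate on haploid calls (one allele per individual and
locus; missing is a first-class state, code −1).

* **PL** — percent of loci with ≥2 distinct observed alleles in the
  population, out of the loci with ≥1 observed call.
* **n_a** — mean number of distinct observed alleles over *all* loci; a
  locus with no observed call in the population contributes 0. This is why
  n_a can fall below 1 in heavily missing populations.
* **H_S** — per locus with n ≥ 2 observed calls, the small-sample-corrected
  gene diversity n/(n−1)·(1 − Σₖ pₖ²); averaged over those loci. A
  population where every such locus is monomorphic has H_S = 0.

**Weir–Cockerham θ.** For each population pair, locus and allele with at
least one call on both sides and positive pooled within-population degrees
of freedom (n₁ + n₂ − 2 > 0):

    MSP = Σᵢ nᵢ(pᵢ − p̄)²/(r−1)        r = 2
    MSG = Σᵢ nᵢpᵢ(1−pᵢ)/Σᵢ(nᵢ−1)
    n_c = (Σnᵢ − Σnᵢ²/Σnᵢ)/(r−1)
    a = (MSP − MSG)/n_c,  b = MSG

and the multilocus estimate is θ = Σa / Σ(a+b) over all informative
(locus, allele) cells. Negative estimates are kept (no clamping); pairs with
Σ(a+b) = 0 — e.g. two populations fixed for the same allele everywhere —
are reported as NA and excluded from the mean/SD summary. Loci where both
samples are singletons (n₁ = n₂ = 1) are excluded because MSG is undefined.
The formulas are written per-allele, so multiallelic codes work unchanged;
for biallelic SNPs both alleles contribute symmetrically.

**Multilocus genotypes.** Two individuals share an MLG iff their call
vectors are identical at every locus with missing treated as its own state
(exact matching; no distance threshold). The mean pairwise difference
averages, over unordered pairs of distinct MLGs, the proportion of
pairwise-complete loci at which they differ; with fewer than two MLGs (or no
complete locus for a pair) the quantity is NA.

**Locus filter.** Loci are dropped when the missing fraction strictly
exceeds the cutoff (default 0.25) or, optionally, when at most one allele is
observed overall. The filter reports every dropped locus with its reason.

## Spatial hurdle-Beta model

Gene diversity over many populations is semi-continuous: a sizable fraction
of populations are (near-)monomorphic. The model separates the two regimes
at a threshold (default H_S = 0.009, chosen to split a bimodal empirical
distribution at its gap):

    z_i ~ Bernoulli(π_i)              logit π_i = α_z + X_i β_z + u_z(s_i)
    y_i | z_i = 1 ~ Beta(μ_i φ, (1−μ_i) φ)   logit μ_i = α_y + X_i β_y + u_y(s_i)

with independent exponential-kernel Gaussian processes
u ~ GP(0, σ² e^{−d/range}) per component (a deliberate simplification: one
shared field is a config option, but independent fields let the zero process
and the diversity process decouple spatially). The Beta "precision"
parameterization implies Var(y|μ,φ) = μ(1−μ)/(1+φ).

**Priors** (covariates are z-scored first): Normal(0, 5) on intercepts and
slopes; half-Normal(1) on σ; Gamma(shape 2, rate 0.1) on φ; LogNormal with
unit log-SD centered on a quarter of the domain diameter for the range.
Coordinates must be projected (km); inputs that look like lon/lat degrees
are rejected unless explicitly overridden, because the kernel distance is
Euclidean.

**Inference.** The model is a latent Gaussian model and is fitted with an
INLA-like scheme rather than a general-purpose MCMC:

1. For fixed hyperparameters θ = (log σ, log range[, log φ]) the latent
   block x = (u, α, β) has a log-concave conditional; its mode is found by
   Fisher-scoring Newton iterations (the expected information keeps the
   curvature positive for the Beta likelihood) and the latent block is
   integrated out by a Laplace approximation.
2. The low-dimensional marginal posterior p(θ|y) is maximized
   (Nelder–Mead), its Hessian estimated by central differences with step
   0.05 (large enough to sit above the inner-Laplace evaluation noise), and
   approximated by a Gaussian on the log scale. Directions flatter than the
   prior's own curvature are floored, so weakly identified hyperparameters
   get wide—not absurd—intervals.
3. Joint posterior draws: θ from that Gaussian (or, with
   `method="emcee"`, from an ensemble sampler on the same marginal
   posterior), then x from its Gaussian Laplace conditional at each θ.

Diagnostics (split R-hat, ESS via arviz) are computed per scalar parameter;
R-hat > 1.05 on any parameter is recorded as a warning on the fit. The two
methods agree closely on the cases we tested; `laplace` is the default
because it is an order of magnitude faster and deterministic given the seed.

**Scores.** From the pointwise posterior log-likelihoods (the hurdle
likelihood per observation: Bernoulli everywhere, plus Beta on the positive
class): lppd = Σᵢ log meanₛ p(yᵢ|θₛ), p_WAIC = Σᵢ varₛ log p(yᵢ|θₛ),
WAIC = −2(lppd − p_WAIC) (deviance scale, smaller is better); CPOᵢ by the
harmonic-mean identity and LCPO = meanᵢ log CPOᵢ (higher is better).
Candidate covariate sets are ranked by WAIC with LCPO breaking ties.

**Orientation.** The binary component models presence of diversity
(z = 1 ⇔ H_S above threshold). Because published tables sometimes label the
same component by the zero class, `summary(orientation="absence")` reports
the sign-flipped (α_z, β_z).

**Prediction surfaces.** π and μ are evaluated per pixel of a covariate
raster stack; the spatial field is kriged to pixel centers with weights
computed at the posterior-mean hyperparameters (an approximation that avoids
a per-draw kernel factorization), plus independent conditional noise per
pixel. Posterior mean and SD surfaces are returned; NoData in any covariate
propagates to all outputs.

## Circuit-theory resistance

Non-NoData pixels are graph nodes; neighbors (8-neighborhood by default, 4
as an option) are joined with edge resistance equal to the mean of the two
pixel resistances, ×√2 for diagonal moves (the average-resistance
connection scheme; average-conductance is the other convention in the
field — the choice matters little for smooth rasters and the 4/8 and scheme
options are exposed). Zero resistance (fully suitable habitat) is floored
at 10⁻⁶ to keep conductances finite. Effective resistance between focal
pixels is computed from the dense Laplacian pseudo-inverse
(R_ij = L⁺ᵢᵢ + L⁺ⱼⱼ − 2L⁺ᵢⱼ, via `scipy.linalg.pinvh`) below 2500 nodes,
and per-pair conjugate-gradient solves on the grounded Laplacian (ILU
preconditioner, tolerance 10⁻¹⁰) above. Points snap to their containing
pixel center; two points in one pixel have distance 0; focal points on
NoData or in disconnected components are errors, which is what makes sea a
true barrier for the uniform-0.5 geography raster.

A note on the dense path: `numpy.linalg.pinv` produced numerically poor
pseudo-inverses for these Laplacians in our environment (residuals ~10⁻³),
so the symmetric `pinvh` is used deliberately; the test oracle uses the
deflation identity L⁺ = (L + J/n)⁻¹ − J/n instead, keeping the two routes
independent.

## Environmental ordination and assignment

PCA is computed on z-scored variables (correlation matrix); the leading
loadings (eigenvector × √eigenvalue) are varimax-rotated with Kaiser
normalization (statsmodels' rotation engine, tolerance tightened to 1e-10).
Scores use the regression method (Z R⁻¹ Λ); percent variance per component
is recomputed post-rotation from sums of squared loadings. Sign convention:
each loading column's largest-magnitude entry is made positive, making
results deterministic. Total retained variance and communalities are
rotation-invariant (asserted in tests); individual rotated columns are not
orthogonal as vectors — only the rotation matrix is orthogonal.

IBE distances are Euclidean over all retained rotated components; per-axis
distances |scoreᵢₖ − scoreⱼₖ| are also provided since single axes are
interpretable as environmental gradients, and the squared all-axes distance
equals the sum of squared per-axis distances.

Cluster assignment from a STRUCTURE-style Q matrix: per population the
unweighted mean membership per cluster over its individuals; assigned to
every cluster with mean ≥ 0.3 (inclusive); homogeneous iff exactly one.
Habitat change from orthophoto snapshots uses the fixed 80-square census
grid (8 categories); per habitat the percent of squares occupied per
snapshot, differenced between consecutive snapshots and averaged, in
percentage points.

## (N)MLPE regression

For pairwise responses over unordered population pairs p = (i, j):

    fst_p = β₀ + x_p β + g_{loc(i)} + g_{loc(j)} + c_i + c_j + ε_p

with g ~ N(0, σ_g²) per spatial-location group, c ~ N(0, σ_c²) per
population, ε ~ N(0, σ_ε²). Pairs sharing exactly one population have
residual correlation ρ = (σ_g² + σ_c²)/(2(σ_g² + σ_c²) + σ_ε²); pairs
sharing none are uncorrelated. The nested form is realized as two additive
random effects rather than a bespoke correlation object — mathematically
equivalent and much easier to verify against a dense covariance. When every
population is its own location the two variances are not separately
identifiable and σ_g is fixed at 0 (classic MLPE).

Estimation is maximum likelihood (not REML) so AIC comparisons across fixed
-effect structures are valid. The variance ratios γ_k = σ_k²/σ_ε² are
optimized on the log scale (Nelder–Mead from four spread starting points;
the profiled objective is 1–2-dimensional) with β and σ_ε² profiled out in
closed form; all solves use the Woodbury identity on the low-rank
random-effect structure, so tables with tens of thousands of pairs cost
only a q×q factorization (q = populations + location groups).
AIC = 2k − 2logLik with k counting intercept, slopes and all free variance
parameters. Significance is a 95% Wald interval excluding zero.

Predictors are z-scored before fitting (the response is left on the F_ST
scale). `dredge` enumerates every predictor subset whose members are
pairwise non-collinear (|Pearson r| < 0.6 over table rows), always including
the intercept-only model, and ranks by AIC with Akaike weights.
`model_average` uses conditional (natural) averaging over the ΔAIC < 2 set:
weight-renormalized mean per predictor with the Buckland unconditional SE
Σw_m √(se_m² + (β_m − β̄)²).

## Synthetic-data generator

The generator is first-class, tested code; its defaults emulate the study
design the package targets: 278 populations × 6 haploid individuals × 240
biallelic SNPs on a ~800 × 700 km landscape (40 × 35 grid of 20-km cells),
three spatially autocorrelated environmental fields (exponential kernel,
SD 1, range 150 km), and a hurdle-Beta diversity process with
α_z = 1.2, β_z = (−0.6, 0.3, 0), α_y = −2.2, β_y = (−0.4, 0.2, 0), φ = 30,
σ_z = 0.75, σ_y = 0.5, range 150 km — yielding roughly a quarter of
populations in the zero-diversity class and positive H_S values centered
near 0.1 with spread ~0.05, the regime the model is built for.

Genotypes: per locus an ancestral frequency p₀ ~ U(0.1, 0.9); population
frequencies are logit-normal perturbations with a spatially correlated
component (SD 1.2, range 150 km — the source of isolation by distance) and
independent drift of scale 2·√(2Fᵢ/(1−Fᵢ)), Fᵢ ~ U(0.3, 0.9). These drift
settings were fixed once as a compromise: with individuals drawn
independently within populations, mean H_S ≈ 0.13 and mean pairwise
F_ST ≈ 0.73 at survey scale — the right order for a highly selfing
regional survey, though a real survey's combination of lower H_S at equal
F_ST also reflects within-population clonality that the generator does not
model. Zero-diversity populations are forced monomorphic by a single
Bernoulli draw per locus.

Pairwise tables are generated *directly* from the MLPE generative model
(β₀ = 0.64, β_ibd = 0.08, β_ibe = 0.04, β_ibr = 0, σ_pop = 0.05,
σ_res = 0.08 over z-scored predictors) so the mixed-model tests have exact
ground truth; the genotype route exists for end-to-end integration tests
where F_ST is computed, not assumed.

Randomness: one master seed spawns named substreams (landscape,
populations, genotypes, pairwise), so adding draws to one stage never
perturbs another, and all artifacts round-trip losslessly through the
package's writers/readers.

What the generator does **not** emulate: within-population clonal
structure, ascertainment bias of SNP panels, linkage between loci, temporal
change, and sea barriers in the default mask (a barrier strip is an
option). Passing recovery tests therefore demonstrates correctness of the
estimators under the stated generative assumptions, not robustness to
those unmodeled features.

## Test and verification scales

Recovery and selection studies are run at reduced, fixed sizes chosen to
keep the full battery desk-scale: 30 populations × 20 replicates for the
NMLPE study, 300 populations × 20 (tests) or 10 (acceptance script)
short-chain refits for the hurdle study, grids ≤ 25 × 20 for landscapes,
and ≤ 8 populations for dense-oracle likelihood comparisons. Oracle
tolerances: 1e−10 (F_ST, resistance), 1e−8 (NMLPE likelihood, WAIC
recomputation), 1e−6 (varimax, OLS limit).

Known limitations: the hurdle model's hyperparameter posterior is a
Gaussian approximation on the log scale (an ensemble-MCMC alternative is
built in and agrees on test cases, but both rest on the inner Laplace
approximation); kriged prediction SDs ignore hyperparameter-dependence of
the kriging weights; spatial confounding between smooth covariate fields
and the GP term attenuates covariate coefficients in either model exactly
as it does for the real estimators this package mirrors, and the recovery
tests measure — rather than hide — that behavior.
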