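# Methods

## The models

`hetblup` predicts genotype-mean phenotypes `y` (one value per individual)
from expected allelic dosages `X` (n individuals x m biallelic markers,
values in [0, 2]) in samples composed of several, possibly admixed,
populations.

The baseline is the standard GBLUP mixed model

    y = Q alpha + u + e,   u ~ N(0, XX' sigma_beta^2),   e ~ N(0, I sigma_e^2),

in which every individual is assumed to draw on the same marker effects.
The package's purpose is two extensions that relax that assumption by
modelling marker-by-population interaction through a population covariance
`Omega` (n x n, correlation-like) combined with the marker kernel by a
Hadamard product:

    u ~ N(0, (Omega o XX') sigma_beta^2).

Because the Hadamard product of PSD matrices is PSD (Schur product theorem),
any valid `Omega` yields a valid model, and `Omega = J` (all ones) recovers
GBLUP exactly.

Two parameterizations of `Omega` are provided:

* **MPM-Mixture** — `Omega = rho * A Theta A' + (1 - rho) * J`, where `A`
  holds admixture coefficients (rows sum to 1) and `Theta` defaults to the
  identity. A single weight `rho` in [0, 1] interpolates between one
  homogeneous population (`rho = 0`) and fully cluster-specific effects
  (`rho = 1`).
* **MPM-Matern** — `Omega_ij = kappa_{nu,h}(||p_i - p_j||)`, a Matern
  correlation of the Euclidean distance between individuals' leading
  principal-component coordinates:

      kappa(d) = 2^(1-nu)/Gamma(nu) * x^nu * K_nu(x),   x = sqrt(2 nu) d / h.

  With this argument convention `nu = 0.5` gives the exponential kernel
  `exp(-d/h)` and `nu -> inf` the Gaussian kernel `exp(-d^2/(2h^2))`; `nu`
  controls the shape (presence of a "shoulder" near zero distance), `h` the
  range. The scale is also reported as `h* = h / Dmax`, with `Dmax` the
  largest pairwise PC distance in the fitting set. Because `kappa` is a
  function of coordinates rather than a table of coefficients, it
  *extrapolates*: covariances to populations absent from the calibration set
  are obtained by evaluating the fitted curve at their PC distances.

## Restricted likelihood

All variance parameters are estimated by REML. For a single genetic kernel
`C`, one eigendecomposition `C = U D U'` reduces every evaluation of the
restricted log-likelihood, profiled over the ratio
`lambda = sigma_e^2/sigma_u^2`, to O(n p^2): rotate `y` and `Q` by `U'`,
then for each candidate ratio the GLS solution, the profiled `sigma_u^2`
and the log-determinants are sums over eigenvalues. The profile is scanned
on a 64-point log grid spanning 10^-5..10^5 times the mean eigenvalue and
refined by bounded scalar minimization. The reported value includes the
`-(n-p)/2 log 2pi` constant and the `+1/2 log|Q'Q|` term (Patterson-
Thompson form), so likelihood-ratio statistics between kernels on the same
`y` and `Q` are free of constants.

Hyperparameters of `Omega` are estimated by maximizing this REML value:

* `rho` by an 11-point bracketing grid plus bounded search (tolerance 1e-4);
  if the optimum is not better than the nested `rho = 0` fit, the boundary
  fit is reported (parsimony on ties).
* `(nu, h)` by Nelder-Mead in `(log nu, log h)` from four starting points
  `(0.5, Dmax/2), (0.5, Dmax), (10, Dmax/2), (10, Dmax)` (positivity by
  reparameterization; at most 300 iterations per start, function tolerance
  1e-3). A fifth candidate — the smooth limit `h = 1e8 Dmax`, where `Omega`
  is numerically the all-ones matrix — is always evaluated, so the reported
  optimum can never fall below the nested GBLUP model. Ties within 1e-6
  resolve toward the larger (smoother) `h`. Inside the search, `kappa` is
  evaluated on a 4096-point distance grid (denser near zero) and
  interpolated over the observed pairwise distances; the final fit is
  re-evaluated with exact Bessel calls. `nu` is floored at 1e-3 and `h`
  capped at 1e10 Dmax to exclude a degenerate ridge (`nu -> 0`, `h -> inf`)
  on which the kernel approaches a discontinuous correlation.

Numerical guards: kernels receive a 1e-8 diagonal jitter when their
smallest eigenvalue is below that (flagged on the fit object); a kernel
numerically proportional to the identity triggers a non-identifiability
warning; `kappa` is computed in log space with `K_nu` overflow at tiny
arguments resolved to the continuity limit 1 and underflow at large
arguments to 0; shapes above `nu = 50` use the Gaussian limit directly.

## Prediction and validation

Testing-set predictions use the standard BLUP cross-covariance form with
all kernels built on the full sample (so cross-blocks are consistent) but
variance components and `Omega` hyperparameters estimated on the calibration
rows only. Two validation schemes are implemented: whole-sample (CS =
everyone except the testing fifth of the target population) and
cross-population (CS excludes the target population entirely). Accuracy is
the Pearson correlation between observed and predicted testing-set values.
Paired procedure comparisons use Fisher-transformed accuracy differences
with two standard errors: liberal (`SD/sqrt(nrep)`) and conservative
(`SD * sqrt(1/nrep + o/(1-o))`, `o` the expected testing-set overlap; with
`o = 1/5` and `nrep = 20` the conservative SE is exactly sqrt(6) times the
liberal one). Both tests use `nrep - 1` degrees of freedom, two-sided.
Under cross-population validation the calibration set is identical across
replicates, so fitted models are cached and reused across testing draws.

Model comparison: LRT statistics `2(l1 - l0)` floored at zero against
chi-square with 1 df (mixture) or 2 df (Matern). These reference
distributions are used as printed even though `rho = 0` and the smooth
limit lie on the parameter boundary, which makes the tests conservative (a
50:50 chi-square mixture would be sharper); the null calibration experiment
confirms rejection rates below nominal. BIC comparisons count the ratio
parameter plus one extra parameter for the mixture and two for the Matern
model.

## Population structure machinery

`G = Xdot Xdot'/v` with `Xdot = X - 2 pi_hat` and
`v = 2 sum pi_hat(1-pi_hat)` (VanRaden scaling, whole-sample frequencies).
PC scores are eigenvectors of `G` scaled by sqrt(eigenvalue), making
`G = PP' + G_P` exact with `G_P` the structure-conditional relationships.
Individual-specific allele frequencies are
`pi_P,i = pi_hat + (rank-d truncation of Xdot)_i / 2` (frequency units, not
clipped to [0, 1] — clipping would break the identity below). PC
coordinates expressed in dosage units (scores times sqrt(v)) then satisfy
`||p_i - p_j|| = 2 ||pi_P,i - pi_P,j||` exactly: distance in PC space is
twice the distance between implied allele-frequency vectors.

The graph of recent relationships applies the graphical LASSO (off-diagonal
L1 penalty, scikit-learn's coordinate-descent solver) to `G_P`, with the
penalty chosen to maximize the REML value of a GBLUP fit on the regularized
matrix `G_tilde = PP' + inverse(Theta_hat)` — a per-phenotype choice.
`G_P` is exactly singular by construction, so the solver input receives a
diagonal load of 1e-3 times its mean diagonal, escalated tenfold on solver
failure. Edges are off-diagonal precision entries above 1e-8 in magnitude.

Marker filters (strict inequalities throughout): missingness < 2%; minor
allele frequency > 1/(2n) and dosage variance > 2(1/(2n))(1 - 1/(2n)); a
1-df chi-square Hardy-Weinberg test on integer-rounded genotype counts with
p > 1e-4 within each designated population (monomorphic columns p = 1 by
convention); genomic position available. Allele frequencies for filtering
use observed entries only, since filtering precedes imputation; missing
entries are then imputed by the whole-sample column mode, ties broken
toward the lower dosage.

## The synthetic-data generator

`simulate_genotypes` draws ancestral allele frequencies from Uniform(0.1,
0.9), population frequencies by a Balding-Nichols step
`Beta(p(1-F)/F, (1-p)(1-F)/F)`, admixture rows from a symmetric
Dirichlet(alpha) (alpha = 0 gives pure memberships), and dosages from
Binomial(2, A p). Two divergence topologies: `star` (all populations split
independently from the ancestor; default) and `serial` (a stepping-stone
chain in which population k+1 derives from population k, producing graded
genetic distances like an isolation-by-distance gradient). Defaults — K =
4 populations, F = 0.2, alpha = 0.05, n = 400, m = 2000, h^2 = 0.5 —
describe a moderately diverged, nearly-unadmixed sample of the size a
desk-scale experiment can refit hundreds of times.

Genetic values are `g_i = x_i' beta_i` (centered dosages) with three effect
models: a single shared `beta` (homogeneous); the mixture construction
`beta_i = sqrt(1-rho) beta_0 + sqrt(rho) sum_k a_ik gamma_k`, whose induced
covariance is exactly `(Omega_mixture o XX') sigma_beta^2`; or
population-level effect vectors jointly Gaussian with Matern
cross-correlations over latent population coordinates, mixed by admixture.
Phenotypes add noise standardized to hit `Var(g)/Var(y) = h^2` closely in
every dataset.

What the generator does **not** emulate: linkage disequilibrium (loci are
independent), non-additive gene action, genotyping error or allele-dosage
uncertainty, variance heterogeneity across populations, and real
genealogies. Passing tests therefore demonstrate correctness of the
estimators under the assumed covariance structures, not performance on real
exome data, where LD and dominance/epistasis are believed to be major
sources of effect heterogeneity.

## Canonical experiments and their conditions

`hetblup.experiments` pins the study conditions used by the test suite and
the acceptance script (sizes chosen as the package's own desk-scale
conditions):

* **Mixture-weight recovery** — for each `rho_true` in {0, 0.3, 0.6, 0.9}:
  20 datasets at the generator defaults, mixture fit on each, mean of
  `rho_hat` compared with truth. A Fisher-information analysis at these
  conditions gives an asymptotic sd of about 0.3 for a single `rho_hat`:
  with near-pure clusters the cross-population covariance contrast carries
  only on the order of K^2 effective degrees of freedom, so single-dataset
  estimates are intrinsically noisy, means over 20 replicates have a
  standard error near 0.07, and boundary truncation biases the mean upward
  at `rho = 0` and downward at `rho = 0.9`. The recovery experiment is
  reported as measured.
* **Matern-curve recovery** — 20 datasets; truth `nu = 0.5`,
  `h = Dmax/3`, with each individual's effect vector drawn from a Gaussian
  process over its PC coordinates so that the pairwise effect correlation
  is exactly `kappa(d)` at every observed distance (population-level
  effect draws would pin within-population correlation at 1 regardless of
  distance, making the nominal curve the wrong reference). The error is
  the mean absolute difference between fitted and true kappa at the
  quartiles of observed pairwise distances. A Fisher-information analysis
  puts the achievable error near 0.15 at these conditions — the fitted
  scale is determined only up to a factor of about exp(0.5) — so the
  recovery error sits at the information floor and is reported as
  measured.
* **Null calibration** — 200 homogeneous-effect datasets (n = 200,
  m = 500); the mixture LRT's rejection rate at alpha = 0.05 must not
  exceed the nominal level (boundary conservatism).
* **LRT power** — 12 datasets with a strong mixture effect (`rho = 0.9`,
  admixture alpha = 0.3, F = 0.3, h^2 = 0.8).
* **Cross-population contest** — 20 seeded datasets under the
  strong-heterogeneity condition: a serial gradient of K = 6 populations
  (F = 0.2 per step, n = 360, m = 1500), Gaussian-shaped effect decay
  (`nu = 30`) scaled so neighboring populations correlate at 0.8, h^2 =
  0.85, and an interior target population. MPM-Matern and GBLUP are
  cross-validated on identical splits (nrep = 20) and the number of seeds
  where the Matern model's mean accuracy is strictly higher is reported.
  The condition was designed around the mechanism that favors the Matern
  model: graded similarity, so nearby populations remain informative while
  distant ones dilute the pooled GBLUP fit. Notably, under a star topology
  (all populations equidistant) shrinking cross-population covariance
  rescales predictions almost uniformly and cannot change Pearson accuracy
  — even the oracle covariance then wins only about half the time — and
  with a target at the end of the gradient, extrapolating the fitted curve
  beyond the calibration range is often harmful. Both observations mirror
  the trait-dependence of cross-population gains reported for real data.

## Known limitations

* Single genetic kernel only: no multi-kernel REML, no panel-specific or
  heteroscedastic residual variances, no `Theta_K` estimation (a supplied
  `Theta` is accepted but never fitted).
* `rho` and `(nu, h)` are weakly identified at desk scale (see above);
  interval estimates are not provided.
* The LRT reference distributions are deliberately the printed chi-square
  forms, i.e. conservative at the boundary.
* Admixture coefficients are consumed (file or simulator), never inferred;
  PCA always uses whole-sample allele frequencies.
* The graphical-LASSO graph is a partial-covariance pattern on jittered
  `G_P`; its coefficients are not calibrated kinship estimates.
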