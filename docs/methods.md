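# Methods

## Model and assumptions

The inference layer treats metabolite levels near a metabolic steady state
as a linear stochastic system: small fluctuations `x(t)` of log abundances
follow an Ornstein–Uhlenbeck process `dx = J x dt + S dW` with Jacobian
`J` (entries are reaction elasticities, units 1/time) and diagonal noise
input of intensity `D = S Sᵀ / 2`-like scale. When `J` is Hurwitz (all
eigenvalue real parts negative) the process has a stationary covariance
`C` characterised by the continuous Lyapunov equation

    J C + C Jᵀ = −2 D.

Three assumptions matter in practice:

* **Stationarity and linearity.** Observed samples are treated as draws
  from the stationary distribution of the linearised system. Field
  metabolomics data satisfy this at best approximately within one harvest
  and condition; the pipeline therefore slices by condition and time point
  before estimating covariance.
* **Log scale.** Abundances are modelled as exponentiated Gaussians, so
  covariance is always estimated on log-transformed values.
* **Network sparsity.** A directed metabolic network restricts which
  Jacobian entries are free: edge `source → target` frees entry
  `(target, source)`; the diagonal (self-turnover) is always free.

## Forward and inverse solves

`forward_lyapunov` delegates to SciPy's Bartels–Stewart solver and is the
simulator backbone and independent oracle for the inverse path.

`solve_inverse_jacobian` writes one equation per unordered index pair
(p ≤ q) of the Lyapunov identity, giving n(n+1)/2 equations in the m free
entries, and solves by least squares (LAPACK `gelsd`). Off-diagonal
equations are weighted by √2 so the objective equals the Frobenius norm of
the symmetric residual `J C + C Jᵀ + 2 D`; the returned solution is then
the true Frobenius-optimal one, which the residual-optimality property
test checks by random perturbation. Rank-deficient systems — the expected
regime when observations are fewer than metabolites, making `C` singular —
get the minimum-norm solution, with the number of unresolved degrees of
freedom surfaced as `rank_deficiency`. Identifiability requires m ≤
n(n+1)/2 *and* full column rank; chains and rings with n ≥ 3 are
identifiable and the round-trip test recovers planted Jacobians to 1e−8
relative. A 2-ring (full 2×2 mask: 4 unknowns, 3 equations) is the
smallest non-identifiable case and is excluded from round-trip claims.

## Monte-Carlo ensemble over noise matrices

The fluctuation intensities are not observable, so the inverse solve is
repeated for random diagonal `D` (default 10⁴ draws) and the entry-wise
median and interquartile range are reported. Implementation note: the
coefficient matrix depends only on `(C, mask)`, and each diagonal draw
only changes the right-hand side, so the pseudoinverse is computed once
and every iteration is a matrix–vector product — numerically identical to
per-draw least squares (the single-draw test asserts agreement with
`solve_inverse_jacobian`) and fast enough that 10⁴ iterations on 48
metabolites with ~150 network edges take seconds on one CPU.

Noise diagonal entries default to **half-normal** (|z|, z standard
normal): a negative diagonal `D` has no interpretation as a fluctuation
intensity, and signed draws make the ±D solution pairs cancel under the
median. `noise="normal"` keeps literal signed standard-normal draws for
replication of that convention. Because the solve is linear in `D` and
homogeneous of degree −1 in `C`, medians are exactly equivariant: scaling
`C` by α scales every median entry by 1/α at a fixed seed.

## Differential Jacobian

Groups are compared entry-wise by `dJ = ln(|J₁| / |J₂|)` on the shared
mask. The log-ratio is taken on magnitudes because it is undefined for
opposite-signed entries; sign concordance is reported as a flag, and the
shared sign (where concordant) labels the entry activating (> 0) or
inhibiting (< 0). Entries with magnitude below `1e−9 × median(|masked
entries|)` in either group (configurable) are flagged undefined rather
than yielding infinite ratios. Swapping the groups negates every entry
exactly. The edge report lists masked entries with |dJ| above a threshold
as tidy source/target rows — the table behind circular differential-flux
plots.

The headline computational claim is *differential sign recovery*: for two
6-node systems sharing mask and noise with three edges differing by a
factor 2, Monte-Carlo medians at 200 draws per group recover the planted
dominance sign on at least 2 of the 3 edges (the acceptance suite plants
and checks exactly this; in practice all 3 are recovered across seeds).

## SSI and quadrants

`SSI_i = (1 − Ys_i/Yp_i)/SI` with `SI = 1 − MYs/MYp`. Two algebraic
properties are enforced by test: the Yp-weighted mean of SSI is exactly 1,
and SSI is invariant to rescaling all yields by a common factor.
`stress_intensity` returns SI even when ≤ 0 (e.g. an unstressed panel);
`compute_ssi` refuses such panels since the index is undefined there.

The quadrant biplot needs a split of the stressed-trait axis, which is not
a canonical part of the index; the default is the median of Ys across
genotypes (balanced, scale-free), with mean and explicit-value policies
available. Ties go to the tolerant / high-yield side: SSI exactly 1 is
"not susceptible", and a genotype at the trait threshold counts as
high-yielding.

## Correlation screen

Each replicate observation carries its genotype's SSI, so a 36 × 3 slice
correlates at n = 108 — deliberately replicate-level rather than
genotype-mean pairing, which matches the reported significance levels of
such screens at |r| ≈ 0.4. The statistic is Pearson r on log abundance
with t = r√(n−2)/√(1−r²) and a two-sided p (t distribution, n−2 df);
Benjamini–Hochberg q-values are reported alongside the raw-p significance
flag so either multiplicity convention is available. Natural log is the
default; r is invariant to the base. The default slice is the
drought-stressed condition at the middle harvest, the most
stress-responsive time point in the motivating design; both are
configurable. Zero-variance metabolites are excluded from the BH family
with a warning, never silently dropped.

## Synthetic data: what it does and does not emulate

* `make_toy_network` draws off-diagonal entries (magnitude U[0.2, 1],
  random sign) on chain/ring/random topologies and sets each diagonal to
  −(row abs-sum + U[0.5, 1.5]); Gershgorin dominance then guarantees a
  Hurwitz Jacobian by construction. Noise intensities are U[0.5, 1.5];
  `C_true` is the exact forward solution, asserted to satisfy the Lyapunov
  identity to 1e−10.
* `simulate_abundances` draws exact stationary samples (Cholesky of
  `C_true`) and exponentiates, so the pipeline's log transform recovers
  the Gaussian layer without approximation.
* `generate_yield_panel` defaults to the motivating design: 36 genotypes,
  3 replicates, half tolerant with 10% mean loss vs 50% for the
  susceptible class, 5% multiplicative lognormal noise (exactly
  noise-free at cv 0), baseline 100-seed weight Normal(25 g, 4 g)
  truncated at 5 g — a realistic desi chickpea seed weight.
* `generate_ssi_correlated_metabolome` plants a column whose log value is
  `ρ·z_g + √(1−ρ²)·ε` with `z_g` the genotype's standardized SSI shared
  by its replicates, so the expected replicate-level sample correlation
  is ρ.

Not emulated: GC–MS instrument artefacts (drift, batch effects, missing
peaks), genotype-specific covariance structure, or SNP data. Passing tests
therefore demonstrate correctness of the estimators under the model's own
assumptions, not robustness to instrument noise.

## Numerical choices and problem sizes

* Least-squares driver `gelsd`; pseudoinverse via SVD; default rcond.
* Half-minimum offset policy for nonpositive abundances applies the
  offset to the whole metabolite column (the common metabolomics
  convention), and only to columns that contain a nonpositive value.
* Monte-Carlo default 10⁴ iterations; property tests use 200–500
  iterations, which already stabilise medians on ≤ 48-variable systems.
  Sampling-convergence checks use 10³ and 10⁵ samples against a
  5·√(2/n) entry-wise band; the null-calibration check uses 500 seeds
  against a 3σ binomial band around 0.05.
* Degenerate inputs: all-zero covariance, non-Hurwitz forward inputs,
  constant phenotypes, empty slices, and sub-minimal group sizes all
  raise informative errors; an edge-free network degrades to a
  diagonal-only Jacobian with a warning.

## Known limitations

* With singular covariance (more metabolites than observations) the
  minimum-norm solution is one of infinitely many least-squares optima;
  conclusions should then rest on differential comparisons under a shared
  seed, not on absolute entry values. `rank_deficiency` quantifies this.
* The Monte-Carlo median under random `D` estimates `J` only up to the
  unknown true noise scale; it is meaningful relatively (between groups,
  between entries), which is exactly how the differential Jacobian uses it.
* The quadrant trait threshold is a reporting convention, not an inferred
  quantity; membership near the threshold is sensitive to the policy.
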