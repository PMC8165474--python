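# Methods

## Model and attack algebra

A study releases the OLS coefficients `β̂` of the linear GRS `y = Φβ + ε`,
`ε ~ N(0, σ_y²)` i.i.d., where `Φ = [X, 1]` is the M×(N+1) design of binary
SNP indicators plus intercept.  With `K = (1/M)ΦᵀΦ`, the normal equations are
`K β̂ = (1/M)Φᵀy` — an identity the test suite checks on every fit, because
the whole attack is built on it.

If a second release adds m individuals (design rows `Φ_m`, phenotypes `y_m`),
subtracting the two normal-equation systems gives

```
K (β̂_{M+m} − β̂_M) = (1/M) Φ_mᵀ (y_m − Φ_m β̂_{M+m}) =: Φ_mᵀ C_m .
```

Each coordinate of the left side (the attack vector `d`) is therefore the sum
of the constants `C_j` over the added individuals carrying that SNP: a
subset-sum code for the m genotypes.  The intercept coordinate is always the
full sum `ΣC_j`, which anchors the constant identification.  `M` never needs
to be known: it only scales `C_m`, not the recovered genotypes.

### Exact attack (K known)

* m=1: `C = d[N+1]`; SNP i is called 1 iff `d_i` is nearer `C` than `0`.
  `|C|` below tolerance is a degenerate instance (the added individual's
  residual is ~0) and raises an explicit error.
* m>1, simple path: cluster the entries of `d` (relative tolerance
  `1e-6·max|d|`, so rescaling the phenotype rescales `C` but never changes
  the calls); require exactly `2^m` clusters; the values not expressible as a
  pairwise sum of observed values are the constants; validate `ΣC = d[N+1]`.
* m>1, extended path: when combinations are missing (or a sum coincidence
  `C_k = C_i + C_j` over-eliminates — real: it occurs for the constants
  (0.2, 0.5, 0.9)), the candidate pool is augmented with pairwise
  differences and searched for m-subsets that sum to the intercept entry
  *and* explain every `d` value as a subset-sum.  Competing subsets are
  ranked by the independent-Bernoulli likelihood of the genotypes they imply
  under public SNP frequencies; near-ties are returned in an ambiguity list
  rather than silently resolved.  The subset search is capped (default 2^20
  subsets) and failure is an explicit infeasibility error — with `N < 2^m`
  the value lattice cannot be resolved at all, which is the documented
  feasibility frontier.
* Overlapping panels: when the studies share only part of their SNP panels,
  restricting the *rows* of the full products `K'β̂'` and `Kβ̂` to the shared
  SNPs (plus intercept) cancels the shared cohort exactly and leaves
  `C·[φ₀]` over the shared coordinates.  Restricting rows *and columns* of K
  before multiplying is not an identity (the cross terms between shared and
  panel-only SNPs do not cancel; we verified the residual is orders of
  magnitude above the signal), so the implementation takes both panels'
  co-occurrence matrices and restricts the products.
* Add *and* remove: if study A has M+a and study B has M+b participants with
  an M-core shared, `K(β̂_A − β̂_B)` is an (a+b)-individual problem whose
  constants carry the negated residuals for the B-only individuals.  The
  same identification machinery applies; which subset was added versus
  removed is supplied as metadata (a, b) since signs alone cannot identify
  it (an added individual's residual may have either sign).

### Estimated K: EM and stochastic EM

With `K̂` from a disjoint public sample, `x = K̂Δ` (`Δ = β̂_new − β̂_old`) is
modelled as `N(Φ_mᵀC_m, σ²ΔᵀΔ·I)`; entries of `Φ_m` get Bernoulli priors
`α_i` from the public frequencies, with `α_{N+1} = 1` for the intercept row.
The noise model treats the entries of K̂ as i.i.d. Gaussian, ignoring K's
symmetry and boundedness — a deliberate simplification that buys closed-form
updates.

* m=1 (exact EM): E-step is the two-component responsibility
  `π_i = σ(log α_i − log(1−α_i) + [x_i² − (x_i−C)²]/(2s²))` with
  `s² = σ²ΔᵀΔ`, computed in log-space; M-step sets `Ĉ = Σπ_i x_i / Σπ_i` and
  `σ̂² = Σ[π_i(x_i−Ĉ)² + (1−π_i)x_i²] / ((N+1)ΔᵀΔ)` — the unique zero of the
  derivative of the expected complete-data log-likelihood (derived, since
  only the derivative setup is standard).  The observed-data log-likelihood
  is monotone across iterations (checked in tests).  Convergence: relative
  change of (C, σ²) below 1e-8, max 500 iterations.  σ² is floored at
  `1e-12·mean(x²)` so the exact-K limit cannot divide by zero; at the floor
  the responsibilities saturate and the calls equal the exact attack's.
  Initialization from prior probabilities or from all-zeros made no
  qualitative difference in our runs; both are implemented.
* m>1 (stochastic EM): the E-step is replaced by systematic-sweep Gibbs
  sampling of the indicators via the closed-form full conditional
  (site-independent, individuals coupled); the M-step solves the least-squares
  system `(ZᵀZ)C = Zᵀx` (ridge-stabilized only if singular) and sets σ² to
  the mean squared residual; C is sorted ascending after every iteration
  (with the matching column permutation of Z) to break the label symmetry.
  Runs are fixed-length (default 2000 iterations, burn-in 500, averaging
  window 1000; the experiment protocols use 800/200/600) because SEM
  converges in distribution, not pointwise; C, σ² and the indicator
  frequencies are averaged over the window.
* Readout refinement: the sampler's stationary noise keeps σ² on a plateau,
  so the averaged indicator frequencies cannot sharpen even when the data are
  noiseless.  Since the posterior factorizes over sites given (C, σ²), for
  m ≤ 12 the package follows the SEM run with a deterministic EM polish —
  E-step by exact enumeration of the 2^m per-site states, M-step by weighted
  least squares — started from the SEM averages, and runs `n_restarts = 3`
  chains, keeping the one with the highest observed-data log-likelihood.
  This makes the noiseless limit (`K̂ = K`) reproduce the exact attack on
  every seed we tested while leaving estimated-K behavior unchanged.

### Error bound

The relative error of the unscaled reconstruction `φ₀ = KΔ` under `K̂`
satisfies `‖φ̂₀−φ₀‖/‖φ₀‖ ≤ ‖K⁻¹‖·‖K−K̂‖` in spectral norms (the only norm
consistent with the eigenvalue form `1/min eig(K)`); with a ridge penalty λ
the first factor is bounded by `1/λ` because K is PSD.  The bound is checked
against the observed error on 50 simulated pairs in the acceptance suite.

## Synthetic cohorts

The simulator emulates the attack's study protocol: one population, four
disjoint cohorts (private base M, added m, public M̂, test pool).  Defaults
are M=1000, N=200, public 800, per-SNP frequencies uniform in (0.25, 0.75)
(only common variants), binary coding, and unit-variance Gaussian phenotype
noise around a linear effect vector (standard-normal effects unless given).
The phenotype noise level of the original experiments is not stated anywhere;
unit variance is our choice and the experiments state it.  Allele-count
coding (0/1/2) sums two independent haplotype layers.  Optional LD structure
uses a per-block Gaussian latent factor thresholded to the target marginal
frequency — tunable pairwise correlation that gives K non-trivial
off-diagonals, not a realistic LD map.  A master seed spawns independent
streams for genotypes, phenotype noise, and cohort assignment, so varying one
never perturbs the others.

What the simulator does *not* model: population stratification, admixture,
realistic LD decay, genotyping error, or missingness.  Passing tests
demonstrate the algebra and the estimators under the model's own
assumptions; absolute accuracies on real cohorts (which depend on population
structure the simulator does not claim to match) are out of scope, and only
directional claims (EM beats the most-common-variant baseline; accuracy grows
with public-sample size; robustness to atypical individuals) are asserted.

## Experiment protocols and problem sizes

`run_protocol` reproduces the figure-level experiments at desk scale — 5
splits × 10 test draws by default (overridable): exact-K single and m=3
(accuracy 1.0 by construction, kept as a regression tripwire for tolerance
drift), EM across public sizes {200, 400, 800}, SEM at m=3 with public 800,
and EM accuracy across private sizes {200 … 30000} at N=100 with a fixed
2000-individual public sample.  The private-size grid starts at 200 because
M=100 with N=100 SNPs is a singular OLS system.  Reports are pandas tables
regenerable bit-identically from the recorded master seed.

## Numerical choices

* GRS fits solve the normal equations by Cholesky; a singular system with
  λ=0 raises a rank-deficiency error — never a silent pseudo-inverse —
  because the attack algebra needs the normal-equation identity to hold
  tightly.  The ridge penalty `Mλ` never touches the intercept (penalizing
  the constant column would break the `K[N+1,N+1]=1` semantics).
* K and the frequency tables are kept as integer counts divided by M at the
  last step, so assembling K from frequencies reproduces `build_K` bit for
  bit.
* Gaussian perturbation of K is applied to the upper triangle and mirrored
  (entrywise i.i.d. noise would break the symmetry the algebra assumes), and
  the corner is reset to 1.
* d-value clustering is scale-invariant (relative tolerance, default
  `1e-6·max|d|`); the zero class is the cluster nearest 0.
* Accuracy between recovered and true genotype sets is scored under the
  optimal individual matching (linear assignment), since the attack cannot
  label individuals.

## Known limitations

* The extended constant search is exponential in the candidate pool and
  capped; genuinely ambiguous instances return an ambiguity list, and
  `N < 2^m` is refused outright.
* The SEM refinement enumerates `2^m` states and is limited to m ≤ 12; above
  that the sampled indicator frequencies are returned as-is.
* The Gaussian error model for K̂ ignores symmetry and support constraints;
  σ̂² is a model-scale parameter, not a calibrated estimate of the sampling
  error of K̂.
* Binary-coding attacks assume the released models were fit on the same
  coding; allele-count support covers K construction and the value-lattice
  structure (3^m values), not the probabilistic attacks.
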