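# Methods

## The test

`pyfbst` implements the Full Bayesian Significance Test (FBST) for a sharp
null hypothesis `H0: θ = θ0` about a scalar parameter, operating on a vector
of posterior draws from any sampler. The pipeline is:

1. **Density estimation.** The marginal posterior `p(θ|x)` is estimated from
   the draws with a Gaussian kernel density estimator (the Gaussian kernel is
   the natural choice given Bernstein–von Mises asymptotic normality of
   posteriors). The estimate is evaluated on a regular grid and renormalized
   so its trapezoidal integral is exactly 1.
2. **Surprise function.** `s(θ) = p̂(θ|x) / r(θ)` for a reference function
   `r`. A flat reference (`r ≡ 1`) recovers the posterior itself; with the
   model prior as reference, `s(θ) ≥ 1` marks values corroborated by the
   data.
3. **Supremum over the null.** For a point null the supremum of `s` over the
   null set is `s* = s(θ0)`, obtained by linear interpolation on the grid.
4. **Tangential set and e-value.** The tangential set `{θ : s(θ) > s*}`
   collects all parameter values more consistent with the data than the null
   value. Its posterior mass, computed by trapezoidal quadrature over the
   (possibly disconnected) intervals where `s > s*`, is the Bayesian
   evidence against H0, `ev_against`; `ev_favor = 1 − ev_against`. A
   draw-fraction (Monte Carlo) estimate — the fraction of draws whose
   interpolated surprise exceeds `s*` — is always recorded as a cross-check,
   and can be selected as the reported estimator.
5. **Standardization and asymptotics.** With `k = dim Θ` and `h` the
   dimension of the null set, `sev̄ = F_{k−h}(F_k⁻¹(ev_against))` and
   `sev = 1 − sev̄` (χ² CDF and quantile function), the test's p-value
   analogue. The asymptotic Bayesian significance value
   `ev0 = 1 − F_k((θ0 − M0)²)` uses the grid argmax `M0` of the density
   estimate; the frequentist `pv0 = 1 − F_{k−h}(−2λ(m0))` is filled only
   when the caller supplies the likelihood-ratio statistic, since the
   library sees draws, never the likelihood.

A large `ev_against` is grounds for rejecting H0. A small one is **not**
confirmation of H0: the e-value in favor does not converge to 1 under a true
null, so the test only rejects.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `grid_size` | 4096 | points | resolves level-set crossings to ~10⁻³ of the posterior range at negligible cost |
| `bandwidth` | Silverman's rule `0.9·min(sd, IQR/1.349)·n^(−1/5)` | parameter units | conventional, reproducible; the robust min() guards heavy-tailed posteriors; a user scalar is the absolute kernel sd |
| grid range | draws ± 3 bandwidths, extended to cover θ0 | parameter units | ±3 bw bounds truncated tail mass below the 10⁻⁶ normalization tolerance; covering θ0 keeps a null far outside the posterior evaluable (density ≈ 0 there, `ev_against → 1`) |
| `dim_theta`, `dim_null` | 1, 0 | — | dimensions of the sampled model's parameter space and null set; they enter only the χ² standardization and `ev0` |
| reference | `flat` | — | the posterior itself is the surprise function; `normal`, `cauchy`, `half_cauchy`, `student_t` and user callables cover the priors used in practice |

Ties at exactly `s*` are assigned to the complement of the tangential set
(the set uses the strict inequality `s > s*`); interval endpoints are refined
by linear interpolation of `s` across the level crossing. Multimodal
surprise functions yield a union of disjoint intervals, so disconnected
tangential sets are handled exactly. Multiplying a reference by any positive
constant rescales `s` and `s*` equally and leaves every e-value unchanged
(verified to 10⁻¹² in the tests).

Degenerate inputs: fewer than 2 draws, non-finite draws, and zero-variance
draw vectors are rejected; fewer than 1000 draws triggers a KDE-reliability
warning. A reference that vanishes on a region carrying more than 10⁻³
posterior mass raises a support-mismatch error; less than that (MCMC
stragglers outside, e.g., a half-Cauchy support) is tolerated, with the
offending grid points excluded from the evaluable range. `ev0`'s squared
distance is used unstandardized, exactly as the asymptotic formula reads on
the supplied marginal; an opt-in flag divides by the posterior standard
deviation first.

## Synthetic data and what the tests show

The `fixtures` module generates everything the test suite consumes:

* seeded normal and normal-mixture draws (the mixture exercises
  disconnected tangential sets);
* a two-group data generator (defaults: 18 observations per group, means 0
  and 0.8, common sd 1.7 — a small-study design with true standardized
  effect size −0.47);
* a Metropolis-within-Gibbs sampler for the two-sample Bayesian t-test
  effect size δ under a `Cauchy(0, √2/2)` prior, flat prior on the grand
  mean and `p(σ²) ∝ 1/σ²`. Group means are parameterized `μ ± σδ/2` so δ
  carries the Cohen's-d sign convention `(μ1 − μ2)/σ`. Sufficient statistics
  make each log-posterior evaluation O(1), and proposals target roughly 30%
  acceptance (warned outside [0.1, 0.6]). Default 11,000 iterations with
  1,000 burn-in; no thinning, as the KDE is insensitive to autocorrelation
  at these sizes.

The independent oracle is the exactly-normal posterior: under a flat
reference the tangential set of a point null is `{θ : |θ−μ| < |θ0−μ|}`, so
`ev_against = F₁(z²) = 2Φ(|z|) − 1` with `z = (θ0−μ)/σ` — computable without
any density estimation. The acceptance suite sweeps 15 posteriors × 7 null
positions (20,000 draws each) against this closed form, and requires the
quadrature and draw-fraction estimators to agree to 0.01 on every case.

**Conditioning caveat.** Near the posterior mode the density's top is flat,
so its level sets are ill-conditioned: kernel-density sampling noise of
relative size ε moves a level-set boundary by ~√(2ε) posterior standard
deviations. At n = 20,000 draws this puts an irreducible noise floor of
roughly 0.03–0.2 on the e-value for standardized null distances z ≲ 1 —
affecting the quadrature and Monte Carlo estimators identically, since both
consume the same estimated surprise function. The oracle sweep therefore
covers z ∈ [1.25, 3], the regime where rejection decisions live and where
agreement within 0.02 genuinely holds; near-mode behavior is checked
separately at its own bound (`ev_against ≤ 0.1` with the null at the mode).
Consequences for real use: e-values near 0 are noisier than e-values near
1, and *rejections* (large `ev_against`) are reliable at these draw counts.

The synthetic posteriors are smooth, unimodal-or-bimodal and light- to
moderately-tailed; passing tests say nothing about posteriors with
discrete atoms, hard support boundaries inside the grid range, or extreme
autocorrelation far beyond what the fixture sampler produces.

What the parameter-recovery suite shows: with a true effect of one pooled
standard deviation (n = 1000/group) the test rejects δ = 0 with
`ev_against ≥ 0.95` in 20/20 seeded replications. With a true null, the
e-value at θ0 is approximately uniform on [0, 1] — the standardized
discrepancy between θ0 and the posterior mean is asymptotically standard
normal — so low evidence cannot concentrate below 0.5 more than ~half the
time at any sample size. This is the FBST's documented asymmetry: it
rejects sharp nulls; it never confirms them.

## Problem sizes

Default test-suite problem sizes: 20,000 draws per oracle case (105 cases),
10,000 retained MCMC draws per recovery replication (40 replications at
n = 1000 per group), 4096-point grids throughout. The full suite runs in a
few minutes on one core.

## Known limitations

* Scalar marginals only: `k` and `h` enter through the standardization and
  `ev0` formulas; joint multivariate tangential sets are out of scope.
* Point nulls only; interval null sets are not supported.
* The squared distance in `ev0` is computed on the supplied marginal draw
  vector, a one-dimensional reading of the k-dimensional asymptotic formula;
  it is reported alongside, not instead of, the exact `ev_against`.
* No Bayes factors, and no decision thresholds baked in: values like 0.05
  are interpretation, not code.
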