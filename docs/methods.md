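# Methods

## Model and conventions

The diversification process starts at the crown age t_c with two ancestor
species and runs to the present t_p; time increases from past to present
throughout.  Per-species speciation and extinction rates λ_n(t), μ_n(t) may
depend on the current diversity n and on time; they are clamped at zero
inside the rate model so the process generator is always valid.  The data
are the branching times of the ultrametric reconstructed tree (t_2 < … <
t_{k_p−1}, with the conventions t_0 = t_1 = t_c, t_{k_p} = t_p); topology is
discarded because for this model class all topologies with the same
branching times are equally probable.  All likelihoods are densities in the
branching times: the dt differentials at the nodes are dropped, as is
standard, so values are comparable across methods but a user comparing
against simulation histograms must multiply by bin widths.

Two sampling schemes at the present are supported: n-sampling (a known
count m_p of extant species is absent from the tree) and ρ-sampling (each
extant species is included independently with probability f_p).
Conditioning is always on survival of both crown lineages to the present —
survival, not sampled survival — so the same conditioning probability P_c
divides both sampling variants.  This choice matters for ρ-sampling: the
numerator then retains the crown factor (1−ξ̃_c)², because even a surviving
crown lineage may have no *sampled* descendants.  The closed-form and
Q-framework routes in this package implement the same convention, which is
what makes them agree identically; a sampled-survival conditioning would
instead cancel that factor.

## The Q-framework

Q_m^k(t) is propagated as a vector over m = 0..M:

* **Branches.**  The tridiagonal ODE system (sub-diagonal
  λ_{k+m−1}(m−1+2k), diagonal −(λ_{m+k}+μ_{m+k})(m+k), super-diagonal
  μ_{k+m+1}(m+1)) is integrated with scipy's BDF solver; the exact
  tridiagonal Jacobian is supplied as a sparse matrix, which keeps the
  per-step linear algebra O(M).  The operator chain is realized as
  sequential ODE solves, not matrix exponentials: for time-dependent rates
  the generator at different times need not commute, and the ODE solution
  is correct regardless.
* **Nodes.**  At branching time t_k the diagonal operator k·λ_{k+m}(t_k)
  is applied and k increments.
* **Start.**  Q_m^{k=2}(t_c) = δ_{m,0}: no missing species at the crown.
* **Scaling.**  Q magnitudes decay exponentially with tree age and k_p; a
  log-scale factor is split off whenever the vector maximum leaves a unit
  window, so the stored values stay well scaled.
* **Truncation.**  No inflow from m = M+1 (reflecting closure).  Two
  defenses are in place: a tail-ratio check Q_M/max_m Q_m (default
  threshold 10⁻⁶) after every branch solve, and an adaptive chooser that
  starts at M = max(3k_p, m_p+20, 30) and doubles until a further doubling
  moves the log-likelihood by < 10⁻⁹ (hard cap 10⁴).  With zero extinction
  the m > 0 components never feed back into Q_0 (the downward coupling is
  proportional to μ), so the tail check may be disabled for pure-birth
  runs; note that the m > 0 components themselves are *not* zero under pure
  birth — they track would-be-unsampled lineages — only Q_0 decouples.

The conditioning probability propagates δ_{m,0} with k = 2 and no node
operators over [t_c, t_p] and applies the weights 6/((m+2)(m+3)), which for
m = 0 equal 1.  ρ-sampling is assembled as the weighted sum
Σ_m f^{k_p}(1−f)^m Q_m (the m = 0 row of the mass-extinction operator); the
delta-spike extinction route is kept only as a conceptual cross-check, via
the thinned-geometric identity tested against first principles.

## Kendall functions

For diversity-independent rates the single-lineage descendant distribution
is P_0 = ξ, P_n = (1−ξ)(1−η)η^{n−1}.  ξ and η are evaluated from their
integral representations by solving one initial-value problem for
(α, ∫λα, ∫μα) with a high-order explicit method (DOP853, rtol 10⁻¹²) —
this avoids O(n²) nested quadrature — and both printed variants (λ-integral
and μ-integral denominators) are formed and required to agree within 100×
the quadrature tolerance.  Constant-rate models short-circuit to the closed
forms; when |λ−μ|·Δ < 10⁻⁸ the analytic critical limit
ξ = η = λΔ/(1+λΔ) (and its ρ-sampling generalization with fλΔ) replaces
the 0/0-unstable printed expressions.  The ρ-sampling variants ξ̃, η̃ fold
f_p into the same denominators; f_p = 1 reproduces the plain pair exactly.

Default tolerances — quadrature 10⁻¹⁰ absolute, branch ODE rtol 10⁻¹⁰ with
atol 10⁻¹⁴ — are the package's own choices (no external reference
prescribes them) and are exposed as arguments everywhere.

## Generating-function oracle

For diversity-independent rates the generating function of the Q-vector is
the closed product F_k(z,t) = H²(z,t_c,t)·∏_{j=2}^{k−1} jλ(t_j)H(z,t_j,t)
with H = (1−ξ)(1−η)/(1−zη)².  The oracle builds these as truncated power
series (coefficients of H are (1−ξ)(1−η)(m+1)η^m) and multiplies them by
truncated convolution, never touching the ODE code path.  Coefficient
extraction at degree m_p gives Q_{m_p}^{k_p}(t_p) a second way; a third is
the fully closed form with composition sums.  The composition sum
Σ_{m|m_p} ∏_j (m_j+1)η_j^{m_j} is computed as the degree-m_p coefficient of
∏_j (1−η_j z)⁻² by series convolution, O(k_p·m_p²); exhaustive enumeration
is retained only as a test oracle.  Series arithmetic is plain floating
point; near-critical rates (η → 1) are handled by enlarging the truncation,
not by higher precision, at the problem sizes exercised here.

## Simulator

Exact Gillespie simulation from the crown pair, with total rates
n·λ_n(t), n·μ_n(t).  Time-dependent rates use thinning against an envelope
equal to 1.05× the maximum of the total rate over a 65-point bracketing
grid of the remaining window, refreshed after every event; the accepted
event is then exact.  The grid maximum is not a certified bound for
arbitrarily wiggly rate functions — an undershoot is detected and raised as
a configuration error rather than silently biasing the sample — so sharply
oscillating rates need a smoother parameterization.  n-sampling removes a
uniformly chosen subset of exactly m_p extant species (replicates with
fewer extant species than required are flagged infeasible, never silently
resampled); ρ-sampling thins independently.  Reconstruction prunes to
sampled tips, suppressing unifurcations, and reports which condition failed
(too few tips, or a crown lineage without sampled descendants) instead of
returning a degenerate tree.  Random streams derive per-replicate
generators as default_rng([seed, r]) so any replicate is reproducible in
isolation.

The simulator emulates exactly the process the likelihoods describe —
Markovian speciation/extinction with memoryless lineages and exchangeable
tips.  It does not emulate features of real phylogenies such as
measurement error in branching times, lineage-specific rate variation, or
non-random taxon sampling; passing simulation-closure tests therefore
validates internal consistency of the implementation, not the adequacy of
the model for any empirical clade.

## What the validation suites cover, and at what size

* Diversity-independent n-sampling: 200 random configurations (constant and
  exponentially time-modulated rates, λ ∈ [0.1,1], μ ∈ [0, 0.9λ], crown
  windows of 1–3 time units, k_p ∈ 2..6, m_p ∈ 0..4), Q-framework vs
  breaking-the-tree closed form, tolerance 10⁻⁶ in log-likelihood.  The
  sweep truncation M = 900 is sized for the worst draws (growing rates near
  criticality, where the missing-species distribution is widest).
* ρ-sampling: the same grid with f_p ∈ {0.2, 0.5, 0.9, 1}, plus the
  identity P_s = f^{k_p}F_{k_p}(1−f) against the series oracle at 10⁻⁸.
* Pure birth with linear diversity dependence λ_n = λ₀(1−n/K), μ = 0:
  50 random trees against the finite product formula at 10⁻⁸ (ODE tolerance
  tightened to 10⁻¹², which this small non-stiff system affords).
* Conditioning identity P_c = (1−ξ)² on a 5×5 rate grid at 10⁻⁸ relative.
* Kendall quadrature vs printed constant-rate forms at 10⁻¹⁰, including
  continuity across λ = μ.
* Oracle triangle (ODE / series / closed form) pairwise at 10⁻⁸.
* Simulation closure at λ = 0.8, μ = 0.4 over 5 time units, 10⁴
  replicates: survival fraction within 3 Monte-Carlo SE of the propagated
  P_c, occupancy histogram vs the truncated master equation by a pooled
  chi-square test at significance 10⁻³, mean tip count within 3 SE of
  2e^{(λ−μ)Δ}.
* Parameter recovery: 100 pure-birth trees at λ = 0.8 over 3 time units
  (≈ 20 tips on average); the grid-search MLE (grid 0.4–1.6, step 0.01)
  under the branching-time likelihood has mean within 10% of truth.  The
  residual few-percent downward shift of the mean is ordinary small-sample
  MLE behavior for per-tree estimates, not an implementation artifact.

These sizes keep the full test run in a few minutes on one CPU while
leaving comfortable margins at every tolerance.

## Known limitations

* The Q-framework supports diversity-dependent models *with* extinction,
  but no independent analytic formula exists for that regime; correctness
  there rests on the proven special cases plus the master-equation and
  simulation cross-checks.  Results for such models should be read with
  that caveat.
* Components Q_m many orders of magnitude below the vector maximum (e.g.
  m_p ≫ E[missing]) fall below double-precision ODE resolution; the
  degenerate-likelihood error reports this rather than returning noise.
* Only crown-start processes are handled (no stem age), conditioning is on
  crown survival only, and missing species at the crown age are excluded
  by the initial vector δ_{m,0}.
* The individual Q_m values are treated as nonnegative quantities
  proportional to probabilities; the implementation asserts nonnegativity
  but not boundedness by 1.
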