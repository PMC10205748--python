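# Methods

## Model and regimes

The package models intratumor competition between a drug-sensitive burden
`S(t)` and a drug-resistant burden `R(t)` with shared logistic resources:

    dS/dt = r (1 − (S + R)/K) S − u δ S
    dR/dt = r (1 − (c S + R)/K) R

| parameter | meaning | units | reference scale |
|---|---|---|---|
| `r` | intrinsic growth rate of both clones | per day | 0.13–0.18 |
| `K` | shared carrying capacity | burden (IU/L-equiv.) | 540–800 |
| `δ` | kill rate of sensitive cells at MTD | per day | 0.09–0.14 |
| `c` | competitive strength of S over R | — | 1.7–3.2 (always > 1) |
| `u` | normalized dose (fraction of MTD) | — | [0, 1] |

Burdens are treated as proportional to a serologic marker (LDH); no claim
is made that they are literal cell counts. Writing `δ_eff = uδ`, the
dynamics fall into three regimes separated by `r` and `r(c−1)/c`:
monostable resistant takeover for `δ_eff > r` (Case I) and for
`r > δ_eff > r(c−1)/c` (Case II, the decline-then-relapse phenotype under
MTD), and bistability for `0 < δ_eff < r(c−1)/c` (Case III), where the
sensitive-only state `(K(1 − δ_eff/r), 0)` is locally stable and its basin
is bounded by the stable manifold of the unstable coexistence equilibrium.
Boundary equalities are reported as "degenerate" rather than silently
assigned; `u = 0` is reported as "untreated" (its resistant-only state is
non-hyperbolic, so no stability label is asserted there).

Containment at a tolerable volume `K_tol` requires
`r(1 − K_tol/K) < δ_eff < r(1 − 1/c)` — the effective dose window. Both
bounds are exposed on the kill-rate scale and normalized by `δ` (fractions
of MTD, clamped to [0, 1]). The window is nonempty iff `K_tol > K/c`; the
fraction `K/(c·K_0)` of the initial burden is the smallest tolerable
volume at which containment is possible at all.

## Numerical integration

Two integrators are used deliberately:

- `model.simulate` (general dose policies) uses adaptive RK45 with
  `rtol = 1e−8`, `atol = 1e−10·K`. Bistability makes trajectories near the
  separatrix tolerance-sensitive, hence the tight settings. Negative
  overshoot is clamped to zero (Poisson-scale burdens cannot be negative).
- The likelihood, identifiability, basin, adaptive-therapy and
  control sweeps use a compiled fixed-step RK4 kernel (step ≤ 0.1 day for
  the likelihood, 0.05 day elsewhere). With rates of order 0.2/day the
  local error is ~(r·Δt)^5 ≈ 1e−9 relative; the test suite checks the two
  integrators against each other at 1e−5 relative. The kernels exist
  because profile likelihood and the dose × pause sweep each require on
  the order of 1e5 ODE solves.

Attractor membership integrates to `max(4000, 30/r)` days and declares
convergence within `1e−3·K` (Euclidean) of an attractor — a choice, since
no convergence tolerance is canonical; the slow saddle transit makes a
long horizon necessary. The separatrix is located by bisection in `R`
along vertical sections `S = const` (bracket `1e−6·K`): membership is
monotone in `R` at fixed `S`, whereas rays through the saddle do not cross
its stable manifold transversally, so a radial parameterization around the
saddle is ill-posed.

## Observation model and calibration

Observed burdens are Poisson with the model-predicted total
`y(t_n) = S(t_n) + R(t_n)` as intensity:

    NLL(p) = Σ_n [ −V(t_n) ln y(t_n; p) + y(t_n; p) + lnΓ(V(t_n)+1) ]

The `lnΓ(V+1)` term generalizes the factorial so real-valued (non-integer)
burdens are accepted; it is constant in `p` and kept only so absolute NLL
values are comparable. Initial conditions are not fitted: `S(0)+R(0)` is
anchored to the first observation and the resistant fraction fixed at 1%,
leaving exactly `(r, K, δ, c)` free — the identifiability analysis
presumes this. Optimization is Nelder–Mead over
`(ln r, ln K, ln δ, ln(c−1))`, which enforces positivity and `c > 1`
without penalties; ten restarts perturb the start log-uniformly by ±50%
(the simplex method is local and pilot fits showed a competing local
minimum with `δ ≈ 0`). Convergence: simplex tolerances `1e−8` in both
coordinates and function value.

## Identifiability

The sensitivity matrix stacks `∂(S,R)/∂(r,K,δ,c)` at the observation
times, by central differences at `(1 ± ε)p̂` with `ε = 0.001`;
sensitivities are raw (unscaled). The Fisher information is `F = MᵀM`.
The numerical rank counts singular values above `τ·σ_max` with
`τ = 1e−12`: differencing noise is ~1e−6 relative in `M`, and singular
values square in `F`, so the numerically-zero floor of `F` sits near
(1e−6)² — a threshold of 1e−8 on `F` would misclassify genuinely
informative directions (rich 30-point designs carry `σ₄/σ₁ ≈ 5e−10`).

Profile likelihoods sweep each parameter over ±20% of its estimate on a
41-point grid, re-fitting the other three parameters warm-started outward
from the estimate. "Identifiable" requires an interior minimum whose
endpoints exceed it by more than 1.92 (the χ²₁ 95% half-threshold) — an
operationalization chosen here, as no numeric criterion is canonical. The
overall verdict requires full FIM rank *and* all four interior profiles,
because the two diagnostics can disagree (a full-rank FIM with a flat
profile direction). A multi-start uniqueness check (≥20 dispersed
Nelder–Mead starts; agreement within 1% NLL and 5% in parameters) stands
in for symbolic structural analysis.

## Synthetic cohort and the recovery study

The generator emulates an MTD-treated melanoma cohort: 5–10 visits over
180–250 days (even spacing with ±5-day jitter; the real visit schedule is
not public), parameters drawn uniformly from ranges bracketing the
reference patients, kill rates drawn from the interior 15–85% of the
Case II interval `(r(c−1)/c, r)` so every synthetic patient shows the
decline-then-relapse phenotype, initial burdens 300–800 (capped at 0.9·K),
a 1% resistant fraction, and Poisson noise. An optional flag multiplies
one interior point by 1.5 to mimic the occasional off-trend measurement;
no canonical outlier magnitude is implied. Per-patient seed streams are
spawned from the cohort seed, so patient `i` is reproducible regardless of
how many others are generated.

What the generator does **not** emulate: assay-specific (non-Poisson)
noise, dropout/censoring, visit-dependent measurement error, or
phenotype plasticity. Passing recovery tests therefore demonstrate
correctness of the estimator under the stated observation model, not
robustness to real-world LDH artefacts.

The parameter-recovery study (`dosewindow.recovery`) refits 20 synthetic
patients observed at a **log-spaced** 30-point schedule over 300 days.
The schedule was fixed by design analysis, not data fitting: the
Cramér–Rao bound (including the first-observation anchor as a nuisance)
shows an even 30-point grid cannot resolve the `r`–`δ` likelihood ridge
(bound for `r` ≈ 14% relative), while front-loading points into the
initial decline — whose curvature separates `r` from `δ` — brings the
bound to ≈ 9%/7% for `r`/`δ`. Even so, the achievable median error for
`r` sits near the 10% regression bound, so reseeded reruns of the study
can land slightly above it; `δ`, `c` and `K` have comfortable margins.

## Optimal control

The containment schedule minimizes `J(u) = ∫₀ᵀ [S + R + ½Bu²] dt` subject
to the dynamics and the endpoint `S(T) = K_tol`, with `B` the
toxicity/cost weight of the quadratic dose penalty. Pontryagin's principle
gives the adjoint system and the pointwise characterization
`u* = clamp(δSλ₁/B, 0, 1)`. The solver is a forward–backward sweep on a
fixed mesh (4 steps/day; 5841 nodes at `T = 1460`, forward and backward
grids must coincide), with the damped update `u ← ½(u_old + u_formula)`
(undamped sweeps oscillate), iterated to a relative L1 change below 1e−8 —
tight enough that the returned control satisfies the pointwise
characterization to 1e−6 — with a 500-sweep cap and divergence detection.
The endpoint is enforced by secant iteration on the free terminal adjoint
`λ₁(T)` (initial guesses 0 and 10, chosen to bracket the plateau-scale
value `≈ 1/|net rate|`), stopping at `|S(T) − K_tol| < 1e−3·K_tol` within
60 steps; each sweep is warm-started from the previous control. Halving
the mesh step changes the cost by < 0.1% and the plateau by < 0.005
(checked in the suite).

Within the `B`-sweep, larger `B` buys a lower plateau dose at the price of
a terminal dose spike that rescues the endpoint; the "containment" `B` is
the one whose schedule is maximally flat (minimum variance of `u*` over
the last 10% of the horizon). Its plateau — the median of `u*` over the
middle 50% of the horizon — is the minimum effective dose, and coincides
(to two decimals) with the lower edges of both the continuous and the
adaptive dose windows. literature weight values (e.g. `B = 691.9` for the
reference patient) are treated as approximate: they are
discretization-sensitive, so the package reproduces the containment
behavior at that `B`, not the literal weight. Very small weights can fail:
the terminal state then sits so close to the separatrix that
`S(T; λ₁(T))` becomes effectively discontinuous at double precision and
the secant stalls; such failures are reported, not hidden.

## Adaptive therapy

The scheduler applies the dose until the total burden falls below
`pause_level × (S(0)+R(0))`, pauses until it regrows to `0.999·K_tol`,
and repeats; `K_tol` doubles as the progression threshold. TTP is the
first time the burden strictly exceeds `K_tol` (relative tolerance 1e−9,
so starting exactly at `K_tol` is exempt), the degenerate value 1 when the
burden grows from treatment start (tested as `d(S+R)/dt > 0` at `t = 0⁺`
under the ON dose), and the horizon when the tumor never progresses.
Switching times are localized by bisection to 1e−6 day and 1e−6·K in
burden. Default protocol: doses 0.01–1.00 in steps of 0.01, pause levels
{0.5, …, 0.9}, a 1460-day horizon, initial state
`(0.99, 0.01) × K_tol`. The adaptive window `EDW_AT` is the maximal
contiguous dose band whose every cell attains the full horizon; one
reference patient's band is narrower than 0.01, so sub-0.01 steps are
supported and that band is asserted only as nonempty with width ≤ 0.01.

## Design choices that were genuinely open

- Fixture provenance: the reference parameters are stored verbatim and
  checksummed; the pipeline re-derives the window bounds from `(r, K, c)`
  as a self-test, separating data provenance from computation.
- Report percentages round half-up to integer percent.
- The initial burden `K_0` implied by a reference lower bound is recovered
  by inverting `r(1 − K_0/K)`.
- The CLI is a thin layer; all computation lives in the library.

## Known limitations

- Two genetically fixed clones, well-mixed, no immune compartment, no
  phenotype switching, and a burden marker assumed proportional to total
  cell number — the same abstractions as the underlying model.
- Containment statements are asymptotic properties of the deterministic
  ODE; stochastic extinction/fixation at low copy numbers is outside the
  model.
- The recovery study's `r`-error bound is at the statistical wall (see
  above); this is a property of the design and noise model, not of the
  optimizer.
- Structural identifiability is addressed empirically (multi-start
  uniqueness), not symbolically.
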