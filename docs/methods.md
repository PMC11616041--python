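# Methods

## 1. Model structure

Eight components connected by first-order fractional transfer
coefficients L(I,J) (fraction of compartment J moved to compartment I
per day):

```
dose -> 1 -> 2 -> [delay 3] -> 4 -> 5 (plasma) <-> 6 (stores, large)
        |    |                              <-> 7 (stores, small)
        v    +-----------------> 5           -> [delay 8] -> out
       out                           6 -> out
```

- Compartment 1: dose entry; exits L(2,1) = 30/d (absorption) and
  L(0,1) = 9.99/d (loss), fixing absorption efficiency at
  30/(30+9.99) = 0.7502.
- Compartment 2: chylomicron processing; exits L(3,2) = 30/d into the
  absorption delay and L(5,2) = 0.3/d directly to plasma.
- Component 3: pure time delay DT(3) (fitted, ≈ 0.129 d).
- Compartment 4: hepatocytes, secreting retinol-RBP into plasma at
  L(5,4).
- Compartment 5: plasma retinol, the sampling site. Exchanges with
  storage compartments 6 and 7 and feeds delay 8 (DT(8) = 0.052 d),
  which represents irreversible tissue uptake.
- Irreversible losses: L(0,1), L(0,6), and all of delay 8's throughput.

**Loss-partition constraint.** L(8,5) is eliminated by requiring the two
irreversible disposal fluxes to be equal at steady state,
R(8,5) = R(0,6), which gives

```
L(8,5) = L(0,6) · L(6,5) / (L(5,6) + L(0,6)).
```

This holds exactly at every fitting iterate (structural, not penalized).

## 2. Tracer solution

The sub-system upstream of plasma is feed-forward, so it is solved in
closed form: q1 and q2 are one- and two-exponential functions, and the
fluxes entering the delay and the plasma are analytic. The exchange
block (q4, q5, q6, q7) is linear with constant coefficients, so its
response to each exponential forcing term (with onset shifted by DT(3))
is evaluated exactly by eigendecomposition; running integrals (needed
for cumulative losses and the delay-8 bookkeeping, which uses the plasma
integral at t − DT(8)) use the numerically stable φ(z) = (e^z − 1)/z
form. The result is the exact solution of the delay system — a strictly
stronger form of method-of-steps in which the lagged forcing is known
analytically rather than from dense interpolation.

Degenerate spectra are handled in two ways: a genuine coincidence
between an upstream decay rate and an exchange eigenvalue triggers a
relative 1e-6 nudge of the upstream source coefficients (mass balance is
preserved exactly; output error O(1e-7)), and a near-defective
eigenvector matrix falls back to numerical integration (`method="ode"`,
LSODA with rtol 1e-9/atol 1e-12, analytic forcing, integration split at
the delay onset). The two paths agree to ≈1e-8 on the study grid, and
both are checked in the test suite against an independent 256-stage
Erlang-chain approximation of the delays (matrix-exponential stepping of
a 521-state linear system): agreement is ≈1e-5 on plasma fraction of
dose for t ≥ 0.5 d, comfortably within the 1e-4 oracle tolerance. Mass
conservation holds to ~1e-12 (analytic) / ~1e-9 (ODE).

## 3. Steady state and summaries

Given the group plasma mass M(5), the tracee balance is a 6-unknown
linear solve (masses of compartments 1, 2, 4, 6, 7 and dietary input
U(1)). Derived quantities:

- TBS = M(6) + M(7); disposal rate DR = R(0,6) + R(8,5);
  U(1) = DR / absorption efficiency (automatic from whole-body balance).
- Plasma transit time = 1/(L(6,5)+L(7,5)+L(8,5)).
- Expected plasma visits from the embedded jump chain,
  1/(1 − p_return); residence time = visits × transit time. The
  recycling number is reported as visits − 1 (≈ 25 for the bundled
  parameters; see §6).
- FCR = 100·DR/(M5+M6+M7) %/d; store half-life reported as 50/FCR
  (conventional arithmetic; an ln 2 variant is available);
  years-of-stores = TBS/DR/365.

## 4. Super-subject composite and fitting

Per-subject fraction of dose FDp = tracer concentration × plasma volume
/ dose, with plasma volume from the Nadler female blood-volume
regression × (1 − hematocrit); missing hematocrits are imputed from the
cohort mean and flagged. Subjects whose *every* FDp falls below 10% of
the contemporaneous cohort geometric mean are excluded whole (the
implausibly-low-dose screen; threshold configurable — note a subject who
is alone at a sampling time cannot be flagged at that time, since they
define the contemporaneous mean). Remaining values are pooled into
per-time geometric means with fractional-standard-deviation (FSD)
weights: 0.02 at day 14, 0.05 at days 21/28, 0.5 where n ≤ 4, 0.1
elsewhere.

The fit minimizes Σ((obs − model)/(FSD·obs))² over the logs of the seven
adjustable parameters {L(5,4), L(6,5), L(5,6), L(7,5), L(5,7), L(0,6),
DT(3)} with `scipy.optimize.least_squares` (trust-region reflective),
seeded multiplicative restarts (default 5, ×/÷1.5 jitter), and
convergence at ftol 1e-10 / gtol 1e-8. Although the log-parameterization
already enforces positivity, wide physical boxes are imposed (rates
1e-7–1e4 /d, DT(3) 1e-5–20 d): without them, restart trajectories can
wander to numerically degenerate regions (rates ~e±40) where the model
evaluation slows by orders of magnitude. The boxes exceed physiological
values by several orders of magnitude; a parameter finishing at a bound
raises a warning. Parameter FSDs come from the Gauss–Newton covariance
on the log scale, cov = s²(JᵀJ)⁻¹ with s² = WRSS/(n − p); a singular
information matrix raises an unidentifiable-parameter report naming the
offending directions.

## 5. RID, cohort generator, pipeline

RID coefficients from the fitted model: Fa(t) = FD6 + FD7,
SAp = FDp/M(5), SAs = Fa/TBS, S = SAp/SAs, FaS = Fa·S (so that
FaS = FDp·TBS/M(5) identically). TBS for an individual = FaS(t)/SAp(t)
with SAp from her own sample; liver concentration assumes 80% of body
vitamin A in a liver weighing 2.4% of body weight.

The synthetic cohort generator draws anthropometry from truncated
normals, applies lognormal multipliers (geometric mean 1, configurable
CV) to the adjustable parameters, and induces stores heterogeneity by
jointly rescaling L(5,6) and L(0,6) (preserving their ratio and hence
the loss partition) until each subject's own steady state hits her
lognormal TBS target. Sampling schedules follow the study design: all
subjects at day 14, an even 21/28 split, and one auxiliary time dealt
from repeated random permutations so a per-time cap is respected.
Measurement noise is multiplicative lognormal. All outputs are
bit-reproducible for a fixed (config, seed).

The pipeline (`retikin all`) chains generation/loading → composite →
fit → steady state → summaries → RID coefficients → per-subject
predictions → group summaries, writing CSV reports plus `results.json`;
report-only mode reproduces the state-variable and coefficient tables
from a parameter file without data.

## 6. Known limitations and discrepancies

- **Recycling number.** The bundled coefficients imply ≈26.2 expected
  plasma visits (≈25 recycles) and a ≈29 d flux-weighted interval
  between recycles. Conventional reports of ≈37 recycles / ≈30 d for
  this parameter set are not reproducible under any standard definition
  we examined; the suite asserts the computed value against an
  independent absorbing-Markov-chain oracle and documents the gap.
- **FaS offset.** Computed FaS values (0.974/0.684/0.604 at
  14/28/91 d) sit ≈1% below conventionally reported ones
  (0.983/0.691/0.610), consistent with round-off in 6-digit printed
  coefficients; ratios across days match exactly.
- **Terminal-slope identifiability.** From a single composite curve the
  storage-loss rate L(0,6) is weakly identified: on noisy synthetic
  cohorts its estimate often collapses toward zero on individual seeds
  (warned as a bound hit / singular information matrix), dispersing
  per-seed TBS errors while leaving the estimator close to
  median-unbiased across seeds. This is a property of the design (few
  late time points, FSD 0.1 weights), not of the optimizer.
- **Generator dispersions are placeholders.** Only composite data
  existed for the source population, so between-subject kinetic CVs,
  the plasma retinol distribution, and the noise CV are plausible
  defaults, clearly configurable, not estimates.
- **No inflammation adjustment, no child/lactation models, no
  mixed-effects estimation** — the method is a single fit to the
  composite curve by construction.
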