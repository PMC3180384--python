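# Methods

This note documents the statistical models, the numerical choices, and the
limits of what the synthetic tests demonstrate.

## Time convention and input handling

Node "age" is time before present; tips sit at age 0 and the crown (root)
at age equal to the tree depth.  All analyses operate on the branching
times — the n−1 node ages of a rooted, binary, ultrametric chronogram —
which are a sufficient statistic for every model here.  Trees are rescaled
to unit root depth before analysis (the scale only reparameterizes rates;
γ, ΔAIC and all p-values are scale-invariant, which the tests check
numerically).

Ultrametricity is validated to a relative tolerance of 1e-6: chronograms
produced by numerical ultrametrization carry rounding noise, so smaller
deviations are repaired by snapping terminal branches until all tips are
exactly contemporaneous, while larger deviations are treated as data errors
rather than warnings.  A consequence of snapping is that a parse→write→parse
round trip preserves each branch length to the writer's 10 significant
digits *plus* an absolute perturbation bounded by the accumulated rounding
(~1e-9 of the depth), which is the contract the round-trip test asserts.
Tied node ages are allowed (they produce zero-length internode intervals,
which only ever enter likelihoods multiplicatively as exposure, never as
divisors).  Inner-node labels are ignored, explicit root edges discarded,
and polytomies rejected.

## The γ statistic and its nulls

γ standardizes the "center of mass" of the cumulative lineage-time
T_i = Σ_{k≤i} k·g_k.  Under constant-rate pure birth the normalized
T_i/T are order statistics of n−2 iid uniforms, so γ is a standardized
uniform mean: mean 0, sd 1, and very nearly normal already for n ≳ 10.
The one-tailed p-value is the lower normal tail Φ(γ).

The pure-birth simulator draws internode intervals sequentially:
g_k ~ Exponential(k·λ_k) while k lineages exist, attaches each new lineage
to a uniformly chosen extant lineage, and cuts the tree at the instant the
(n+1)-th event would begin — so the final interval g_n is a full
Exponential(n·λ_n) draw, justified by memorylessness.  This choice is
load-bearing: cutting instead *at* the n-th event (as some legacy
simulators do) shifts the γ null right by ≈ +0.3 to +0.7 at small n and
destroys the mean-0/sd-1 calibration.  The test suite pins the calibration
(null mean and sd within ±0.10; 5% quantile at n = 500 within ±0.06 of
−1.645) and cross-checks γ itself against ape's `gammaStat` to 1e-8.

The MCCR test corrects for incomplete sampling: the full clade size is the
known richness inflated by 10% assumed undescribed diversity (rounded half
away from zero), complete trees of that size are simulated, pruned
uniformly at random to the sampled tip count, and the empirical α-quantile
of γ (linear-interpolation quantile) over 5000 replicates is the corrected
critical value γ_C.  Monte Carlo p-values use the add-one convention
p = (1 + b)/(reps + 1), so the smallest reportable p is 1/(reps+1).
Because random pruning biases γ negative, γ_C always lies left of the
complete-sampling value; the size of the test is then correct by
construction, which a calibration test verifies on fresh pruned-null draws.

Per-replicate randomness uses a counter-based scheme
(`SeedSequence((seed, i))`), making replicate sets reproducible and
order-independent.

## Likelihoods

**Pure-birth family** (yule1, yule2, ddl, ddx): the piecewise likelihood

    LH = Σ_{k=2..n−1} ln(k·λ_k) − Σ_{k=2..n} k·λ_k·g_k

with λ_k the per-lineage rate during the k-lineage interval (yule1: r1;
ddl: r1(1 − k/K); ddx: r1·k^(−x); yule2: r1 above the shift age st, r2
below, splitting any interval that straddles st).  The final interval
contributes exposure only (the process is censored at the present).  The
Σ ln k combinatorial constant is included throughout; MLEs, ΔAIC and all
comparisons are invariant to it.  A non-positive rate attached to an
observed branching yields −∞ rather than an exception.

**Constant birth–death** in (r = λ−μ, a = μ/λ): derived via the
coalescent-point-process construction — node depths iid with
F(x) = (1 − e^(−rx))/(1 − a·e^(−rx)) conditioned on the crown age and on
both crown lineages surviving:

    ln L = ln (n−1)! + (n−2) ln r − r(2x₂ + Σ_{i≥3} x_i)
           + n ln(1−a) − 2 Σ_{i=2..n} ln(1 − a·e^(−r x_i))

This is algebraically identical to ape's `birthdeath` deviance (checked in
the tests to 1e-6) and reduces exactly to the yule1 form at a = 0 — the
binding nesting contract.

**Time-varying birth–death** (spvar/exvar/bothvar): rates decay
exponentially in time measured forward from the crown ("explosive start"):
λ(t) = λ₀·e^(−k·t_fwd) and μ(t) = μ₀·e^(−z·t_fwd) (spvar: z = 0; exvar:
k = 0).  The generalized likelihood uses ρ(t) = ∫₀ᵗ (λ−μ) ds and
W(t) = e^(−ρ(t))(1 + ∫₀ᵗ λ(s)e^(ρ(s)) ds):

    ln L = ln (n−1)! − 2ρ(t_c) − 2 ln W(t_c)
           + Σ_{i=3..n} [ ln λ(x_i) − ρ(x_i) − 2 ln W(x_i) ]

ρ has closed form for exponential rates; the remaining integral is
evaluated by 30-point Gauss–Legendre quadrature per internode segment,
which is exact to well below 1e-8 for these smooth integrands (the
constant-rate reduction to the closed-form bd likelihood is asserted at
1e-8).  At k = z = 0 the model is the constant birth–death model, the
second binding nesting contract.  The published description of these
models is ambiguous about the extinction trajectory; exponential decay was
chosen because it nests cleanly and keeps μ ≥ 0 everywhere.  These three
models are reported alongside the battery but excluded from the headline
ΔAIC, which compares {yule1, bd} against {yule2, ddl, ddx}.

## Fitting

* yule1 — closed form, λ̂ = (n−2)/T.
* ddl, ddx — 1-D profile over the shape parameter (log(K−(n−1)) on a
  241-point grid over ~17 decades, or x on [−8, 8]) with the closed-form
  conditional rate r̂1 = (n−2)/D, refined by bounded scalar minimization
  between the bracketing grid points.
* yule2 — the shift age is profiled over the observed interior branching
  ages (root and most recent node excluded), with closed-form
  events/exposure rate estimates per epoch; an event falling exactly on the
  shift age counts toward the younger epoch.
* bd, spvar, exvar, bothvar — bounded Nelder–Mead with 10 quasi-random
  (Sobol) restarts, the restart seed derived deterministically from a hash
  of the branching times.  The a = 0 (and zero-decay) boundary fits are
  always evaluated explicitly so a fit can never be reported worse than
  its nested submodel.

**DDL boundary ridge.**  K is allowed below n (down to n−1), matching fits
in which the final interval's rate is negative and its survival term
rewards the likelihood.  When the weighted mean Σk²g/Σkg exceeds n−1 the
conditional likelihood is *unbounded* along K → Σk²g/Σkg with r1 → ∞, so
no MLE exists.  The rate is therefore boxed at 100× the pure-birth rate;
a fit pegged at that box is reported with `converged = False`, and
bootstrap replicates with non-converged fits are redrawn.  On trees with a
genuine diversity-dependent signal the optimum is interior and unaffected.

AIC = −2·LH + 2k with k = 1 (yule1), 2 (bd, ddl, ddx), 3 (yule2, spvar,
exvar), 4 (bothvar).  ΔAIC = AIC_rc − AIC_rv, positive favoring rate
variation; its p-value is the add-one proportion of null ΔAIC values (from
pure-birth trees at the full clade size, pruned to the sampled size) at or
above the observed one.

## Synthetic data and fixtures

The generator is the study-conditions module: the nine-clade fixture suite
reproduces the published sampled/known/age triples (47/55/32.4 Ma,
42/47/38.05, 11/13/49, 15/18/9, 10/10/14.4, 19/20/8.2, 10/10/11.9,
28/29/28.2, 75/80/21.9) with diversity-dependent generators (r1 = 5,
K = the 10%-inflated full clade size — clades near their ceiling) for all
but the one clade the study found constant-rate, which is generated as
pure birth (λ = 1).  For yule2 *simulation* the shift is interpreted as
forward time from the crown (total depth is unknown until a forward
simulation ends); fitting keeps the age-before-present convention.
Simulating DDL requires K > n (the final interval needs a positive rate),
slightly stronger than the K > n−1 the likelihood permits.  The bd
simulator conditions on reaching n survivors by acceptance sampling
(capped at 1e5 attempts) and prunes extinct lineages; at μ = 0 it is
exactly the yule simulator.

What the fixtures do *not* emulate: topological imbalance beyond the
uniform-attachment (Yule) prior, dating error and ultrametrization
artifacts, posterior correlation structure among tree samples, or
non-random (e.g. geographically clustered) missing taxa.  Passing tests
therefore demonstrate correctness of the statistics under the stated
generative models, not robustness to reconstruction bias in empirical
chronograms.

## Problem sizes in the shipped tests

The suite simulates at the sizes the statistics are specified at (2000
trees of 50 tips for the γ null; 5000 MCCR replicates; 200 replicates for
parameter recovery and for false-positive control at n ≈ 40; 8000
replicates of n = 500 for the asymptotic quantile, via the interval-level
fast path) and completes in a few minutes on one CPU.

## Known limitations

* The time-varying models assume monotone decaying rates; increasing-rate
  histories are out of scope.
* The yule2 shift grid is discrete (observed branching ages); continuous
  shift optimization is deliberately not attempted, so the reported st is
  always an observed node age.
* The MCCR and bootstrap nulls assume missing taxa are missing uniformly
  at random.
* Consensus-tree construction for posterior samples is out of scope; a
  summary tree must be supplied separately, and γ uncertainty is
  summarized over at most 1000 posterior draws.
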