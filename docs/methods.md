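# Methods

This note documents the model, the inference machinery, the defaults and
the design choices made where the design was genuinely open.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Model of dynamics

The study layout is five contiguous half-open day intervals
[a) pre-perturbation, b) pulse 1, c) recovery 1, d) pulse 2, e) recovery 2]
with the two pulses required to have positive length.  A prototype
signature's log-amplitude is constant on (a), (b), (d) — at the
pre-treatment equilibrium level μ_a and the transient levels X_b, X_d — and
follows `μ + (X − μ)·exp(−Δt/λ)` on (c) and (e), where Δt is elapsed time
since the end of the preceding pulse and λ > 0 is the e-folding relaxation
time in days, measured on the log scale.  The trajectory is therefore
continuous at the pulse-to-recovery boundaries, and one relaxation time
after a pulse the log-amplitude sits at e⁻¹ of the transient plus
(1 − e⁻¹) of the equilibrium (≈ 33%/67%); the tests assert the exact e⁻¹
form.

Interval parameters are linked by normal random-walk increments:
X_b ~ N(μ_a, σ_δ²), μ_c = μ_a + δ_{a→c}, X_d ~ N(μ_c, σ_δ²),
μ_e = μ_c + δ_{c→e}.  Two binary switches activate δ_{a→c} and δ_{c→e}
(otherwise the levels are tied *exactly*), giving the four reachable
equality patterns over (μ_a, μ_c, μ_e); a third switch frees λ_e from λ_c.
The transients X_b, X_d are always free: only the equilibrium levels and
relaxation times carry dimensionality switches.  Switch priors are
Bernoulli(0.5).

## Observation model

Counts are negative binomial parameterized by mean m and inverse shape ε
(Var = m + ε m²), with log link

    m_sot = exp(f(t, θ_k) + γ_so + φ_st).

γ_so ~ N(0, σ_γ²) scales a series' baseline abundance; φ_st is the
*deterministic* centered log total-read count of the sample, so
exp(φ ratio) equals the sequencing-depth ratio.  Making φ deterministic
(rather than a sampled latent) guarantees identifiability of γ and the
signature levels.  ε takes one value (ε₁) on the unperturbed intervals and
another (ε₂) during the pulses, both with log-normal priors.  For ε below
10⁻⁸ the NB mass is evaluated in its exact Poisson limit; the
gamma-function form loses precision there.

### Default hyperparameters

| parameter | default | rationale |
|---|---|---|
| μ_a prior | N(η, 2²), η = log mean count per series | empirical Bayes centering |
| increments σ_δ | 1 (log scale) | e^±1 fold changes typical |
| log λ prior | N(log 7, 1²) | median one week, broad |
| ε₁, ε₂ prior | LogNormal(−1, 1) | CV ~ 40–90% plausible range |
| σ_γ | 1 | order-of-magnitude baseline spread |
| switch prior | 0.5 | dimensionality left to the data |
| DP α prior | Gamma(1, 1) | weakly informative |

All are exposed via `Hyperparams`.

## Inference

One Dirichlet process is shared across subjects (each (subject, refOTU)
series is one mixture unit), which is what makes the combined-ecosystem
SD3 score and cross-subject consensus groups well defined.  The sampler
alternates:

1. **Assignments** — CRP Gibbs with 3 auxiliary fresh components per unit
   (the standard non-conjugate auxiliary-component scheme).  A removed
   singleton's parameters occupy the first auxiliary slot.
2. **Signature parameters** — random-walk Metropolis on μ_a, X_b, X_d, the
   active increments and log λ's, using the joint NB likelihood of the
   signature's member series.
3. **Switches** — reversible-jump toggles.  Birth draws come from the
   prior, so acceptance reduces to likelihood ratio × switch prior odds ×
   any prior factors that move with the activated increment (the a→c
   increment shifts μ_c and hence the X_d prior).  Exception: the λ_e
   birth proposal is an equal mixture of the prior and N(log λ_c, 0.3²) —
   with many member series the λ_e likelihood is sharply peaked and pure
   prior proposals are essentially never accepted, freezing the switch;
   proposing near the shared constant restores mixing while leaving the
   invariant distribution unchanged (the acceptance ratio uses the mixture
   density).
4. **Nuisance** — Metropolis on each γ_so and on log ε₁, log ε₂;
   Escobar–West auxiliary-variable update of α.

Chains initialize one singleton cluster per series with interval-mean
heuristics for the levels, μ-switches on where the empirical level shift
exceeds 0.5, and the λ-switch at its prior probability (no cheap empirical
proxy exists for it).  Proposal scales adapt every 100 sweeps during
burn-in only (target acceptance 0.2–0.5), then freeze, preserving detailed
balance for retained draws.  All randomness derives from the configured
seed through spawned generator streams: identical seeds give bit-identical
pooled samples.

Presets: the **desk-scale** protocol (2 chains × 2,000 burn-in + 2,000
sampling, thin 10 → 400 pooled draws) used by the tests and the acceptance
script, and the **full protocol** (8 chains × 10,000 + 5,000, thin 10 →
4,000 draws) for real analyses.  Convergence can be checked with the
provided potential-scale-reduction statistic (floored at 1, where the
finite-sample estimator's dips below 1 carry no meaning).

## Posterior summaries

* SD1/SD2/SD3 follow the definitions in the README; entropy uses natural
  log (exp(H) makes the "equivalent number" base-free).  SD2^I weights
  subjects by series counts O_s/ΣO_s, which makes SD3 exactly 1 for
  disjoint ecosystems and 1/S for fully shared ones.
* The SD3 permutation test relabels each subject's signature identities
  independently within each draw — preserving every within-subject
  occupancy vector while reducing cross-subject sharing to chance — and
  reports p = (1 + #{SD3_perm ≤ SD3_obs})/(n_perm + 1).  Permuting
  assignments or refitting per subject are alternative readings; this one
  keeps the within-host structure fixed by construction.
* RTD: one constant per series and interval (the posterior median of the
  assigned signature's λ), Gaussian KDE with Silverman bandwidth
  (config-overridable).  The kernel's support extends below zero; the
  density integrates to one over its full support.
* CSGs: average-linkage agglomeration of posterior co-assignment
  probabilities, stopped at the round of the mean occupied-signature count
  across draws; ties broken by lowest pair index (deterministic,
  permutation-equivariant).  Consensus trajectories are mapped to a
  reference subject's time-scale by the piecewise-linear boundary-anchored
  map, centered at the pre-treatment level and scaled to unit maximum
  absolute deviation — the amplitude normalization is a convention; any
  monotone alternative would change only the vertical scale.
* Enrichment: hypergeometric upper-tail p-values at order/family/genus,
  BH-FDR pooled across all (group, rank, label) tests, 0.05 threshold.

## Experimental design

Conditioning on λ's and switch states makes the trajectory linear in the
level parameters with basis entries from interval indicators and decay
weights, i.e. an NB GLM.  The design utility is the prior-averaged,
occupancy-weighted log-determinant of the per-signature Fisher information
(GLM weights m/(1 + εm)) plus a ridge r = 10⁻⁶ so designs smaller than the
parameter count stay comparable during greedy growth.  Forward greedy
selection with earliest-day tie-break is deterministic and
permutation-invariant; prior samples are 500 uniform thins of a fitted
posterior.  The dispersed baseline minimizes the maximum sampling gap on
the candidate grid.  Aggregation across signatures (occupancy-weighted sum
of log-determinants) is a package choice; a single stacked information
matrix would mix parameter blocks of different dimension.

## Synthetic data generator

The generator emulates the antibiotic-pulse study design: 3 subjects,
60 series per subject by default, two 5-day pulses at days 56–60 and
238–242 of a 300-day study, ~38 irregular sampling days (dense around the
pulses), log-normal per-sample sequencing depths (sd 0.15 around 2×10⁵
reads), γ ~ N(0, 0.5²), and NB noise calibrated so the count CV hits the
target 0.6 at the median mean via CV² = 1/m + ε; the pulse-interval
dispersion is 2ε₁ (perturbation increases overdispersion; the exact factor
is unreported in comparable studies and is config-exposed).  Series are
assigned to K = 8 signatures in balanced random fashion.

The gold-standard library is drawn from the prior subject to (i) a minimum
pairwise trajectory RMS separation of 1.0 log units and (ii) an
*identifiability floor*: every active switch effect must amount to at
least a two-fold change (|δ| ≥ log 2; |log λ_e/λ_c| ≥ log 2), including
the transient-to-equilibrium deviations |X_b − μ_c| and |X_d − μ_e| ≥
log 2, since a relaxation time is observable only through the transient it
decays from.  Without the floor, part of the "truth" is unidentifiable
from any data and recovery error measures the benchmark's ill-posedness
rather than the algorithm.  Truth-implied diversity scores treat the
generating configuration as a single degenerate posterior draw.

What the generator does **not** emulate: sequencing-platform artifacts
(chimeras, PCR bias), compositional coupling between taxa (series are
conditionally independent given their signatures), drift in taxonomy
assignment, or non-exponential recovery kinetics.  Passing recovery tests
therefore demonstrate correctness of the inference machinery under the
model's own assumptions at realistic noise, not robustness to model
misspecification.

## Problem sizes and numerical choices

Tests and the acceptance script use the desk-scale protocol and
3 × 60-series datasets (~10 minutes on one core); the full protocol on a
real-sized dataset (3 × ~250 series, 50+ days) is hours.  Exponents in the
NB mean are clipped at ±60 before exponentiation; average-linkage
similarity comparisons use a 10⁻¹² tie tolerance; degenerate KDE inputs
(all constants equal) fall back to a narrow Gaussian bump.  Empty
datasets, non-positive totals, overlapping schedule intervals, and
held-out days overlapping a design are rejected with typed errors.

## Known limitations

* λ's longer than a recovery interval are only weakly identified; their
  posterior medians shrink toward the prior median (one week).
* SD1_λ is the hardest quantity to recover.  When a signature's two
  relaxation times are truly tied, the posterior probability of the λ
  switch does not fall to zero but to the Occam factor — roughly
  √(2π)·σ·p(λ̂), where σ is the posterior width of log λ_e given the
  switch is on — which at desk-scale cluster sizes (~20 member series) is
  0.2–0.4 rather than ≈0.  The expected >1-constant fraction therefore
  shrinks toward the 0.5 switch prior, and its relative error against a
  hard-switch generating truth can reach tens of percent even though the
  posterior itself is exactly correct (the reversible-jump kernel was
  validated against an independence-sampler and quadrature oracle).  The
  bias decays like 1/√(cluster size); at real-study scale (hundreds of
  series per subject) the switch posteriors are decisive.  SD1_μ, SD2 and
  SD3 do not suffer from this: their indicators are driven by level
  contrasts the data measure directly.
* The permutation null for SD3 conditions on the fitted assignments; it
  does not propagate refitting uncertainty.
* Greedy design is forward-only (no swaps/removals), as is conventional;
  it is within the usual (1 − 1/e)-style guarantees for submodular-like
  utilities but not provably optimal.
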