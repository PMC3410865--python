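# trajmix

Bayesian nonparametric inference of **time-dependent signatures of microbial
taxa** from sequencing-count time series under known perturbations, with
signature-diversity statistics, relaxation-time analysis, consensus
signature groups, and automated D-optimal experimental design.

## The problem

Longitudinal 16S surveys of a host microbiome — for example stool samples
collected from human subjects over ~300 days spanning two 5-day courses of
a broad-spectrum antibiotic — yield, per subject, a refOTU × time-point
table of sequencing counts on an irregular sampling grid.  Classical
diversity or dissimilarity indices treat each time-point as a static
snapshot.  `trajmix` instead models each taxon's counts as a realization of
a continuous-time latent trajectory and asks which taxa *share* dynamics,
how fast they re-equilibrate after each perturbation, and how much of that
dynamic repertoire is shared across hosts.

## The model

Counts `y_sot` (subject *s*, refOTU *o*, day *t*) are negative binomial,

    y_sot ~ NB(m_sot, ε),      Var = m + ε m²,
    m_sot = exp( f(t, θ_k) + γ_so + φ_st ),

with a log link: `γ_so` a per-series baseline offset, `φ_st` the centered
log total-read depth, and ε equal to ε₁ on unperturbed intervals and ε₂
during the antibiotic pulses.  The **prototype signature** `f(t, θ_k)` is
piecewise over the five perturbation-delimited intervals (a) pre-antibiotic,
(b) pulse 1, (c) recovery 1, (d) pulse 2, (e) recovery 2: constant at the
equilibrium level `μ_a` on (a) and at the transient levels `X_b`, `X_d`
during the pulses, and an exponential relaxation on (c) and (e):

    f(t) = μ + (X − μ) · exp(−(t − t₀)/λ),

with relaxation time `λ` in days (log scale).  Interval parameters are tied
by a random walk (`μ_c = μ_a + δ_{a→c}`, …), and binary **dimensionality
switches** `c_μ`, `c_λ` activate or tie the extra equilibrium levels and
the second relaxation time, so each signature uses 1–3 distinct levels and
1–2 relaxation constants.

Every (subject, refOTU) series is assigned to a signature by a **Dirichlet
process** mixture shared across subjects.  Inference is MCMC: CRP Gibbs
updates with auxiliary components, random-walk Metropolis on signature
parameters, reversible-jump toggles of the switches, and an Escobar–West
update of the DP concentration.  From the pooled posterior the package
computes:

* **SD1** — expected fraction of refOTUs using >1 equilibrium level
  (SD1_μ) or >1 relaxation time (SD1_λ);
* **SD2** — exponentiated-entropy "equivalent signatures per 100 refOTUs";
* **SD3** — combined-over-independent SD2 ratio measuring cross-subject
  sharing (1/S fully shared … 1 disjoint), with a permutation test;
* **RTD** — kernel density of per-refOTU posterior-median relaxation
  constants per recovery interval;
* **CSG** — consensus signature groups from average-linkage clustering of
  posterior co-assignment probabilities, with consensus trajectories on a
  common time-scale and hypergeometric taxon enrichment (BH-FDR);
* **Designs** — Bayesian D-optimal sampling days for future experiments
  (`g(T) = E_Θ Σ_k w_k log|IM_k(T) + rI|`, greedy optimization), evaluated
  by held-out RMSE against evenly dispersed baselines.

## Worked example

```python
import numpy as np
from trajmix import (McmcConfig, TrajectoryMixture, filter_refotus,
                     run_mcmc, sd1_scores, sd2_score, sd3_score)
from trajmix.simulate import generate_counts_dataset

# three subjects, 20 refOTU series each, two antibiotic pulses, count CV ~60%
data, truth = generate_counts_dataset(n_refotus=20, seed=7)
data = filter_refotus(data)                      # >=5 counts on >=10 days

model = TrajectoryMixture(n_burnin=2000, n_sampling=2000, thin=10,
                          n_chains=2, seed=1)
model.fit(data, truth.schedules)

print("signatures:", model.n_signatures_)
print("SD1 (mu, lambda):", {s: tuple(round(v, 2) for v in p)
                            for s, p in sd1_scores(model.samples_).items()})
print("SD2:", {s: round(sd2_score(model.samples_, s), 1) for s in data.subjects})
print("SD3:", round(sd3_score(model.samples_), 2))
```

Output (about four minutes on one core):

```
signatures: 9
SD1 (mu, lambda): {'S1': (0.9, 0.63), 'S2': (0.81, 0.64), 'S3': (0.84, 0.68)}
SD2: {'S1': 32.4, 'S2': 38.8, 'S3': 30.5}
SD3: 0.4
```

Read: in each subject 81–90% of series changed equilibrium level after at
least one pulse and roughly two thirds used distinct relaxation times on
the two recovery intervals; a typical subject carried ~30–39 equivalent
signatures per 100 series; and SD3 ≈ 0.4 means cross-subject sharing
reduced the combined repertoire to 40% of what independent ecosystems
would show.

The same pipeline is available from the shell:

```bash
trajmix simulate --out sim/ --seed 7
trajmix fit --counts S1=sim/counts_S1.tsv --schedule sim/schedule.yaml --out fit/
trajmix summarize --samples fit/samples.jsonl --schedule sim/schedule.yaml --out fit/
trajmix design --samples fit/samples.jsonl --schedule sim/schedule.yaml \
    --budget 20 --out design.json
```

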