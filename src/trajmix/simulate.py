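"""Synthetic datasets from the generative model, and recovery benchmarking.

The default geometry emulates the antibiotic-pulse study the model targets:
three subjects, two 5-day antibiotic pulses (days 56–60 and 238–242) within
a 300-day study, dense stool sampling around the pulses and sparse sampling
elsewhere (~40 irregular days), and negative-binomial counts with a
coefficient of variation of about 60%.

Because the real study's fitted signatures are not available, the
gold-standard signature library is drawn from the model prior subject to a
minimum pairwise trajectory separation, and — so that the benchmark's
"truth" is identifiable — active switch effects are resampled until they
amount to at least a two-fold change (level increments of at least log 2;
relaxation-time ratios of at least 2).  A level shift smaller than
day-to-day noise would not constitute a scientifically meaningful extra
equilibrium level, and treating it as truth would make recovery error
ill-defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .errors import ConfigError, DataError
from .io_data import CountsDataset, PerturbationSchedule
from .mixture import ModelState, PosteriorSamples
from .signatures import (
    Hyperparams,
    PrototypeSignature,
    evaluate_signature,
    sample_signature_prior,
)

DEFAULT_SCHEDULE = PerturbationSchedule(
    boundaries=((0.0, 56.0), (56.0, 61.0), (61.0, 238.0), (238.0, 243.0), (243.0, 300.0))
)

_TAXON_POOL = {
    "order": ["Bacteroidales", "Clostridiales", "Lactobacillales", "Erysipelotrichales"],
    "family": [
        "Bacteroidaceae", "Porphyromonadaceae", "Ruminococcaceae",
        "Lachnospiraceae", "Lactobacillaceae",
    ],
    "genus": [
        "Bacteroides", "Parabacteroides", "Faecalibacterium", "Roseburia",
        "Blautia", "Lactobacillus", "unclassified",
    ],
}


def default_observation_days(schedule: PerturbationSchedule = DEFAULT_SCHEDULE) -> np.ndarray:
    """Irregular sampling grid: dense around the pulses, sparse elsewhere."""
    a0, b0, c0, d0, e0, e1 = schedule.knots
    days: set[float] = set()
    days.update(float(t) for t in np.arange(a0, b0 - 1, 10.0))
    days.add(b0 - 7.0)
    for start, end in (schedule.boundaries[1], schedule.boundaries[3]):
        days.update([start, start + 2.0, end - 1.0])
    for start, end in ((c0, d0), (e0, e1)):
        for off in (0.0, 1.0, 3.0, 5.0, 7.0, 10.0, 14.0, 19.0, 25.0):
            if start + off < end:
                days.add(start + off)
        t = start + 40.0
        while t < end - 5.0:
            days.add(t)
            t += 30.0
    days.add(e1)
    return np.array(sorted(d for d in days if a0 <= d <= e1))


def simulation_hyperparams() -> Hyperparams:
    """Prior used to draw the gold-standard library (baseline ~200 counts)."""
    return Hyperparams(mu_a_mean=float(np.log(200.0)), mu_a_sd=1.0)


# ---------------------------------------------------------------------------
# library sampling


def _enforce_effect_floor(
    sig: PrototypeSignature, hyper: Hyperparams, rng: np.random.Generator,
    min_effect: float,
) -> PrototypeSignature:
    """Resample active switch effects until they reach the identifiability floor."""
    if min_effect <= 0:
        return sig
    d_ac, d_ce = sig.d_ac, sig.d_ce
    lam_e = sig.lambda_e
    if sig.c_mu[0]:
        while abs(d_ac) < min_effect:
            d_ac = float(rng.normal(0.0, hyper.delta_sd))
    if sig.c_mu[1]:
        while abs(d_ce) < min_effect:
            d_ce = float(rng.normal(0.0, hyper.delta_sd))
    if sig.c_lambda:
        while abs(np.log(lam_e / sig.lambda_c)) < min_effect:
            lam_e = float(np.exp(rng.normal(hyper.loglambda_mean, hyper.loglambda_sd)))
    # relaxation times are observable only through the transient they decay
    # from: the same floor applies to the pulse-to-equilibrium deviations
    mu_c = sig.mu_a + d_ac if sig.c_mu[0] else sig.mu_a
    mu_e = mu_c + d_ce if sig.c_mu[1] else mu_c
    X_b, X_d = sig.X_b, sig.X_d
    while abs(X_b - mu_c) < min_effect:
        X_b = float(rng.normal(sig.mu_a, hyper.delta_sd))
    while abs(X_d - mu_e) < min_effect:
        X_d = float(rng.normal(mu_c, hyper.delta_sd))
    return PrototypeSignature(
        mu_a=sig.mu_a, X_b=X_b, X_d=X_d, d_ac=d_ac, d_ce=d_ce,
        lambda_c=sig.lambda_c, lambda_e=lam_e, c_mu=sig.c_mu, c_lambda=sig.c_lambda,
    )


def sample_prototype_library(
    K: int,
    hyper: Hyperparams | None = None,
    seed: int = 0,
    min_separation: float = 1.0,
    min_effect: float = float(np.log(2.0)),
    schedule: PerturbationSchedule = DEFAULT_SCHEDULE,
    max_tries: int = 1000,
) -> list[PrototypeSignature]:
    """Draw K prior signatures with a minimum pairwise trajectory distance.

    Separation is the root-mean-square difference of log-amplitude
    trajectories on an even day grid; candidates are redrawn until every
    pair clears ``min_separation`` (error after ``max_tries`` failures).
    """
    if K < 1:
        raise ConfigError("need K >= 1 signatures")
    hyper = hyper or simulation_hyperparams()
    rng = np.random.default_rng(seed)
    grid = np.linspace(schedule.start, schedule.end, 200)
    library: list[PrototypeSignature] = []
    trajs: list[np.ndarray] = []
    for _ in range(K):
        for _try in range(max_tries):
            sig = _enforce_effect_floor(
                sample_signature_prior(hyper, rng), hyper, rng, min_effect
            )
            if min_separation <= 0:
                library.append(sig)
                break
            f = np.asarray(evaluate_signature(sig, grid, schedule))
            if all(
                float(np.sqrt(np.mean((f - g) ** 2))) >= min_separation for g in trajs
            ):
                library.append(sig)
                trajs.append(f)
                break
        else:
            raise ConfigError(
                f"could not find {K} signatures at separation {min_separation} "
                f"in {max_tries} draws"
            )
    return library


# ---------------------------------------------------------------------------
# dataset generation


@dataclass
class SimulationTruth:
    """Everything needed to trace each generated count back to its mean."""

    signatures: list[PrototypeSignature]
    units: list[tuple[str, str]]
    z: np.ndarray
    gamma: np.ndarray
    eps1: float
    eps2: float
    phi: dict[str, np.ndarray]
    schedules: dict[str, PerturbationSchedule]
    seed: int
    subjects: list[str] = field(default_factory=list)

    def as_posterior_samples(self) -> PosteriorSamples:
        """The generating configuration as a single degenerate posterior draw."""
        state = ModelState(
            signatures=list(self.signatures),
            z=self.z.copy(),
            gamma=self.gamma.copy(),
            eps1=self.eps1,
            eps2=self.eps2,
            alpha=1.0,
        )
        return PosteriorSamples(units=list(self.units), subjects=list(self.subjects),
                                draws=[state])


def cv_to_eps(cv_target: float, median_mean: float) -> float:
    """Invert CV^2 = 1/m + eps at the median NB mean m."""
    eps = cv_target**2 - 1.0 / median_mean
    if eps <= 0:
        raise ConfigError(
            f"target CV {cv_target} unattainable at mean {median_mean:.1f} "
            "(below the Poisson floor 1/sqrt(m))"
        )
    return float(eps)


def generate_counts_dataset(
    n_subjects: int = 3,
    n_refotus: int = 20,
    K: int = 8,
    schedule: PerturbationSchedule = DEFAULT_SCHEDULE,
    times: np.ndarray | None = None,
    cv_target: float = 0.6,
    gamma_sd: float = 0.5,
    depth_sd: float = 0.15,
    base_total: int = 200_000,
    eps2_factor: float = 2.0,
    hyper: Hyperparams | None = None,
    library: list[PrototypeSignature] | None = None,
    seed: int = 0,
) -> tuple[CountsDataset, SimulationTruth]:
    """Generate a multi-subject NB count dataset from a signature library.

    Series are assigned to signatures in balanced random fashion (every
    signature is used), per-series offsets gamma are normal, per-sample
    sequencing depths are log-normal, and the unperturbed dispersion eps1 is
    calibrated so the counts hit ``cv_target`` at the median mean
    (CV^2 = 1/m + eps); the pulse-interval dispersion is ``eps2_factor``
    times larger.
    """
    rng = np.random.default_rng(seed)
    hyper = hyper or simulation_hyperparams()
    if library is None:
        library = sample_prototype_library(
            K, hyper, seed=int(rng.integers(2**31 - 1)), schedule=schedule
        )
    K = len(library)
    if times is None:
        times = default_observation_days(schedule)
    times = np.asarray(times, float)
    subjects = [f"S{i+1}" for i in range(n_subjects)]
    n_units = n_subjects * n_refotus
    z = rng.permutation(np.arange(n_units) % K)
    gamma = rng.normal(0.0, gamma_sd, size=n_units)

    iv = schedule.interval_indices(times)
    pulse = np.isin(iv, (1, 3))
    F = np.array([evaluate_signature(sig, times, schedule) for sig in library])

    # per-sample sequencing depths -> totals -> read-depth offsets
    phi, totals = {}, {}
    for s in subjects:
        ld = rng.normal(0.0, depth_sd, size=len(times))
        totals[s] = np.maximum((base_total * np.exp(ld)).astype(np.int64), 1)
        lt = np.log(totals[s].astype(float))
        phi[s] = lt - lt.mean()

    # calibrate dispersion at the median mean
    M = []
    for si, s in enumerate(subjects):
        rows = slice(si * n_refotus, (si + 1) * n_refotus)
        M.append(np.exp(F[z[rows]] + gamma[rows, None] + phi[s][None, :]))
    median_mean = float(np.median(np.concatenate([m.ravel() for m in M])))
    eps1 = cv_to_eps(cv_target, median_mean)
    eps2 = eps2_factor * eps1

    counts, refotus = {}, {}
    units: list[tuple[str, str]] = []
    r_vec = np.where(pulse, 1.0 / eps2, 1.0 / eps1)
    for si, s in enumerate(subjects):
        m = M[si]
        y = rng.negative_binomial(r_vec[None, :], r_vec[None, :] / (r_vec[None, :] + m))
        counts[s] = y.astype(np.int64)
        refotus[s] = [f"otu{si * n_refotus + o + 1:03d}" for o in range(n_refotus)]
        units.extend((s, rid) for rid in refotus[s])
        totals[s] = np.maximum(totals[s], y.sum(axis=0))

    taxonomy = _assign_taxonomy(refotus, z, n_refotus, subjects, rng)
    data = CountsDataset(
        subjects=subjects, counts=counts, times={s: times.copy() for s in subjects},
        refotus=refotus, taxonomy=taxonomy, totals=totals,
    )
    truth = SimulationTruth(
        signatures=library, units=units, z=z, gamma=gamma, eps1=eps1, eps2=eps2,
        phi=phi, schedules={s: schedule for s in subjects}, seed=seed,
        subjects=subjects,
    )
    return data, truth


def _assign_taxonomy(refotus, z, n_refotus, subjects, rng) -> dict[str, dict[str, str]]:
    """Labels correlated with the generating clusters so enrichment is testable."""
    tax = {}
    pools = _TAXON_POOL
    for si, s in enumerate(subjects):
        for o, rid in enumerate(refotus[s]):
            k = z[si * n_refotus + o]
            labels = {}
            for rank in ("order", "family", "genus"):
                pool = pools[rank]
                if rng.random() < 0.7:       # cluster-linked label
                    labels[rank] = pool[k % len(pool)]
                else:
                    labels[rank] = pool[int(rng.integers(len(pool)))]
            tax[rid] = labels
    return tax


# ---------------------------------------------------------------------------
# recovery benchmarking


def truth_implied_scores(truth: SimulationTruth) -> dict:
    from .summaries import sd1_scores, sd2_score, sd3_score

    ps = truth.as_posterior_samples()
    out = {"sd1": sd1_scores(ps), "sd2": {s: sd2_score(ps, s) for s in truth.subjects}}
    if len(truth.subjects) > 1:
        out["sd3"] = sd3_score(ps)
    return out


def recovery_benchmark(truth: SimulationTruth, fitted: PosteriorSamples) -> dict:
    """Compare a fitted posterior against the generating configuration.

    Reports relative errors of the signature-diversity scores, median
    relative errors of the per-series relaxation constants on both
    post-pulse intervals, and the adjusted Rand index between the consensus
    partition and the generating partition.
    """
    from .summaries import (
        build_csgs,
        coassignment_matrix,
        posterior_median_lambdas,
        sd1_scores,
        sd2_score,
        sd3_score,
    )

    if list(fitted.subjects) != list(truth.subjects):
        raise DataError("fitted samples and truth cover different subjects")
    if list(fitted.units) != list(truth.units):
        raise DataError("fitted samples and truth cover different units")

    true_ps = truth.as_posterior_samples()
    true_sd1 = sd1_scores(true_ps)
    est_sd1 = sd1_scores(fitted)
    sd_errors: dict[str, dict[str, float]] = {}
    for s in truth.subjects:
        errs = {}
        for i, name in enumerate(("sd1_mu", "sd1_lambda")):
            t, e = true_sd1[s][i], est_sd1[s][i]
            errs[name] = abs(e - t) / t if t > 0 else abs(e - t)
        t, e = sd2_score(true_ps, s), sd2_score(fitted, s)
        errs["sd2"] = abs(e - t) / t
        sd_errors[s] = errs
    result = {
        "sd_rel_errors": sd_errors,
        "max_sd12_rel_error": max(v for errs in sd_errors.values() for v in errs.values()),
    }
    if len(truth.subjects) > 1:
        t, e = sd3_score(true_ps), sd3_score(fitted)
        result["sd3_rel_error"] = abs(e - t) / t

    for interval in ("c", "e"):
        true_lam = posterior_median_lambdas(true_ps, interval)
        est_lam = posterior_median_lambdas(fitted, interval)
        rel = np.abs(est_lam - true_lam) / true_lam
        result[f"lambda_{interval}_median_rel_error"] = float(np.median(rel))

    _, mat = coassignment_matrix(fitted)
    groups = build_csgs(mat, fitted)
    labels = np.empty(fitted.n_units, int)
    index = {u: i for i, u in enumerate(fitted.units)}
    for g, csg in enumerate(groups):
        for m in csg.members:
            labels[index[m]] = g
    result["ari"] = float(adjusted_rand_score(truth.z, labels))
    return result
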