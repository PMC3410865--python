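"""Bayesian D-optimal selection of sampling days for future experiments.

Conditioned on the relaxation times and switch states, a prototype
signature's trajectory is linear in its level parameters
(mu_a, X_b, d_ac, X_d, d_ce), with basis entries given by interval
indicators and exponential decay weights — an NB generalized linear model
with log link.  The Fisher information of a design is then
IM = sum_t w_t x_t x_t', with GLM weight w_t = m_t / (1 + eps * m_t), and
the expected-information-gain utility is approximated by

    g(T) = mean_j sum_k (n_k / N) log det(IM_k(Theta_j, T) + r I)

over samples Theta_j from the prior (a posterior fitted to pilot data),
with occupancy weights n_k/N and a small ridge r so that designs smaller
than the parameter count remain comparable during greedy growth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DataError
from .io_data import CountsDataset, PerturbationSchedule, restrict_to_days
from .mixture import (
    McmcConfig,
    PosteriorSamples,
    posterior_mean_counts,
    run_mcmc,
)
from .signatures import PrototypeSignature, evaluate_signature


@dataclass(frozen=True)
class Design:
    """A set of sampling days within the study range."""

    times: tuple[float, ...]
    budget: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", tuple(sorted(float(t) for t in self.times)))
        if len(self.times) > self.budget:
            raise ConfigError("design exceeds its budget")


@dataclass
class PriorSampleSet:
    """Model configurations drawn from a fitted posterior.

    Each entry carries the active signatures, their occupancy weights and the
    dispersion parameters — enough to evaluate mean counts at any day.
    """

    entries: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.entries:
            raise DataError("prior sample set must be non-empty")

    @classmethod
    def from_posterior(cls, samples: PosteriorSamples, n: int = 500) -> "PriorSampleSet":
        """Uniformly thin the pooled posterior to ``n`` prior samples."""
        thinned = samples.thin_to(n)
        entries = []
        for d in thinned.draws:
            occ = np.bincount(d.z, minlength=d.n_signatures).astype(float)
            entries.append(
                {
                    "signatures": list(d.signatures),
                    "weights": occ / occ.sum(),
                    "eps1": d.eps1,
                    "eps2": d.eps2,
                }
            )
        return cls(entries)


# ---------------------------------------------------------------------------
# information matrices


def glm_basis(
    theta: PrototypeSignature, times, schedule: PerturbationSchedule
) -> np.ndarray:
    """Design-matrix rows x_t of the conditionally linear trajectory model.

    Columns correspond to the active level parameters in the order
    (mu_a, X_b, [d_ac], X_d, [d_ce]); increment columns are present only
    when the corresponding switch is on.
    """
    times = np.atleast_1d(np.asarray(times, float))
    iv = schedule.interval_indices(times)
    c0 = schedule.boundaries[2][0]
    e0 = schedule.boundaries[4][0]
    cols = ["mu_a", "X_b"] + (["d_ac"] if theta.c_mu[0] else []) + ["X_d"] + (
        ["d_ce"] if theta.c_mu[1] else []
    )
    idx = {c: i for i, c in enumerate(cols)}
    X = np.zeros((len(times), len(cols)))
    for row, (t, i) in enumerate(zip(times, iv)):
        if i == 0:
            X[row, idx["mu_a"]] = 1.0
        elif i == 1:
            X[row, idx["X_b"]] = 1.0
        elif i == 2:
            w = np.exp(-(t - c0) / theta.lambda_c)
            X[row, idx["mu_a"]] = 1.0 - w
            X[row, idx["X_b"]] = w
            if theta.c_mu[0]:
                X[row, idx["d_ac"]] = 1.0 - w
        elif i == 3:
            X[row, idx["X_d"]] = 1.0
        else:
            v = np.exp(-(t - e0) / theta.lambda_e)
            X[row, idx["mu_a"]] = 1.0 - v
            X[row, idx["X_d"]] = v
            if theta.c_mu[0]:
                X[row, idx["d_ac"]] = 1.0 - v
            if theta.c_mu[1]:
                X[row, idx["d_ce"]] = 1.0 - v
    return X


def _glm_weights(
    theta: PrototypeSignature,
    times,
    schedule: PerturbationSchedule,
    eps1: float,
    eps2: float,
    gamma: float = 0.0,
    phi=None,
) -> np.ndarray:
    times = np.atleast_1d(np.asarray(times, float))
    phi = np.zeros_like(times) if phi is None else np.asarray(phi, float)
    f = np.asarray(evaluate_signature(theta, times, schedule))
    m = np.exp(f + gamma + phi)
    iv = schedule.interval_indices(times)
    eps = np.where(np.isin(iv, (1, 3)), eps2, eps1)
    return m / (1.0 + eps * m)


def nb_glm_fisher_information(
    theta: PrototypeSignature,
    design: Design | np.ndarray,
    schedule: PerturbationSchedule,
    eps1: float = 0.0,
    eps2: float = 0.0,
    gamma: float = 0.0,
    phi=None,
) -> np.ndarray:
    """Fisher information of a design for one signature's level parameters.

    Symmetric positive semidefinite and additive over disjoint designs; in
    the Poisson limit (eps = 0) the weights reduce to the means m_t.
    """
    times = np.asarray(design.times if isinstance(design, Design) else design, float)
    if times.size == 0:
        raise DataError("design is empty")
    X = glm_basis(theta, times, schedule)
    w = _glm_weights(theta, times, schedule, eps1, eps2, gamma, phi)
    return (X * w[:, None]).T @ X


# ---------------------------------------------------------------------------
# D-optimality


def bayesian_d_optimality(
    design: Design | np.ndarray,
    prior_samples: PriorSampleSet,
    schedule: PerturbationSchedule,
    ridge: float = 1e-6,
    phi=None,
) -> float:
    """Monte-Carlo D-optimality utility g of a design.

    Occupancy-weighted average log-determinant of the per-signature
    information matrices (plus ridge), averaged over the prior samples.
    Permutation-invariant in the design points and monotone non-decreasing
    under design supersets at fixed ridge.
    """
    times = np.asarray(design.times if isinstance(design, Design) else design, float)
    if times.size == 0:
        raise DataError("design is empty")
    total = 0.0
    for entry in prior_samples.entries:
        for sig, wt in zip(entry["signatures"], entry["weights"]):
            im = nb_glm_fisher_information(
                sig, times, schedule, entry["eps1"], entry["eps2"], phi=phi
            )
            sign, logdet = np.linalg.slogdet(im + ridge * np.eye(im.shape[0]))
            total += wt * logdet
    return total / len(prior_samples.entries)


def greedy_design(
    candidates,
    budget: int,
    prior_samples: PriorSampleSet,
    schedule: PerturbationSchedule,
    ridge: float = 1e-6,
) -> tuple[Design, list[float]]:
    """Forward-greedy D-optimal design; deterministic, earliest-day tie-break.

    Returns the design together with the utility value after each addition.
    """
    if budget <= 0:
        raise ConfigError("design budget must be positive")
    cand = sorted(set(float(t) for t in np.atleast_1d(np.asarray(candidates, float))))
    if len(cand) < budget:
        raise DataError("fewer candidate days than the budget")

    # precompute basis rows and weights per (sample, signature, candidate)
    pre = []
    for entry in prior_samples.entries:
        for sig, wt in zip(entry["signatures"], entry["weights"]):
            X = glm_basis(sig, cand, schedule)
            w = _glm_weights(sig, cand, schedule, entry["eps1"], entry["eps2"])
            d = X.shape[1]
            pre.append({"X": X, "w": w, "wt": wt, "im": np.zeros((d, d)),
                        "eye": np.eye(d)})
    n_entries = len(prior_samples.entries)

    chosen: list[float] = []
    remaining = list(range(len(cand)))
    g_path: list[float] = []
    while len(chosen) < budget:
        gains = np.zeros(len(remaining))
        for item in pre:
            X, w = item["X"][remaining], item["w"][remaining]
            ims = (
                item["im"][None, :, :]
                + ridge * item["eye"][None, :, :]
                + w[:, None, None] * X[:, :, None] * X[:, None, :]
            )
            _, logdets = np.linalg.slogdet(ims)
            gains += item["wt"] * logdets
        gains /= n_entries
        best = int(np.argmax(gains))        # remaining is day-sorted: earliest wins ties
        j = remaining.pop(best)
        chosen.append(cand[j])
        g_path.append(float(gains[best]))
        for item in pre:
            x, w = item["X"][j], item["w"][j]
            item["im"] += w * np.outer(x, x)
    return Design(times=tuple(chosen), budget=budget), g_path


def _greedy_cover(cand: list[float], lo: float, hi: float, g: float) -> list[float] | None:
    """Fewest grid days so no gap (incl. to the range ends) exceeds ``g``."""
    pts: list[float] = []
    cur = lo
    while hi - cur > g:
        feas = [c for c in cand if c <= cur + g and (not pts or c > pts[-1])]
        if not feas:
            return None
        pts.append(max(feas))
        cur = pts[-1]
    return pts


def dispersed_design(study_range, budget: int, candidates=None) -> Design:
    """Days spread as evenly as possible over the study range.

    Without a candidate grid this is ``budget`` uniformly spaced days
    including both endpoints.  With a grid, the selected subset minimizes the
    maximum gap (between consecutive days and to the range ends) among all
    grid-feasible subsets of the budget size; leftover budget is filled with
    the earliest unused grid days.
    """
    if budget < 2:
        raise ConfigError("dispersed design needs a budget of at least 2")
    lo, hi = float(study_range[0]), float(study_range[1])
    if candidates is None:
        return Design(times=tuple(np.linspace(lo, hi, budget)), budget=budget)
    cand = sorted(set(float(t) for t in np.atleast_1d(np.asarray(candidates, float))))
    if len(cand) < budget:
        raise DataError("fewer candidate days than the budget")
    # achievable max-gap values are distances between grid days / range ends
    knots = [lo, hi] + cand
    gaps = sorted({abs(a - b) for a in knots for b in knots if a != b})
    chosen = None
    for g in gaps:  # smallest feasible gap wins
        pts = _greedy_cover(cand, lo, hi, g)
        if pts is not None and len(pts) <= budget:
            chosen = pts
            break
    if chosen is None:  # degenerate range; take the earliest days
        chosen = []
    for c in cand:      # pad up to the budget with unused earliest days
        if len(chosen) >= budget:
            break
        if c not in chosen:
            chosen.append(c)
    return Design(times=tuple(sorted(chosen[:budget])), budget=budget)


# ---------------------------------------------------------------------------
# evaluation and strategies


def rmse(actual, predicted) -> float:
    a = np.asarray(actual, float).ravel()
    p = np.asarray(predicted, float).ravel()
    return float(np.sqrt(np.mean((a - p) ** 2)))


def evaluate_design_rmse(
    training_data: CountsDataset,
    design: Design,
    heldout_data: CountsDataset,
    schedules,
    mcmc_config: McmcConfig | None = None,
    hyper=None,
) -> float:
    """Held-out RMSE of a model fitted on the design's sampling days only.

    Predictions are posterior means of m_sot at the held-out days; RMSE is
    the root of the squared prediction error averaged over all refOTUs and
    held-out time-points across subjects.
    """
    for s in heldout_data.subjects:
        if len(heldout_data.times[s]) == 0:
            raise DataError(f"subject {s}: no held-out time-points")
        overlap = set(heldout_data.times[s]) & set(design.times)
        if overlap:
            raise DataError(f"held-out days {sorted(overlap)} overlap the design")
    restricted = restrict_to_days(
        training_data, {s: np.asarray(design.times) for s in training_data.subjects}
    )
    samples = run_mcmc(restricted, schedules, mcmc_config, hyper)
    sq_sum, n_cells = 0.0, 0
    for s in heldout_data.subjects:
        log_tot_train = np.log(np.asarray(restricted.totals[s], float))
        phi_held = np.log(np.asarray(heldout_data.totals[s], float)) - log_tot_train.mean()
        pred = posterior_mean_counts(samples, schedules, s, heldout_data.times[s], phi_held)
        diff = heldout_data.counts[s] - pred
        sq_sum += float(np.sum(diff**2))
        n_cells += diff.size
    return float(np.sqrt(sq_sum / n_cells))


STRATEGIES = ("sequential", "cross_subject", "dispersed")


def design_strategy(
    strategy: str,
    budget: int,
    candidates,
    target_schedule: PerturbationSchedule,
    data: CountsDataset | None = None,
    schedules=None,
    mcmc_config: McmcConfig | None = None,
    hyper=None,
    n_prior_samples: int = 500,
    ridge: float = 1e-6,
) -> Design:
    """Produce a design via one of the three study strategies.

    ``sequential`` fits the model to partial data from the target subject;
    ``cross_subject`` fits to full data from a different subject; both then
    run the greedy D-optimal search with prior samples thinned from that
    posterior.  ``dispersed`` ignores all data and spreads the budget evenly.
    """
    if strategy not in STRATEGIES:
        raise ConfigError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    if strategy == "dispersed":
        return dispersed_design(
            (target_schedule.start, target_schedule.end), budget, candidates
        )
    if data is None or schedules is None:
        raise ConfigError(f"strategy {strategy!r} requires pilot data and schedules")
    samples = run_mcmc(data, schedules, mcmc_config, hyper)
    pset = PriorSampleSet.from_posterior(samples, n_prior_samples)
    design, _ = greedy_design(candidates, budget, pset, target_schedule, ridge)
    return design
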