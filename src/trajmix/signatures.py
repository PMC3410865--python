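"""Generative model for prototype signatures.

A prototype signature is a latent log-amplitude trajectory f(t, theta)
defined piecewise over the five perturbation-delimited intervals: constant
at the pre-treatment equilibrium level mu_a on interval a, constant at the
transient levels X_b / X_d during the two antibiotic pulses, and an
exponential relaxation on the post-pulse intervals c and e — starting from
the preceding transient level and approaching an equilibrium level with an
e-folding relaxation time lambda (in days), measured on the log scale.

Dependencies between interval parameters follow a random walk: X_b is a
normal increment from mu_a, mu_c = mu_a + delta_ac, X_d an increment from
mu_c, mu_e = mu_c + delta_ce.  Two binary "dimensionality switches" c_mu
activate the equilibrium-level increments (delta_ac, delta_ce) and one
switch c_lambda frees lambda_e from lambda_c; with a switch off the
corresponding parameters are tied exactly, so a signature uses between one
and three distinct equilibrium levels and one or two relaxation times.

Counts are negative binomial with mean m = exp(f + gamma_so + phi_st)
(log link) and inverse shape eps (Var = m + eps * m^2): eps1 on the
unperturbed intervals a, c, e and eps2 during the pulses b, d.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import gammaln
from scipy.stats import norm

from .errors import DataError, NumericalError
from .io_data import PerturbationSchedule

_LOG_SEVEN = float(np.log(7.0))


@dataclass
class PrototypeSignature:
    """Parameters theta_k of one prototype signature.

    ``d_ac`` / ``d_ce`` are the random-walk increments giving
    ``mu_c = mu_a + d_ac`` and ``mu_e = mu_c + d_ce``; they must be exactly 0
    while the corresponding switch is off.  ``c_mu`` holds the two
    equilibrium-level switches (a->c, c->e) and ``c_lambda`` the
    relaxation-time switch (lambda_e distinct from lambda_c).
    """

    mu_a: float = 0.0
    X_b: float = 0.0
    X_d: float = 0.0
    d_ac: float = 0.0
    d_ce: float = 0.0
    lambda_c: float = 7.0
    lambda_e: float = 7.0
    c_mu: tuple[bool, bool] = (False, False)
    c_lambda: bool = False

    def __post_init__(self) -> None:
        if self.lambda_c <= 0 or self.lambda_e <= 0:
            raise DataError("relaxation times must be positive")
        if not self.c_mu[0] and self.d_ac != 0.0:
            raise DataError("inactive a->c increment must be zero")
        if not self.c_mu[1] and self.d_ce != 0.0:
            raise DataError("inactive c->e increment must be zero")
        if not self.c_lambda and self.lambda_e != self.lambda_c:
            raise DataError("lambda_e must equal lambda_c while its switch is off")

    # -- effective (tied) values ------------------------------------------
    @property
    def mu_c(self) -> float:
        return self.mu_a + (self.d_ac if self.c_mu[0] else 0.0)

    @property
    def mu_e(self) -> float:
        return self.mu_c + (self.d_ce if self.c_mu[1] else 0.0)

    def to_json(self) -> str:
        d = asdict(self)
        d["c_mu"] = list(d["c_mu"])
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "PrototypeSignature":
        d = json.loads(s)
        d["c_mu"] = tuple(bool(v) for v in d["c_mu"])
        return cls(**d)


@dataclass
class NoiseParams:
    """Dispersion and per-taxon offsets of the count observation model."""

    eps1: float = 0.36
    eps2: float = 0.72
    gamma_so: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.eps1 < 0 or self.eps2 < 0:
            raise DataError("inverse shape parameters must be non-negative")

    def eps_for_interval(self, interval: int) -> float:
        return self.eps2 if interval in (1, 3) else self.eps1


@dataclass
class Hyperparams:
    """Prior settings; defaults give broad, weakly informative priors.

    ``mu_a_mean`` is usually set by empirical Bayes to the log of the mean
    observed counts per refOTU.  Relaxation times are log-normal with median
    one week; switch-on probability 0.5 leaves the dimensionality decision
    to the data.
    """

    mu_a_mean: float = 5.0
    mu_a_sd: float = 2.0
    delta_sd: float = 1.0          # random-walk increments (X_b, X_d, d_ac, d_ce)
    loglambda_mean: float = _LOG_SEVEN
    loglambda_sd: float = 1.0
    logeps_mean: float = -1.0
    logeps_sd: float = 1.0
    gamma_sd: float = 1.0
    switch_prob: float = 0.5
    alpha_shape: float = 1.0       # DP concentration ~ Gamma(shape, rate)
    alpha_rate: float = 1.0

    def __post_init__(self) -> None:
        for name in ("mu_a_sd", "delta_sd", "loglambda_sd", "logeps_sd", "gamma_sd"):
            if getattr(self, name) <= 0:
                raise DataError(f"{name} must be positive")
        if not 0.0 < self.switch_prob < 1.0:
            raise DataError("switch_prob must lie in (0, 1)")


# ---------------------------------------------------------------------------
# trajectory


def evaluate_signature(
    theta: PrototypeSignature, t, schedule: PerturbationSchedule
) -> float | np.ndarray:
    """Log-amplitude f(t, theta) of a prototype signature at day(s) ``t``.

    Constant on intervals a, b, d; on the post-pulse intervals the value
    relaxes exponentially from the preceding transient level toward the
    interval's equilibrium level.  Continuous at the pulse-to-recovery
    boundaries by construction.
    """
    t_arr = np.atleast_1d(np.asarray(t, float))
    iv = schedule.interval_indices(t_arr)
    out = np.empty_like(t_arr)
    c0 = schedule.boundaries[2][0]
    e0 = schedule.boundaries[4][0]
    mu_c, mu_e = theta.mu_c, theta.mu_e
    for i, (ti, ivi) in enumerate(zip(t_arr, iv)):
        if ivi == 0:
            out[i] = theta.mu_a
        elif ivi == 1:
            out[i] = theta.X_b
        elif ivi == 2:
            out[i] = mu_c + (theta.X_b - mu_c) * np.exp(-(ti - c0) / theta.lambda_c)
        elif ivi == 3:
            out[i] = theta.X_d
        else:
            out[i] = mu_e + (theta.X_d - mu_e) * np.exp(-(ti - e0) / theta.lambda_e)
    return float(out[0]) if np.isscalar(t) or np.asarray(t).ndim == 0 else out


def mean_counts(f_value, gamma_so: float = 0.0, phi_st=0.0):
    """NB mean m_sot = exp(f + gamma_so + phi_st).

    gamma_so scales a refOTU's baseline abundance within a subject; phi_st
    is the read-depth offset, so doubling the total reads doubles m.
    """
    return np.exp(np.asarray(f_value, float) + gamma_so + np.asarray(phi_st, float))


# ---------------------------------------------------------------------------
# negative binomial observation model

_POISSON_EPS = 1e-8


def nb_log_pmf(y, m, eps) -> float | np.ndarray:
    """Log mass of the negative binomial with mean ``m`` and inverse shape ``eps``.

    Parameterized so that E[y] = m and Var[y] = m + eps * m^2; eps -> 0 is
    the Poisson limit (taken exactly for eps below 1e-8, where the
    gamma-function form loses precision).
    """
    y_arr = np.atleast_1d(np.asarray(y))
    m_arr = np.atleast_1d(np.asarray(m, float))
    if np.any(m_arr <= 0):
        raise NumericalError("negative binomial mean must be positive")
    if np.any(y_arr < 0) or not np.all(y_arr == np.floor(y_arr)):
        raise DataError("counts must be non-negative integers")
    y_arr = y_arr.astype(float)
    if eps < 0:
        raise DataError("inverse shape must be non-negative")
    if eps < _POISSON_EPS:
        out = y_arr * np.log(m_arr) - m_arr - gammaln(y_arr + 1.0)
    else:
        r = 1.0 / eps
        out = (
            gammaln(y_arr + r)
            - gammaln(r)
            - gammaln(y_arr + 1.0)
            + r * np.log(r / (r + m_arr))
            + y_arr * np.log(m_arr / (r + m_arr))
        )
    return float(out[0]) if out.size == 1 and np.isscalar(y) else out


# ---------------------------------------------------------------------------
# switch semantics and prior


def effective_parameters(theta: PrototypeSignature) -> dict:
    """Resolve switch ties and report the effective dimensionality.

    Returns the tied equilibrium levels / relaxation times together with the
    number of distinct equilibrium levels (1–3) and relaxation times (1–2)
    the signature actually uses.
    """
    levels = (theta.mu_a, theta.mu_c, theta.mu_e)
    lams = (theta.lambda_c, theta.lambda_e)
    return {
        "mu_a": levels[0],
        "mu_c": levels[1],
        "mu_e": levels[2],
        "lambda_c": lams[0],
        "lambda_e": lams[1],
        "n_equilibrium_levels": len(set(levels)),
        "n_relaxation_times": len(set(lams)),
    }


def _lognorm_logpdf(x: float, mean_log: float, sd_log: float) -> float:
    return float(norm.logpdf(np.log(x), mean_log, sd_log) - np.log(x))


def signature_log_prior(theta: PrototypeSignature, hyper: Hyperparams) -> float:
    """Log prior density of a signature under the random-walk prior.

    Sum of: the pre-treatment level prior, normal increment densities for the
    transients and any active equilibrium increments, log-normal densities
    for the active relaxation times, and Bernoulli switch priors.  Raises if
    an inactive increment is nonzero (inconsistent state).
    """
    # dataclass validation already rejects inactive nonzero increments, but a
    # mutated instance may be inconsistent — re-check.
    if not theta.c_mu[0] and theta.d_ac != 0.0:
        raise DataError("inactive a->c increment must be zero")
    if not theta.c_mu[1] and theta.d_ce != 0.0:
        raise DataError("inactive c->e increment must be zero")
    if not theta.c_lambda and theta.lambda_e != theta.lambda_c:
        raise DataError("lambda_e must equal lambda_c while its switch is off")
    lp = float(norm.logpdf(theta.mu_a, hyper.mu_a_mean, hyper.mu_a_sd))
    lp += float(norm.logpdf(theta.X_b, theta.mu_a, hyper.delta_sd))
    lp += float(norm.logpdf(theta.X_d, theta.mu_c, hyper.delta_sd))
    if theta.c_mu[0]:
        lp += float(norm.logpdf(theta.d_ac, 0.0, hyper.delta_sd))
    if theta.c_mu[1]:
        lp += float(norm.logpdf(theta.d_ce, 0.0, hyper.delta_sd))
    lp += _lognorm_logpdf(theta.lambda_c, hyper.loglambda_mean, hyper.loglambda_sd)
    if theta.c_lambda:
        lp += _lognorm_logpdf(theta.lambda_e, hyper.loglambda_mean, hyper.loglambda_sd)
    p = hyper.switch_prob
    for on in (theta.c_mu[0], theta.c_mu[1], theta.c_lambda):
        lp += float(np.log(p if on else 1.0 - p))
    return lp


def sample_signature_prior(hyper: Hyperparams, rng: np.random.Generator) -> PrototypeSignature:
    """Draw a prototype signature from the prior."""
    s_ac, s_ce, s_lam = rng.random(3) < hyper.switch_prob
    mu_a = rng.normal(hyper.mu_a_mean, hyper.mu_a_sd)
    X_b = rng.normal(mu_a, hyper.delta_sd)
    d_ac = rng.normal(0.0, hyper.delta_sd) if s_ac else 0.0
    mu_c = mu_a + d_ac
    X_d = rng.normal(mu_c, hyper.delta_sd)
    d_ce = rng.normal(0.0, hyper.delta_sd) if s_ce else 0.0
    lam_c = float(np.exp(rng.normal(hyper.loglambda_mean, hyper.loglambda_sd)))
    lam_e = (
        float(np.exp(rng.normal(hyper.loglambda_mean, hyper.loglambda_sd)))
        if s_lam
        else lam_c
    )
    return PrototypeSignature(
        mu_a=float(mu_a), X_b=float(X_b), X_d=float(X_d),
        d_ac=float(d_ac), d_ce=float(d_ce),
        lambda_c=lam_c, lambda_e=lam_e,
        c_mu=(bool(s_ac), bool(s_ce)), c_lambda=bool(s_lam),
    )


def trajectory_table(
    theta: PrototypeSignature, schedule: PerturbationSchedule, n_grid: int = 200
) -> np.ndarray:
    """(day, log-amplitude) pairs on an even grid, for TSV export."""
    grid = np.linspace(schedule.start, schedule.end, n_grid)
    return np.column_stack([grid, evaluate_signature(theta, grid, schedule)])
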