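"""Posterior inference for the Dirichlet-process signature mixture.

Each (subject, refOTU) count series is assigned to a latent prototype
signature shared globally across subjects (one Dirichlet process over all
series — the "combined ecosystem" view required by the cross-subject
diversity and consensus analyses).  Sampling alternates:

* CRP assignment Gibbs updates with auxiliary fresh components (Neal's
  algorithm 8 for non-conjugate DP mixtures);
* random-walk Metropolis updates of each active signature's continuous
  parameters under the random-walk prior;
* reversible-jump toggles of the three dimensionality switches, with birth
  proposals drawn from the prior so the acceptance ratio reduces to a
  likelihood ratio times the switch prior odds (times any prior terms that
  depend on the activated increment downstream);
* Metropolis updates of the per-series offsets gamma_so and the two
  dispersion parameters, and an Escobar–West update of the DP
  concentration alpha.

Proposal scales adapt during burn-in only (target acceptance 0.2–0.5) and
are frozen afterwards, preserving detailed balance for the retained draws.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from .errors import ConfigError, DataError
from .io_data import CountsDataset, PerturbationSchedule, compute_read_depth_offsets
from .signatures import (
    Hyperparams,
    PrototypeSignature,
    sample_signature_prior,
)

_HALF_LOG_2PI = 0.5 * float(np.log(2.0 * np.pi))
_EXP_CLIP = 60.0


def _norm_logpdf(x: float, mean: float, sd: float) -> float:
    z = (x - mean) / sd
    return -0.5 * z * z - np.log(sd) - _HALF_LOG_2PI


# ---------------------------------------------------------------------------
# configuration and posterior containers


@dataclass
class McmcConfig:
    """Chain-management settings.

    ``retained_samples`` is ``n_chains * (n_sampling // thin)`` — e.g. the
    full-scale protocol of 8 chains, 10,000 burn-in and every 10th draw over
    5,000 further iterations pools 4,000 posterior samples.
    """

    n_burnin: int = 2000
    n_sampling: int = 2000
    thin: int = 10
    n_chains: int = 2
    seed: int = 0
    n_aux: int = 3
    adapt_interval: int = 100
    use_likelihood: bool = True
    update_alpha: bool = True
    alpha_init: float = 1.0
    proposal_scales: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_burnin < 0 or self.n_sampling < 0 or self.n_chains < 0:
            raise ConfigError("iteration counts must be non-negative")
        if self.thin < 1:
            raise ConfigError("thin must be >= 1")
        if self.n_aux < 1:
            raise ConfigError("need at least one auxiliary component")

    @property
    def retained_samples(self) -> int:
        return self.n_chains * (self.n_sampling // self.thin)

    @classmethod
    def full_protocol(cls, seed: int = 0) -> "McmcConfig":
        """8 chains x (10,000 burn-in + 5,000 sampling, thin 10) -> 4,000 draws."""
        return cls(n_burnin=10_000, n_sampling=5_000, thin=10, n_chains=8, seed=seed)

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "McmcConfig":
        """2 chains x (2,000 + 2,000, thin 10) -> 400 draws; minutes on a laptop."""
        return cls(n_burnin=2_000, n_sampling=2_000, thin=10, n_chains=2, seed=seed)


@dataclass
class ModelState:
    """One retained draw: active signatures, assignments and nuisance."""

    signatures: list[PrototypeSignature]
    z: np.ndarray               # flat unit index -> signature index
    gamma: np.ndarray
    eps1: float
    eps2: float
    alpha: float
    chain: int = 0
    iteration: int = 0

    @property
    def n_signatures(self) -> int:
        return len(self.signatures)


@dataclass
class PosteriorSamples:
    """Pooled retained MCMC draws plus the unit bookkeeping they refer to."""

    units: list[tuple[str, str]]
    subjects: list[str]
    draws: list[ModelState]

    @property
    def n_draws(self) -> int:
        return len(self.draws)

    @property
    def n_units(self) -> int:
        return len(self.units)

    def subject_mask(self, subject: str) -> np.ndarray:
        return np.array([s == subject for s, _ in self.units])

    def units_per_subject(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s, _ in self.units:
            out[s] = out.get(s, 0) + 1
        return out

    def thin_to(self, n: int) -> "PosteriorSamples":
        """Uniformly thin the pooled draws to at most ``n``."""
        if n >= self.n_draws:
            return self
        idx = np.linspace(0, self.n_draws - 1, n).round().astype(int)
        return PosteriorSamples(self.units, self.subjects, [self.draws[i] for i in idx])

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(json.dumps({"units": self.units, "subjects": self.subjects}) + "\n")
            for d in self.draws:
                rec = {
                    "signatures": [json.loads(sig.to_json()) for sig in d.signatures],
                    "z": d.z.tolist(),
                    "gamma": np.round(d.gamma, 10).tolist(),
                    "eps1": d.eps1,
                    "eps2": d.eps2,
                    "alpha": d.alpha,
                    "chain": d.chain,
                    "iteration": d.iteration,
                }
                fh.write(json.dumps(rec, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path) -> "PosteriorSamples":
        with open(path) as fh:
            header = json.loads(fh.readline())
            draws = []
            for line in fh:
                rec = json.loads(line)
                sigs = [
                    PrototypeSignature(
                        **{**sd, "c_mu": tuple(bool(v) for v in sd["c_mu"])}
                    )
                    for sd in rec["signatures"]
                ]
                draws.append(
                    ModelState(
                        signatures=sigs,
                        z=np.array(rec["z"], int),
                        gamma=np.array(rec["gamma"], float),
                        eps1=rec["eps1"],
                        eps2=rec["eps2"],
                        alpha=rec["alpha"],
                        chain=rec["chain"],
                        iteration=rec["iteration"],
                    )
                )
        return cls(
            units=[tuple(u) for u in header["units"]],
            subjects=header["subjects"],
            draws=draws,
        )


# ---------------------------------------------------------------------------
# internal packed state


class _Theta:
    """Mutable signature parameters in sampling coordinates (log lambda)."""

    __slots__ = ("mu_a", "X_b", "X_d", "d_ac", "d_ce", "loglam_c", "loglam_e",
                 "s_ac", "s_ce", "s_lam")

    def __init__(self, mu_a=0.0, X_b=0.0, X_d=0.0, d_ac=0.0, d_ce=0.0,
                 loglam_c=np.log(7.0), loglam_e=np.log(7.0),
                 s_ac=False, s_ce=False, s_lam=False):
        self.mu_a, self.X_b, self.X_d = mu_a, X_b, X_d
        self.d_ac, self.d_ce = d_ac, d_ce
        self.loglam_c, self.loglam_e = loglam_c, loglam_e
        self.s_ac, self.s_ce, self.s_lam = s_ac, s_ce, s_lam

    @property
    def mu_c(self) -> float:
        return self.mu_a + (self.d_ac if self.s_ac else 0.0)

    @property
    def mu_e(self) -> float:
        return self.mu_c + (self.d_ce if self.s_ce else 0.0)

    @property
    def lam_c(self) -> float:
        return float(np.exp(self.loglam_c))

    @property
    def lam_e(self) -> float:
        return float(np.exp(self.loglam_e)) if self.s_lam else self.lam_c

    def copy(self) -> "_Theta":
        t = _Theta.__new__(_Theta)
        for sl in _Theta.__slots__:
            setattr(t, sl, getattr(self, sl))
        return t

    def to_public(self) -> PrototypeSignature:
        return PrototypeSignature(
            mu_a=float(self.mu_a), X_b=float(self.X_b), X_d=float(self.X_d),
            d_ac=float(self.d_ac) if self.s_ac else 0.0,
            d_ce=float(self.d_ce) if self.s_ce else 0.0,
            lambda_c=self.lam_c, lambda_e=self.lam_e,
            c_mu=(bool(self.s_ac), bool(self.s_ce)), c_lambda=bool(self.s_lam),
        )

    @classmethod
    def from_public(cls, sig: PrototypeSignature) -> "_Theta":
        return cls(
            mu_a=sig.mu_a, X_b=sig.X_b, X_d=sig.X_d,
            d_ac=sig.d_ac, d_ce=sig.d_ce,
            loglam_c=float(np.log(sig.lambda_c)),
            loglam_e=float(np.log(sig.lambda_e)),
            s_ac=sig.c_mu[0], s_ce=sig.c_mu[1], s_lam=sig.c_lambda,
        )


class _Cluster:
    __slots__ = ("theta", "members", "fcache")

    def __init__(self, theta: _Theta):
        self.theta = theta
        self.members: set[int] = set()
        self.fcache: dict[str, np.ndarray] = {}

    def invalidate(self) -> None:
        self.fcache.clear()


class _SubjectData:
    """Per-subject arrays packed for fast likelihood evaluation."""

    __slots__ = ("y", "lnyfact", "phi", "times", "iv", "pulse_mask",
                 "dtc", "dte", "masks", "unit_offset")

    def __init__(self, y, phi, times, schedule: PerturbationSchedule):
        self.y = np.asarray(y, np.int64)
        self.lnyfact = gammaln(self.y + 1.0)
        self.phi = np.asarray(phi, float)
        self.times = np.asarray(times, float)
        iv = schedule.interval_indices(self.times)
        self.iv = iv
        self.pulse_mask = np.isin(iv, (1, 3))
        self.masks = [iv == i for i in range(5)]
        c0 = schedule.boundaries[2][0]
        e0 = schedule.boundaries[4][0]
        self.dtc = np.where(self.masks[2], self.times - c0, 0.0)
        self.dte = np.where(self.masks[4], self.times - e0, 0.0)
        self.unit_offset = 0


def _traj(theta: _Theta, sub: _SubjectData) -> np.ndarray:
    """Signature trajectory on one subject's observation grid."""
    f = np.empty_like(sub.times)
    ma, mb, mc, md, me = sub.masks
    f[ma] = theta.mu_a
    f[mb] = theta.X_b
    mu_c = theta.mu_c
    f[mc] = mu_c + (theta.X_b - mu_c) * np.exp(-sub.dtc[mc] / theta.lam_c)
    f[md] = theta.X_d
    mu_e = theta.mu_e
    f[me] = mu_e + (theta.X_d - mu_e) * np.exp(-sub.dte[me] / theta.lam_e)
    return f


# ---------------------------------------------------------------------------
# the sampler


class GibbsSampler:
    """One MCMC chain over the full latent state.

    Exposes the individual update blocks (``update_assignments``,
    ``update_signatures``, ``update_switches``, ``update_nuisance``) as well
    as a combined ``sweep``; ``snapshot`` captures the current state as a
    :class:`ModelState`.
    """

    def __init__(
        self,
        data: CountsDataset,
        schedules: dict[str, PerturbationSchedule],
        hyper: Hyperparams,
        config: McmcConfig,
        rng: np.random.Generator,
        chain_id: int = 0,
    ):
        if sum(data.counts[s].shape[0] for s in data.subjects) == 0:
            raise DataError("empty dataset: no refOTU series to fit")
        self.hyper = hyper
        self.config = config
        self.rng = rng
        self.chain_id = chain_id
        self.schedules = schedules
        self.subjects = list(data.subjects)
        phi = compute_read_depth_offsets(data)
        self.sub: dict[str, _SubjectData] = {}
        self.units: list[tuple[str, int]] = []
        for s in self.subjects:
            sd = _SubjectData(data.counts[s], phi[s], data.times[s], schedules[s])
            sd.unit_offset = len(self.units)
            self.sub[s] = sd
            self.units.extend((s, o) for o in range(data.counts[s].shape[0]))
        self.unit_names = [
            (s, data.refotus[s][o]) for s, o in self.units
        ]
        self.n_units = len(self.units)

        self.gamma = np.zeros(self.n_units)
        self.eps1 = float(np.exp(hyper.logeps_mean))
        self.eps2 = float(np.exp(hyper.logeps_mean))
        self.alpha = float(config.alpha_init)

        self.scales = {
            "mu_a": 0.25, "X_b": 0.25, "X_d": 0.25, "d_ac": 0.25, "d_ce": 0.25,
            "loglam_c": 0.4, "loglam_e": 0.4, "gamma": 0.2, "logeps": 0.3,
        }
        self.scales.update(config.proposal_scales)
        self._acc: dict[str, list[int]] = {k: [0, 0] for k in self.scales}
        self._adapting = False
        self._sweeps_done = 0

        self.clusters: list[_Cluster] = []
        self.z = np.full(self.n_units, -1, int)
        self._init_state()

    # -- initialisation ---------------------------------------------------
    def _init_state(self) -> None:
        if not self.config.use_likelihood:
            cl = _Cluster(_Theta.from_public(sample_signature_prior(self.hyper, self.rng)))
            cl.members = set(range(self.n_units))
            self.clusters = [cl]
            self.z[:] = 0
            return
        # one singleton cluster per unit, seeded from empirical interval means
        for u, (s, o) in enumerate(self.units):
            sd = self.sub[s]
            f0 = np.log(sd.y[o] + 0.5) - sd.phi
            th = _Theta()
            th.mu_a = float(f0[sd.masks[0]].mean()) if sd.masks[0].any() else float(f0.mean())
            th.X_b = float(f0[sd.masks[1]].mean()) if sd.masks[1].any() else th.mu_a
            th.X_d = float(f0[sd.masks[3]].mean()) if sd.masks[3].any() else th.mu_a
            for mask, which in ((sd.masks[2], "ac"), (sd.masks[4], "ce")):
                if mask.any():
                    tail = f0[mask][len(f0[mask]) // 2:]
                    level = float(tail.mean())
                else:
                    level = th.mu_a
                if which == "ac":
                    d = level - th.mu_a
                    if abs(d) > 0.5:
                        th.s_ac, th.d_ac = True, d
                else:
                    d = level - th.mu_c
                    if abs(d) > 0.5:
                        th.s_ce, th.d_ce = True, d
            # the relaxation-time switch has no cheap empirical proxy; start
            # at its prior with the two constants tied
            if self.rng.random() < self.hyper.switch_prob:
                th.s_lam = True
            cl = _Cluster(th)
            cl.members.add(u)
            self.z[u] = len(self.clusters)
            self.clusters.append(cl)

    # -- likelihood helpers ----------------------------------------------
    def _r_vec(self, sub: _SubjectData) -> np.ndarray:
        return np.where(sub.pulse_mask, 1.0 / self.eps2, 1.0 / self.eps1)

    def _cluster_f(self, cl: _Cluster, s: str) -> np.ndarray:
        f = cl.fcache.get(s)
        if f is None:
            f = _traj(cl.theta, self.sub[s])
            cl.fcache[s] = f
        return f

    def _score_unit(self, u: int, f: np.ndarray) -> float:
        """Signature-dependent part of the NB log-likelihood of one series."""
        if not self.config.use_likelihood:
            return 0.0
        s, o = self.units[u]
        sd = self.sub[s]
        a = np.clip(f + self.gamma[u] + sd.phi, -_EXP_CLIP, _EXP_CLIP)
        r = self._r_vec(sd)
        y = sd.y[o]
        return float(np.sum(y * a - (y + r) * np.log(r + np.exp(a))))

    def _score_unit_multi(self, u: int, F: np.ndarray) -> np.ndarray:
        """Scores of one series under several candidate signatures (rows of F)."""
        if not self.config.use_likelihood:
            return np.zeros(F.shape[0])
        s, o = self.units[u]
        sd = self.sub[s]
        a = np.clip(F + (self.gamma[u] + sd.phi)[None, :], -_EXP_CLIP, _EXP_CLIP)
        r = self._r_vec(sd)[None, :]
        y = sd.y[o][None, :]
        return np.sum(y * a - (y + r) * np.log(r + np.exp(a)), axis=1)

    def _score_cluster(self, cl: _Cluster, theta: _Theta) -> float:
        """Joint score of a cluster's members under candidate parameters."""
        if not self.config.use_likelihood:
            return 0.0
        total = 0.0
        by_subject: dict[str, list[int]] = {}
        for u in cl.members:
            by_subject.setdefault(self.units[u][0], []).append(u)
        for s, us in by_subject.items():
            sd = self.sub[s]
            f = _traj(theta, sd)
            rows = [self.units[u][1] for u in us]
            g = self.gamma[us]
            a = np.clip(f[None, :] + g[:, None] + sd.phi[None, :], -_EXP_CLIP, _EXP_CLIP)
            r = self._r_vec(sd)[None, :]
            y = sd.y[rows]
            total += float(np.sum(y * a - (y + r) * np.log(r + np.exp(a))))
        return total

    def _full_loglik(self, eps1: float, eps2: float) -> float:
        """Complete NB log-likelihood of all data (used for dispersion updates)."""
        if not self.config.use_likelihood:
            return 0.0
        total = 0.0
        for s in self.subjects:
            sd = self.sub[s]
            O = sd.y.shape[0]
            F = np.empty_like(sd.y, dtype=float)
            for u in range(sd.unit_offset, sd.unit_offset + O):
                o = self.units[u][1]
                F[o] = self._cluster_f(self.clusters[self.z[u]], s) + self.gamma[u]
            a = np.clip(F + sd.phi[None, :], -_EXP_CLIP, _EXP_CLIP)
            m = np.exp(a)
            r = np.where(sd.pulse_mask, 1.0 / eps2, 1.0 / eps1)[None, :]
            y = sd.y
            total += float(
                np.sum(
                    gammaln(y + r) - gammaln(r) - sd.lnyfact
                    + r * np.log(r / (r + m)) + y * (a - np.log(r + m))
                )
            )
        return total

    # -- priors -----------------------------------------------------------
    def _theta_log_prior(self, th: _Theta) -> float:
        """Prior density in sampling coordinates (log-lambda space)."""
        h = self.hyper
        lp = _norm_logpdf(th.mu_a, h.mu_a_mean, h.mu_a_sd)
        lp += _norm_logpdf(th.X_b, th.mu_a, h.delta_sd)
        lp += _norm_logpdf(th.X_d, th.mu_c, h.delta_sd)
        if th.s_ac:
            lp += _norm_logpdf(th.d_ac, 0.0, h.delta_sd)
        if th.s_ce:
            lp += _norm_logpdf(th.d_ce, 0.0, h.delta_sd)
        lp += _norm_logpdf(th.loglam_c, h.loglambda_mean, h.loglambda_sd)
        if th.s_lam:
            lp += _norm_logpdf(th.loglam_e, h.loglambda_mean, h.loglambda_sd)
        p = h.switch_prob
        for on in (th.s_ac, th.s_ce, th.s_lam):
            lp += float(np.log(p if on else 1.0 - p))
        return float(lp)

    def _sample_theta_prior(self) -> _Theta:
        h, rng = self.hyper, self.rng
        sw = rng.random(3) < h.switch_prob
        th = _Theta()
        th.s_ac, th.s_ce, th.s_lam = bool(sw[0]), bool(sw[1]), bool(sw[2])
        th.mu_a = float(rng.normal(h.mu_a_mean, h.mu_a_sd))
        th.X_b = float(rng.normal(th.mu_a, h.delta_sd))
        th.d_ac = float(rng.normal(0.0, h.delta_sd)) if th.s_ac else 0.0
        th.X_d = float(rng.normal(th.mu_c, h.delta_sd))
        th.d_ce = float(rng.normal(0.0, h.delta_sd)) if th.s_ce else 0.0
        th.loglam_c = float(rng.normal(h.loglambda_mean, h.loglambda_sd))
        th.loglam_e = (
            float(rng.normal(h.loglambda_mean, h.loglambda_sd)) if th.s_lam else th.loglam_c
        )
        return th

    # -- update blocks ----------------------------------------------------
    def update_assignments(self) -> None:
        """CRP Gibbs sweep with ``n_aux`` auxiliary fresh components."""
        m_aux = self.config.n_aux
        log_alpha_frac = np.log(self.alpha / m_aux)
        for u in range(self.n_units):
            s = self.units[u][0]
            sd = self.sub[s]
            old = self.z[u]
            self.clusters[old].members.discard(u)
            orphan = None
            if not self.clusters[old].members:
                orphan = self.clusters.pop(old)
                self.z[self.z > old] -= 1
                self.z[u] = -1
            K = len(self.clusters)
            aux = [orphan.theta if (orphan is not None and j == 0) else None
                   for j in range(m_aux)]
            aux = [t if t is not None else self._sample_theta_prior() for t in aux]
            F = np.empty((K + m_aux, len(sd.times)))
            for k, cl in enumerate(self.clusters):
                F[k] = self._cluster_f(cl, s)
            for j, th in enumerate(aux):
                F[K + j] = _traj(th, sd)
            scores = self._score_unit_multi(u, F)
            logw = np.empty(K + m_aux)
            for k, cl in enumerate(self.clusters):
                logw[k] = np.log(len(cl.members)) + scores[k]
            logw[K:] = log_alpha_frac + scores[K:]
            logw -= logw.max()
            w = np.exp(logw)
            pick = int(self.rng.choice(len(w), p=w / w.sum()))
            if pick >= K:
                cl = _Cluster(aux[pick - K])
                self.clusters.append(cl)
                pick = K
            self.clusters[pick].members.add(u)
            self.z[u] = pick

    def _mh_param(self, cl: _Cluster, name: str, cur_score: float) -> float:
        scale = self.scales[name]
        th_new = cl.theta.copy()
        step = float(self.rng.normal(0.0, scale)) if scale > 0 else 0.0
        setattr(th_new, name, getattr(th_new, name) + step)
        if name == "loglam_c" and not th_new.s_lam:
            th_new.loglam_e = th_new.loglam_c   # keep the tie
        new_score = self._score_cluster(cl, th_new) if step != 0.0 else cur_score
        log_acc = (new_score + self._theta_log_prior(th_new)) - (
            cur_score + self._theta_log_prior(cl.theta)
        )
        self._acc[name][1] += 1
        if np.log(self.rng.random()) < log_acc:
            self._acc[name][0] += 1
            cl.theta = th_new
            cl.invalidate()
            return new_score
        return cur_score

    def update_signatures(self) -> None:
        """Random-walk Metropolis on every active signature's parameters."""
        for cl in self.clusters:
            cur = self._score_cluster(cl, cl.theta)
            for name in ("mu_a", "X_b", "X_d", "loglam_c"):
                cur = self._mh_param(cl, name, cur)
            if cl.theta.s_ac:
                cur = self._mh_param(cl, "d_ac", cur)
            if cl.theta.s_ce:
                cur = self._mh_param(cl, "d_ce", cur)
            if cl.theta.s_lam:
                cur = self._mh_param(cl, "loglam_e", cur)

    def _toggle(self, cl: _Cluster, which: str, cur_score: float) -> float:
        h = self.hyper
        th_new = cl.theta.copy()
        log_prop = 0.0          # proposal density of birth draws
        if which == "ac":
            if th_new.s_ac:
                th_new.s_ac, th_new.d_ac = False, 0.0
                log_prop = -_norm_logpdf(cl.theta.d_ac, 0.0, h.delta_sd)
            else:
                th_new.s_ac = True
                th_new.d_ac = float(self.rng.normal(0.0, h.delta_sd))
                log_prop = _norm_logpdf(th_new.d_ac, 0.0, h.delta_sd)
        elif which == "ce":
            if th_new.s_ce:
                th_new.s_ce, th_new.d_ce = False, 0.0
                log_prop = -_norm_logpdf(cl.theta.d_ce, 0.0, h.delta_sd)
            else:
                th_new.s_ce = True
                th_new.d_ce = float(self.rng.normal(0.0, h.delta_sd))
                log_prop = _norm_logpdf(th_new.d_ce, 0.0, h.delta_sd)
        else:
            # mixture birth proposal: half from the prior, half near the
            # current shared constant — a sharply peaked member likelihood
            # would otherwise make births essentially never accepted
            def log_q(x, loglam_c):
                return float(np.logaddexp(
                    np.log(0.5) + _norm_logpdf(x, h.loglambda_mean, h.loglambda_sd),
                    np.log(0.5) + _norm_logpdf(x, loglam_c, 0.3),
                ))

            if th_new.s_lam:
                th_new.s_lam = False
                th_new.loglam_e = th_new.loglam_c
                log_prop = -log_q(cl.theta.loglam_e, cl.theta.loglam_c)
            else:
                th_new.s_lam = True
                if self.rng.random() < 0.5:
                    th_new.loglam_e = float(
                        self.rng.normal(h.loglambda_mean, h.loglambda_sd)
                    )
                else:
                    th_new.loglam_e = float(self.rng.normal(th_new.loglam_c, 0.3))
                log_prop = log_q(th_new.loglam_e, th_new.loglam_c)
        new_score = self._score_cluster(cl, th_new)
        log_acc = (new_score + self._theta_log_prior(th_new)) - (
            cur_score + self._theta_log_prior(cl.theta)
        ) - log_prop
        if np.log(self.rng.random()) < log_acc:
            cl.theta = th_new
            cl.invalidate()
            return new_score
        return cur_score

    def update_switches(self) -> None:
        """Reversible-jump toggles of the three dimensionality switches."""
        for cl in self.clusters:
            cur = self._score_cluster(cl, cl.theta)
            for which in ("ac", "ce", "lam"):
                cur = self._toggle(cl, which, cur)

    def update_nuisance(self) -> None:
        """Metropolis updates of gamma_so and dispersions; Escobar–West alpha."""
        h = self.hyper
        scale = self.scales["gamma"]
        for u in range(self.n_units):
            s = self.units[u][0]
            f = self._cluster_f(self.clusters[self.z[u]], s)
            step = float(self.rng.normal(0.0, scale)) if scale > 0 else 0.0
            g_old, g_new = self.gamma[u], self.gamma[u] + step
            cur = self._score_unit(u, f)
            self.gamma[u] = g_new
            new = self._score_unit(u, f) if step != 0.0 else cur
            log_acc = (new + _norm_logpdf(g_new, 0.0, h.gamma_sd)) - (
                cur + _norm_logpdf(g_old, 0.0, h.gamma_sd)
            )
            self._acc["gamma"][1] += 1
            if np.log(self.rng.random()) < log_acc:
                self._acc["gamma"][0] += 1
            else:
                self.gamma[u] = g_old

        # dispersions: log-scale random walk
        cur_ll = self._full_loglik(self.eps1, self.eps2)
        for attr in ("eps1", "eps2"):
            e_old = getattr(self, attr)
            step = (
                float(self.rng.normal(0.0, self.scales["logeps"]))
                if self.scales["logeps"] > 0 else 0.0
            )
            e_new = float(np.exp(np.log(e_old) + step))
            new_ll = (
                self._full_loglik(e_new if attr == "eps1" else self.eps1,
                                  e_new if attr == "eps2" else self.eps2)
                if step != 0.0 else cur_ll
            )
            log_acc = (new_ll + _norm_logpdf(np.log(e_new), h.logeps_mean, h.logeps_sd)) - (
                cur_ll + _norm_logpdf(np.log(e_old), h.logeps_mean, h.logeps_sd)
            )
            self._acc["logeps"][1] += 1
            if np.log(self.rng.random()) < log_acc:
                self._acc["logeps"][0] += 1
                setattr(self, attr, e_new)
                cur_ll = new_ll

        if self.config.update_alpha:
            self.alpha = self._sample_alpha()

    def _sample_alpha(self) -> float:
        """Escobar–West auxiliary-variable update of the DP concentration."""
        a, b = self.hyper.alpha_shape, self.hyper.alpha_rate
        k, n = len(self.clusters), self.n_units
        eta = float(self.rng.beta(self.alpha + 1.0, n))
        odds = (a + k - 1.0) / (n * (b - np.log(eta)))
        shape = a + k if self.rng.random() < odds / (1.0 + odds) else a + k - 1.0
        shape = max(shape, 1e-3)
        return float(self.rng.gamma(shape, 1.0 / (b - np.log(eta))))

    # -- chain management -------------------------------------------------
    def sweep(self) -> None:
        self.update_assignments()
        self.update_signatures()
        self.update_switches()
        self.update_nuisance()
        self._sweeps_done += 1
        if self._adapting and self._sweeps_done % self.config.adapt_interval == 0:
            self._adapt()

    def _adapt(self) -> None:
        for name, (acc, tot) in self._acc.items():
            if tot == 0:
                continue
            rate = acc / tot
            if rate > 0.5:
                self.scales[name] *= 1.4
            elif rate < 0.2:
                self.scales[name] /= 1.4
            self._acc[name] = [0, 0]

    def acceptance_rates(self) -> dict[str, float]:
        return {k: (a / t if t else float("nan")) for k, (a, t) in self._acc.items()}

    def run(self) -> list[ModelState]:
        cfg = self.config
        self._adapting = True
        for _ in range(cfg.n_burnin):
            self.sweep()
        self._adapting = False
        draws = []
        for it in range(1, cfg.n_sampling + 1):
            self.sweep()
            if it % cfg.thin == 0:
                draws.append(self.snapshot(iteration=it))
        return draws

    def snapshot(self, iteration: int = 0) -> ModelState:
        order = sorted(range(len(self.clusters)),
                       key=lambda k: min(self.clusters[k].members))
        relabel = {old: new for new, old in enumerate(order)}
        sigs = [self.clusters[old].theta.to_public() for old in order]
        z = np.array([relabel[self.z[u]] for u in range(self.n_units)], int)
        return ModelState(
            signatures=sigs,
            z=z,
            gamma=self.gamma.copy(),
            eps1=self.eps1,
            eps2=self.eps2,
            alpha=self.alpha,
            chain=self.chain_id,
            iteration=iteration,
        )

    # -- data resimulation (joint-distribution sampler checks) ------------
    def resample_counts(self) -> None:
        """Redraw all counts from the current state (posterior-predictive step)."""
        for s in self.subjects:
            sd = self.sub[s]
            r = self._r_vec(sd)
            for u in range(sd.unit_offset, sd.unit_offset + sd.y.shape[0]):
                o = self.units[u][1]
                f = self._cluster_f(self.clusters[self.z[u]], s)
                m = np.exp(np.clip(f + self.gamma[u] + sd.phi, -_EXP_CLIP, _EXP_CLIP))
                sd.y[o] = self.rng.negative_binomial(r, r / (r + m))
            sd.lnyfact = gammaln(sd.y + 1.0)


# ---------------------------------------------------------------------------
# module-level operations


def crp_assignment_update(sampler: GibbsSampler) -> GibbsSampler:
    sampler.update_assignments()
    return sampler


def update_signature_parameters(sampler: GibbsSampler) -> GibbsSampler:
    sampler.update_signatures()
    return sampler


def toggle_dimension_switches(sampler: GibbsSampler) -> GibbsSampler:
    sampler.update_switches()
    return sampler


def update_nuisance(sampler: GibbsSampler) -> GibbsSampler:
    sampler.update_nuisance()
    return sampler


def _as_schedule_dict(schedules, subjects) -> dict[str, PerturbationSchedule]:
    if isinstance(schedules, PerturbationSchedule):
        return {s: schedules for s in subjects}
    return dict(schedules)


def empirical_hyperparams(data: CountsDataset, **overrides) -> Hyperparams:
    """Default hyperparameters with the baseline level set by empirical Bayes.

    The prior mean of the pre-treatment level is the log of the mean observed
    count per refOTU series.
    """
    means = np.concatenate([data.counts[s].mean(axis=1) for s in data.subjects])
    eta = float(np.log(max(means.mean(), 0.5)))
    return Hyperparams(mu_a_mean=overrides.pop("mu_a_mean", eta), **overrides)


def run_mcmc(
    data: CountsDataset,
    schedules,
    config: McmcConfig | None = None,
    hyper: Hyperparams | None = None,
) -> PosteriorSamples:
    """Run independent chains and pool retained draws.

    Every source of randomness derives from ``config.seed`` via spawned
    generator streams, so identical seeds give bit-identical samples.
    """
    config = config or McmcConfig()
    sched = _as_schedule_dict(schedules, data.subjects)
    hyper = hyper or empirical_hyperparams(data)
    draws: list[ModelState] = []
    units = None
    for c, ss in enumerate(np.random.SeedSequence(config.seed).spawn(config.n_chains)):
        sampler = GibbsSampler(
            data, sched, hyper, config, np.random.Generator(np.random.PCG64(ss)), chain_id=c
        )
        units = sampler.unit_names
        draws.extend(sampler.run())
    if units is None:  # n_chains == 0
        units = [
            (s, o) for s in data.subjects for o in data.refotus[s]
        ]
    return PosteriorSamples(units=units, subjects=list(data.subjects), draws=draws)


def posterior_mean_counts(
    samples: PosteriorSamples,
    schedules,
    subject: str,
    times: np.ndarray,
    phi: np.ndarray | None = None,
) -> np.ndarray:
    """Posterior mean of the NB mean m_sot at arbitrary days for one subject.

    ``phi`` carries read-depth offsets for the requested days (zero when the
    future sequencing depth is unknown).  Returns an (O_s, len(times)) array.
    """
    from .signatures import evaluate_signature  # local import to avoid cycle

    sched = _as_schedule_dict(schedules, samples.subjects)[subject]
    times = np.asarray(times, float)
    phi = np.zeros_like(times) if phi is None else np.asarray(phi, float)
    rows = [i for i, (s, _) in enumerate(samples.units) if s == subject]
    out = np.zeros((len(rows), len(times)))
    for d in samples.draws:
        F = np.array([evaluate_signature(sig, times, sched) for sig in d.signatures])
        for j, i in enumerate(rows):
            out[j] += np.exp(F[d.z[i]] + d.gamma[i] + phi)
    return out / max(samples.n_draws, 1)


def gelman_rubin(chains) -> float:
    """Potential-scale-reduction statistic for a scalar summary.

    ``chains`` is an (m, n) array of m >= 2 chains of equal length n >= 2.
    Returns max(R-hat, 1): with finite chains the plain estimator can dip
    marginally below one, which carries no diagnostic meaning.
    """
    x = np.asarray(chains, float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise DataError("need >= 2 chains of equal length")
    m, n = x.shape
    if n < 2:
        raise DataError("chains must have length >= 2")
    W = x.var(axis=1, ddof=1).mean()
    B_over_n = x.mean(axis=1).var(ddof=1)
    if W == 0:
        return 1.0
    v_hat = (n - 1) / n * W + B_over_n
    return float(max(1.0, np.sqrt(v_hat / W)))


# ---------------------------------------------------------------------------
# estimator interface


class TrajectoryMixture(BaseEstimator):
    """Infinite-mixture model of count trajectories (sklearn-style estimator).

    ``fit`` runs the MCMC on a :class:`CountsDataset` (already filtered) and
    stores the pooled posterior plus consensus clustering results; ``predict``
    returns posterior-mean counts for one subject at requested days.

    Parameters mirror :class:`McmcConfig` plus the prior settings; ``hyper``
    of ``None`` selects empirical-Bayes defaults from the data.
    """

    def __init__(
        self,
        n_burnin: int = 2000,
        n_sampling: int = 2000,
        thin: int = 10,
        n_chains: int = 2,
        seed: int = 0,
        n_aux: int = 3,
        hyper: Hyperparams | None = None,
    ):
        self.n_burnin = n_burnin
        self.n_sampling = n_sampling
        self.thin = thin
        self.n_chains = n_chains
        self.seed = seed
        self.n_aux = n_aux
        self.hyper = hyper

    def fit(self, dataset: CountsDataset, schedules):
        from .summaries import build_csgs, coassignment_matrix  # avoid cycle

        config = McmcConfig(
            n_burnin=self.n_burnin, n_sampling=self.n_sampling, thin=self.thin,
            n_chains=self.n_chains, seed=self.seed, n_aux=self.n_aux,
        )
        self.schedules_ = _as_schedule_dict(schedules, dataset.subjects)
        self.samples_ = run_mcmc(dataset, self.schedules_, config, self.hyper)
        occ = [d.n_signatures for d in self.samples_.draws]
        self.n_signatures_ = int(round(float(np.mean(occ)))) if occ else 0
        if self.samples_.n_draws:
            units, mat = coassignment_matrix(self.samples_)
            self.coassignment_ = mat
            groups = build_csgs(mat, self.samples_)
            labels = np.empty(len(units), int)
            for g, csg in enumerate(groups):
                for m in csg.members:
                    labels[units.index(m)] = g
            self.labels_ = labels
        return self

    def predict(self, subject: str, times, phi=None) -> np.ndarray:
        if not hasattr(self, "samples_"):
            raise ConfigError("estimator is not fitted")
        return posterior_mean_counts(self.samples_, self.schedules_, subject, times, phi)
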