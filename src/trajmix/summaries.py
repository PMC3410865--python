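"""Posterior summaries: signature diversity, relaxation times, consensus groups.

All functions are pure: the same :class:`PosteriorSamples` always yields
identical outputs.

Signature-diversity scores
--------------------------
* SD1 (per subject): expected fraction of refOTUs whose assigned signature
  uses more than one distinct equilibrium level (SD1_mu) or more than one
  relaxation time (SD1_lambda).
* SD2 (per subject): expected equivalent number of prototype signatures per
  100 refOTUs — the exponentiated Shannon entropy (natural log) of the
  subject's occupancy distribution, scaled by 100/O_s.
* SD3: ratio of the SD2 score of the pooled "combined ecosystem" to the
  occupancy-weighted average of the per-subject SD2 scores; 1/S when all
  subjects share every signature, 1 when their signature sets are disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde, hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import DataError
from .io_data import PerturbationSchedule, map_to_common_timescale, RANKS
from .mixture import ModelState, PosteriorSamples
from .signatures import evaluate_signature, effective_parameters


# ---------------------------------------------------------------------------
# signature diversity


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def _occupancy(draw: ModelState, mask: np.ndarray | None = None) -> np.ndarray:
    z = draw.z if mask is None else draw.z[mask]
    return np.bincount(z, minlength=draw.n_signatures).astype(float)


def sd1_scores(samples: PosteriorSamples) -> dict[str, tuple[float, float]]:
    """Per-subject (SD1_mu, SD1_lambda) in [0, 1]^2."""
    if samples.n_draws == 0:
        raise DataError("no posterior draws")
    out = {}
    for s in samples.subjects:
        mask = samples.subject_mask(s)
        acc_mu = acc_lam = 0.0
        for d in samples.draws:
            eff = [effective_parameters(sig) for sig in d.signatures]
            multi_mu = np.array([e["n_equilibrium_levels"] > 1 for e in eff])
            multi_lam = np.array([e["n_relaxation_times"] > 1 for e in eff])
            acc_mu += multi_mu[d.z[mask]].mean()
            acc_lam += multi_lam[d.z[mask]].mean()
        out[s] = (float(acc_mu / samples.n_draws), float(acc_lam / samples.n_draws))
    return out


def sd2_score(samples: PosteriorSamples, subject: str) -> float:
    """Expected equivalent signatures per 100 refOTUs for one subject."""
    if subject not in samples.subjects:
        raise DataError(f"unknown subject {subject}")
    mask = samples.subject_mask(subject)
    o_s = int(mask.sum())
    vals = [np.exp(_entropy(_occupancy(d, mask))) for d in samples.draws]
    return 100.0 / o_s * float(np.mean(vals))


def sd2_combined(samples: PosteriorSamples) -> float:
    """SD2 of the hypothetical combined ecosystem (pooled occupancies)."""
    n = samples.n_units
    vals = [np.exp(_entropy(_occupancy(d))) for d in samples.draws]
    return 100.0 / n * float(np.mean(vals))


def sd3_score(samples: PosteriorSamples) -> float:
    """Cross-ecosystem sharing ratio SD2^D / SD2^I in (0, 1]."""
    if len(samples.subjects) < 2:
        raise DataError("SD3 needs at least two subjects")
    per = samples.units_per_subject()
    total = samples.n_units
    sd2_i = sum(per[s] / total * sd2_score(samples, s) for s in samples.subjects)
    return sd2_combined(samples) / sd2_i


def _sd3_of_draws(draws: list[ModelState], masks: dict[str, np.ndarray], total: int) -> float:
    sd2_d = 100.0 / total * float(
        np.mean([np.exp(_entropy(_occupancy(d))) for d in draws])
    )
    sd2_i = 0.0
    for s, mask in masks.items():
        o_s = int(mask.sum())
        vals = [np.exp(_entropy(_occupancy(d, mask))) for d in draws]
        sd2_i += o_s / total * (100.0 / o_s) * float(np.mean(vals))
    return sd2_d / sd2_i


def sd3_permutation_test(
    samples: PosteriorSamples, n_perm: int = 1000, seed: int = 0
) -> float:
    """Permutation p-value for cross-subject signature sharing.

    The null of independent ecosystems is generated by independently
    permuting each subject's signature identities within each draw, which
    preserves every within-subject occupancy vector while reducing
    cross-subject sharing to chance alignment.  Small SD3 indicates sharing,
    so
    p = (1 + #{SD3_perm <= SD3_obs}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise DataError("need at least one permutation")
    observed = sd3_score(samples)
    masks = {s: samples.subject_mask(s) for s in samples.subjects}
    total = samples.n_units
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm_draws = []
        for d in samples.draws:
            K = d.n_signatures
            z_new = np.empty_like(d.z)
            for s, mask in masks.items():
                perm = rng.permutation(K)
                z_new[mask] = perm[d.z[mask]]
            perm_draws.append(
                ModelState(signatures=d.signatures, z=z_new, gamma=d.gamma,
                           eps1=d.eps1, eps2=d.eps2, alpha=d.alpha)
            )
        if _sd3_of_draws(perm_draws, masks, total) <= observed:
            hits += 1
    return (1 + hits) / (n_perm + 1)


# ---------------------------------------------------------------------------
# relaxation times


def posterior_median_lambdas(samples: PosteriorSamples, interval: str = "c") -> np.ndarray:
    """One relaxation constant per (subject, refOTU): the posterior median of
    the assigned signature's lambda on the requested post-pulse interval."""
    if interval not in ("c", "e"):
        raise DataError("interval must be 'c' or 'e'")
    key = "lambda_c" if interval == "c" else "lambda_e"
    per_unit = np.empty((samples.n_draws, samples.n_units))
    for j, d in enumerate(samples.draws):
        lam = np.array([getattr(sig, key) for sig in d.signatures])
        per_unit[j] = lam[d.z]
    return np.median(per_unit, axis=0)


def relaxation_time_density(
    samples: PosteriorSamples,
    interval: str = "c",
    grid: np.ndarray | None = None,
    bw_method: str | float = "silverman",
):
    """Kernel density estimate over per-refOTU relaxation constants (days).

    Returns ``(constants, grid, density)``.  Gaussian kernel, Silverman
    bandwidth by default.
    """
    constants = posterior_median_lambdas(samples, interval)
    spread = constants.std() if constants.std() > 0 else max(constants.mean() * 0.1, 0.5)
    if grid is None:
        # the Gaussian kernel has mass below zero; keep its full support so
        # the estimate integrates to one
        grid = np.linspace(constants.min() - 4 * spread, constants.max() + 4 * spread, 512)
    if constants.std() == 0:
        # degenerate sample: place a narrow Gaussian at the common value
        density = np.exp(-0.5 * ((grid - constants.mean()) / spread) ** 2)
        density /= np.trapezoid(density, grid)
        return constants, grid, density
    kde = gaussian_kde(constants, bw_method=bw_method)
    return constants, grid, kde(grid)


# ---------------------------------------------------------------------------
# consensus signature groups


def coassignment_matrix(samples: PosteriorSamples):
    """Posterior co-assignment probabilities p_{so,s'o'} over all unit pairs.

    Entry (i, j) is the fraction of draws in which units i and j share a
    prototype signature; symmetric with unit diagonal.
    """
    if samples.n_draws == 0:
        raise DataError("no posterior draws")
    n = samples.n_units
    mat = np.zeros((n, n))
    for d in samples.draws:
        mat += d.z[:, None] == d.z[None, :]
    mat /= samples.n_draws
    return list(samples.units), mat


def expected_n_signatures(samples: PosteriorSamples) -> int:
    """Expected number of occupied prototype signatures, rounded to nearest."""
    return int(round(float(np.mean([d.n_signatures for d in samples.draws]))))


def average_linkage_clusters(similarity: np.ndarray, n_clusters: int) -> list[list[int]]:
    """Agglomerate by average linkage on a similarity matrix.

    Repeatedly merges the pair of clusters with the largest average pairwise
    similarity until ``n_clusters`` remain.  Ties are broken by the lowest
    (i, j) pair index, making the result deterministic and equivariant under
    unit permutations up to that rule.
    """
    n = similarity.shape[0]
    clusters: list[list[int]] = [[i] for i in range(n)]
    while len(clusters) > max(n_clusters, 1):
        best, best_pair = -np.inf, None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                sim = float(np.mean(similarity[np.ix_(clusters[i], clusters[j])]))
                if sim > best + 1e-12:
                    best, best_pair = sim, (i, j)
        i, j = best_pair
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return clusters


@dataclass
class ConsensusSignatureGroup:
    """A consensus cluster of (subject, refOTU) series.

    ``trajectory`` holds (grid, median, lower, upper) on the common
    time-scale once :func:`consensus_trajectory` has been attached;
    ``lambda_c`` / ``lambda_e`` are median relaxation constants in days.
    """

    members: list[tuple[str, str]]
    lambda_c: float = float("nan")
    lambda_e: float = float("nan")
    trajectory: dict = field(default_factory=dict)
    enrichment: list[dict] = field(default_factory=list)


def build_csgs(coassignment: np.ndarray, samples: PosteriorSamples) -> list[ConsensusSignatureGroup]:
    """Average-linkage consensus groups, stopped at the expected signature count."""
    n_stop = expected_n_signatures(samples)
    groups = average_linkage_clusters(coassignment, n_stop)
    lam_c = posterior_median_lambdas(samples, "c")
    lam_e = posterior_median_lambdas(samples, "e")
    out = []
    for idx in sorted(groups, key=min):
        out.append(
            ConsensusSignatureGroup(
                members=[samples.units[i] for i in idx],
                lambda_c=float(np.median(lam_c[idx])),
                lambda_e=float(np.median(lam_e[idx])),
            )
        )
    return out


def consensus_trajectory(
    csg: ConsensusSignatureGroup,
    samples: PosteriorSamples,
    schedules: dict[str, PerturbationSchedule],
    reference: str | None = None,
    n_grid: int = 120,
):
    """Median and 95% credible band of member trajectories on a common scale.

    For every member and draw the assigned signature is evaluated on the
    reference day grid (mapped through the member's own schedule), the
    pre-treatment level subtracted and the curve scaled to unit maximum
    absolute deviation; the band is the pointwise 2.5/97.5 percentile across
    all (member, draw) curves.
    """
    if not csg.members:
        raise DataError("empty consensus group")
    reference = reference or samples.subjects[0]
    ref_sched = schedules[reference]
    grid = np.linspace(ref_sched.start, ref_sched.end, n_grid)
    unit_index = {u: i for i, u in enumerate(samples.units)}
    curves = []
    for member in csg.members:
        s = member[0]
        i = unit_index[member]
        t_sub = map_to_common_timescale(ref_sched, schedules[s], grid)
        for d in samples.draws:
            sig = d.signatures[d.z[i]]
            f = np.asarray(evaluate_signature(sig, t_sub, schedules[s]))
            f = f - effective_parameters(sig)["mu_a"]
            peak = np.abs(f).max()
            if peak > 0:
                f = f / peak
            curves.append(f)
    curves = np.asarray(curves)
    med = np.median(curves, axis=0)
    lo, hi = np.percentile(curves, [2.5, 97.5], axis=0)
    csg.trajectory = {"grid": grid, "median": med, "lower": lo, "upper": hi}
    return grid, med, lo, hi


# ---------------------------------------------------------------------------
# enrichment


def taxon_enrichment(
    csg: ConsensusSignatureGroup,
    taxonomy: dict[str, dict[str, str]],
    rank: str,
    universe: list[tuple[str, str]],
) -> list[dict]:
    """Hypergeometric over-representation p-values for labels at one rank.

    The universe is the full set of (subject, refOTU) units; for each label
    L present in the group, p = P(X >= x) with X hypergeometric(N, K_L, n)
    where N = |universe|, K_L = units carrying L, n = group size and x the
    members carrying L.
    """
    if rank not in RANKS:
        raise DataError(f"unknown taxonomic rank {rank!r}")
    def label(unit):
        return taxonomy.get(unit[1], {}).get(rank, "unclassified")

    n_total = len(universe)
    group = list(csg.members)
    results = []
    for lab in sorted({label(u) for u in group}):
        k_lab = sum(1 for u in universe if label(u) == lab)
        x = sum(1 for u in group if label(u) == lab)
        p = float(hypergeom.sf(x - 1, n_total, k_lab, len(group)))
        results.append({"rank": rank, "label": lab, "x": x, "K": k_lab,
                        "n": len(group), "N": n_total, "p": min(p, 1.0)})
    return results


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_all_csgs(
    csgs: list[ConsensusSignatureGroup],
    taxonomy: dict[str, dict[str, str]],
    universe: list[tuple[str, str]],
    fdr_threshold: float = 0.05,
) -> list[dict]:
    """Enrichment at order/family/genus with FDR pooled over all tests."""
    rows = []
    for g, csg in enumerate(csgs):
        for rank in RANKS:
            for rec in taxon_enrichment(csg, taxonomy, rank, universe):
                rec["csg"] = g
                rows.append(rec)
    if rows:
        q = bh_fdr([r["p"] for r in rows])
        for r, qv in zip(rows, q):
            r["q"] = float(qv)
            r["significant"] = bool(qv < fdr_threshold)
        for g, csg in enumerate(csgs):
            csg.enrichment = [r for r in rows if r["csg"] == g]
    return rows
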