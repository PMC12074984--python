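"""Population-size trajectory inference from phylogenies.

The temporal density of coalescences (branchpoints) in an isochronously
sampled genealogy is informative about N(t)/lambda(t), the ratio of
population size to the symmetric self-renewal rate: with k extant lineages
the coalescence rate is k(k-1)/2 times the pairwise rate, and inverting the
Kingman rate interval by interval yields the classic skyline estimator of
N/lambda.  On top of the skyline, rejection ABC over the bounded two-epoch
birth-death model (uniform priors on N, lambda, nu as published) recovers
the parameters themselves: each proposed parameter set simulates a genealogy
via the deterministic-trajectory/time-rescaled-coalescent fast path, and the
closest simulations in standardized summary-statistic space form the
approximate posterior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylotree import Phylogeny
from .synthetic_data import (Epoch, PopModel, WEEKS_PER_YEAR,
                             sample_coalescent_ages, trajectory_segments)

__all__ = [
    "SkylineTrajectory", "ABCConfig", "coalescent_intervals", "skyline",
    "pooled_harmonic_estimate", "simulate_genealogy_summaries",
    "abc_rejection", "clade_entropy_from_merges",
]


@dataclass
class SkylineTrajectory:
    """Ordered intervals with lineage counts and N/lambda estimates."""
    intervals: pd.DataFrame      # columns: age_start, age_end, k, n_over_lambda

    @property
    def estimates(self) -> np.ndarray:
        return self.intervals["n_over_lambda"].to_numpy()


def coalescent_intervals(phylo: Phylogeny, rtol: float = 1e-6) -> list:
    """Intercoalescent intervals (k, dt) from an ultrametric tree.

    Ages are measured backward from the tips.  k decreases by one per
    coalescence; a polytomy of degree d emits d - 2 zero-length intervals.
    Raises on non-ultrametric input, reporting the largest tip-height
    discrepancy.
    """
    times = phylo.node_times()
    tip_depths = [times[t] for t in phylo.tips()]
    height = max(tip_depths)
    spread = height - min(tip_depths)
    if height > 0 and spread > rtol * height:
        raise ValueError(f"tree is not ultrametric: tip-height spread {spread:g}")
    ages = []
    for node in phylo.tree.preorder_internal_node_iter():
        nc = len(node.child_nodes())
        if nc >= 2:
            ages.extend([height - times[node]] * (nc - 1))
    ages.sort()
    n_tips = len(tip_depths)
    intervals = []
    prev = 0.0
    k = n_tips
    for a in ages:
        intervals.append((k, a - prev))
        prev = a
        k -= 1
        if k == 1:
            break
    return intervals


def skyline(intervals, pool_min_dt: float = 0.0) -> SkylineTrajectory:
    """Classic (optionally generalized) skyline estimate of N/lambda.

    Per interval the Kingman inversion gives N/lambda = k(k-1) dt / 2; with
    ``pool_min_dt`` > 0 consecutive intervals are pooled until their summed
    duration reaches the threshold (zero-length polytomy intervals always
    pool with their neighbour), and the pooled maximum-likelihood estimate is
    sum_j k_j (k_j - 1) dt_j / 2 divided by the number of coalescences in the
    group.
    """
    if not intervals:
        raise ValueError("need at least one intercoalescent interval")
    rows = []
    age = 0.0
    group: list = []
    gdt = 0.0
    for k, dt in intervals:
        group.append((k, dt))
        gdt += dt
        if gdt >= pool_min_dt and gdt > 0:
            num = sum(kk * (kk - 1) * d / 2.0 for kk, d in group)
            rows.append((age, age + gdt, group[0][0], num / len(group)))
            age += gdt
            group, gdt = [], 0.0
    if group:
        num = sum(kk * (kk - 1) * d / 2.0 for kk, d in group)
        est = num / len(group) if gdt > 0 else np.nan
        rows.append((age, age + gdt, group[0][0], est))
    df = pd.DataFrame(rows, columns=["age_start", "age_end", "k",
                                     "n_over_lambda"])
    return SkylineTrajectory(df)


def pooled_harmonic_estimate(intervals) -> float:
    """Single pooled N/lambda over the whole tree (constant-size estimator)."""
    num = sum(k * (k - 1) * dt / 2.0 for k, dt in intervals)
    return num / len(intervals)


# ---------------------------------------------------------------------------
# rejection ABC over the bounded two-epoch birth-death model
# ---------------------------------------------------------------------------

@dataclass
class ABCConfig:
    """Priors and settings for rejection ABC (published uniform priors).

    N (adult cap) is uniform on [1e2, 1e5] cells; lambda uniform on
    [0.01, 0.15] divisions per day; nu uniform on [0, lambda].  The epoch
    boundary sits at 10 weeks post-conception; the weakly identified early
    epoch is held fixed at an embryonic-expansion setting rather than
    inferred.
    """
    n_bounds: tuple = (1e2, 1e5)
    lam_bounds_per_day: tuple = (0.01, 0.15)
    epoch_boundary: float = 10.0          # weeks post-conception
    lam_embryo: float = 0.8               # per week, fixed early epoch
    nu_embryo: float = 0.0
    n_sims: int = 2000
    accept_frac: float = 0.05
    n_ltt_points: int = 12
    seed: int | None = None


def _two_epoch_model(n_cap, lam_week, nu_week, cfg: ABCConfig) -> PopModel:
    return PopModel(epochs=(
        Epoch(duration=cfg.epoch_boundary, lam=cfg.lam_embryo,
              nu=cfg.nu_embryo, cap=n_cap),
        Epoch(duration=math.inf, lam=lam_week, nu=nu_week, cap=n_cap),
    ))


def clade_entropy_from_merges(n_tips: int, merge_order: np.ndarray,
                              k_at_cut: int) -> float:
    """Shannon entropy of clade sizes when k_at_cut lineages remain.

    ``merge_order`` lists, per coalescence (oldest-age last), the two clade
    slots merged; under the neutral coalescent the pair is uniform, so a
    random merge sequence reproduces the topology's clade-size law.
    """
    sizes = [1] * n_tips
    merges_done = 0
    # merges happen backward in time; cutting at k lineages means n-k merges
    for (a, b) in merge_order:
        if n_tips - merges_done <= k_at_cut:
            break
        i = a
        j = b if b < i else b + 1        # distinct uniform pair
        sizes[i] += sizes[j]
        sizes[j] = sizes[-1]
        sizes.pop()
        merges_done += 1
    p = np.asarray(sizes, float)
    p /= p.sum()
    return float(-(p * np.log(p)).sum())


def _summaries(coal_ages: np.ndarray, n_tips: int, t_sample: float,
               cfg: ABCConfig, rng: np.random.Generator) -> np.ndarray:
    """Summary vector: LTT at evenly spaced ages, coalescences per epoch,
    MRCA age, and clade entropies at two fixed chronological cuts."""
    ages = np.sort(coal_ages)
    grid = np.linspace(0.0, t_sample, cfg.n_ltt_points)
    ltt = 1.0 + (ages[None, :] > grid[:, None]).sum(axis=1)
    adult_boundary_age = t_sample - cfg.epoch_boundary
    n_coal_adult = float((ages <= adult_boundary_age).sum())
    n_coal_embryo = float(ages.size - n_coal_adult)
    mrca = float(ages.max()) if ages.size else 0.0
    merge_order = [(int(rng.integers(n_tips - m)),
                    int(rng.integers(n_tips - m - 1)))
                   for m in range(n_tips - 1)]
    # entropy cuts: lineage counts at the epoch boundary and at 3/4 of life
    ents = []
    for cut_age in (adult_boundary_age, 0.75 * t_sample):
        k_cut = int(1 + (ages > cut_age).sum())
        ents.append(clade_entropy_from_merges(n_tips, merge_order, k_cut))
    return np.concatenate([ltt, [n_coal_embryo, n_coal_adult, mrca], ents])


def simulate_genealogy_summaries(n_cap, lam_week, nu_week, n_tips, t_sample,
                                 cfg: ABCConfig, rng) -> np.ndarray:
    model = _two_epoch_model(n_cap, lam_week, nu_week, cfg)
    segs = trajectory_segments(model, t_sample)
    ages = sample_coalescent_ages(segs, n_tips, t_sample, rng)
    return _summaries(ages, n_tips, t_sample, cfg, rng)


def observed_summaries(phylo: Phylogeny, t_sample: float, cfg: ABCConfig,
                       seed=None) -> np.ndarray:
    """Summaries of an observed ultrametric tree (chronological, weeks)."""
    intervals = coalescent_intervals(phylo)
    ages = np.cumsum([dt for _, dt in intervals])
    n_tips = phylo.n_tips
    rng = np.random.default_rng(seed)
    return _summaries(np.asarray(ages), n_tips, t_sample, cfg, rng)


def abc_rejection(observed, n_tips: int, t_sample: float,
                  config: ABCConfig | None = None) -> dict:
    """Rejection ABC posterior for (N, lambda, nu) of the adult epoch.

    ``observed`` is either a chronological ultrametric :class:`Phylogeny`
    (>= 20 tips) or a precomputed summary vector.  Parameters are drawn from
    the published uniform priors, genealogies simulated with matched tip
    count and sampling age, and the ``accept_frac`` closest simulations by
    Euclidean distance on summaries standardized by their prior-predictive SD
    are retained.  Returns the accepted draws and posterior medians with 95%
    credible intervals: N (cells), division interval tau = 1/lambda (weeks),
    exit interval 1/nu (weeks) and N/lambda in HSC-years.
    """
    cfg = config or ABCConfig()
    rng = np.random.default_rng(cfg.seed)
    if isinstance(observed, Phylogeny):
        if observed.n_tips < 20:
            raise ValueError("observed tree needs >= 20 tips")
        obs = observed_summaries(observed, t_sample, cfg,
                                 seed=rng.integers(2**31))
    else:
        obs = np.asarray(observed, dtype=float)

    lo_n, hi_n = cfg.n_bounds
    lo_l, hi_l = cfg.lam_bounds_per_day
    Ns = rng.uniform(lo_n, hi_n, cfg.n_sims)
    lams_day = rng.uniform(lo_l, hi_l, cfg.n_sims)
    nus_day = rng.uniform(0.0, lams_day)
    sims = np.empty((cfg.n_sims, obs.size))
    for i in range(cfg.n_sims):
        sims[i] = simulate_genealogy_summaries(
            Ns[i], lams_day[i] * 7.0, nus_day[i] * 7.0,
            n_tips, t_sample, cfg, rng)
    sd = sims.std(axis=0)
    sd[sd == 0] = 1.0
    dist = np.sqrt((((sims - obs) / sd) ** 2).sum(axis=1))
    n_accept = max(int(round(cfg.accept_frac * cfg.n_sims)), 1)
    if n_accept < 100:
        import warnings
        warnings.warn(f"only {n_accept} accepted simulations; consider a "
                      "larger n_sims or acceptance fraction")
    idx = np.argsort(dist)[:n_accept]
    acc = pd.DataFrame({
        "N": Ns[idx],
        "lambda_per_day": lams_day[idx],
        "nu_per_day": nus_day[idx],
        "distance": dist[idx],
    })
    acc["tau_weeks"] = 1.0 / (acc["lambda_per_day"] * 7.0)
    with np.errstate(divide="ignore"):
        acc["exit_weeks"] = 1.0 / (acc["nu_per_day"] * 7.0)
    acc["n_over_lambda_hsc_years"] = (
        acc["N"] / (acc["lambda_per_day"] * 7.0) / WEEKS_PER_YEAR)

    def q(col):
        v = acc[col].to_numpy()
        return {"median": float(np.median(v)),
                "ci": (float(np.quantile(v, 0.025)),
                       float(np.quantile(v, 0.975)))}

    return {"accepted": acc,
            "posterior": {c: q(c) for c in ("N", "tau_weeks", "exit_weeks",
                                            "n_over_lambda_hsc_years")},
            "observed_summaries": obs}
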