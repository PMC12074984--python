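"""Fitness-landscape estimation from duplex VAF spectra.

Under a continuous-time branching model of stem-cell dynamics, variants with
fitness effect s arise at constant rate mu in a pool of N cells dividing
symmetrically every tau years.  The density of variants per unit l = ln(VAF)
is

    rho(l) = theta / (1 - 2 e^l) * exp(-e^l / (phi (1 - 2 e^l)))

with theta = N tau mu setting the low-VAF amplitude and
phi = (e^{st} - 1) / (2 N tau s) the typical maximum VAF a variant reaches
by age t (neutral limit phi = t / (2 N tau)).  Fitting the synonymous
(neutral) spectrum therefore yields N tau and mu; fixing phi and refitting
the non-synonymous spectrum restricted to the neutral VAF range yields the
non-synonymous rate; and mixing rho(l | s) over an exponential-power
distribution of fitness effects mu(s) ~ exp(-(s/d)^beta), beta = 3, yields
the fitness landscape (scale d and the non-neutral fraction).

The module also houses the unit conversions used when interpreting fits:
annual growth <-> per-division selective advantage, the drift threshold
s* = lambda / N, clone establishment time 1/s, and burden <-> per-bp rates
on the diploid genome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import gammainc

from .synthetic_data import VAFSpectrum, WEEKS_PER_YEAR

__all__ = [
    "NeutralFit", "DFEFit", "log_vaf_density", "phi_from_params",
    "doane_bin_count", "fit_neutral", "fit_nonsynonymous", "fit_dfe",
    "annual_to_per_division", "per_division_to_annual", "drift_threshold",
    "establishment_time", "per_bp_rate", "scale_panel_rate",
    "DIPLOID_MOUSE_GENOME_BP",
]

DIPLOID_MOUSE_GENOME_BP = 5.46e9      # 2 x 2.73 Gb, configurable constant
_LMAX = math.log(0.5)


@dataclass
class NeutralFit:
    """Neutral-spectrum fit: N tau (HSC-years), mu (per panel per year)."""
    n_tau: float
    mu: float
    theta: float
    phi: float
    n_variants: int
    age_t: float


@dataclass
class DFEFit:
    """Exponential-power fitness landscape fit (shape beta fixed)."""
    scale_d: float
    beta: float
    nonneutral_frac: float
    strong_frac: float        # annual growth in the 50-200 % band
    loglik: float
    n_variants: int
    flagged: bool = False


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def log_vaf_density(l, theta: float, phi: float):
    """Variant density rho(l) per unit l = ln(VAF).

    Defined for l < ln(0.5); tends to theta as l -> -inf and to zero at the
    l -> ln(0.5) boundary, where the essential-singularity decay dominates.
    """
    l = np.asarray(l, dtype=float)
    if np.any(l >= _LMAX):
        raise ValueError("log-VAF must be below ln(0.5)")
    if theta <= 0 or phi <= 0:
        raise ValueError("theta and phi must be positive")
    v = np.exp(l)
    denom = 1.0 - 2.0 * v
    return theta / denom * np.exp(-v / (phi * denom))


def _shape(l: np.ndarray, phi: float) -> np.ndarray:
    v = np.exp(l)
    denom = 1.0 - 2.0 * v
    return np.exp(-v / (phi * denom)) / denom


def phi_from_params(s: float, t: float, n_tau: float) -> float:
    """Typical maximum VAF phi = (e^{st} - 1) / (2 N tau s).

    Continuous at s = 0 where phi = t / (2 N tau); increases with both s
    and t.
    """
    if n_tau <= 0 or t <= 0:
        raise ValueError("n_tau and t must be positive")
    if abs(s) < 1e-12:
        return t / (2.0 * n_tau)
    return math.expm1(s * t) / (2.0 * n_tau * s)


# ---------------------------------------------------------------------------
# neutral and non-synonymous fits
# ---------------------------------------------------------------------------

def doane_bin_count(x: np.ndarray) -> int:
    """Doane's rule: k = 1 + log2(n) + log2(1 + |g1| / sigma_g1), ceiled."""
    n = x.size
    if n < 3:
        return max(n, 1)
    g1 = float(stats.skew(x))
    sg = math.sqrt(6.0 * (n - 2) / ((n + 1) * (n + 3)))
    return int(math.ceil(1 + math.log2(n) + math.log2(1 + abs(g1) / sg)))


def _tail_grid(l_floor: float, phi: float, n_grid: int = 2000):
    """Reverse-cumulative mass of the normalized shape on a dense grid."""
    grid = np.linspace(l_floor, _LMAX - 1e-9, n_grid)
    dens = _shape(grid, phi)
    cum = np.concatenate([[0.0], np.cumsum(
        0.5 * (dens[1:] + dens[:-1]) * np.diff(grid))])
    total = cum[-1]
    tail = total - cum
    return grid, tail, total


def _fit_phi(l_obs: np.ndarray, edges: np.ndarray, l_floor: float,
             phi_bounds=(1e-7, 5e-2)) -> float:
    emp_tail = (l_obs[None, :] >= edges[:, None]).mean(axis=1)

    def loss(log_phi):
        grid, tail, total = _tail_grid(l_floor, math.exp(log_phi))
        model = np.interp(edges, grid, tail) / total
        return float(((model - emp_tail) ** 2).sum())

    lo, hi = math.log(phi_bounds[0]), math.log(phi_bounds[1])
    grid = np.linspace(lo, hi, 120)
    losses = [loss(g) for g in grid]
    i = int(np.argmin(losses))
    res = optimize.minimize_scalar(
        loss, bounds=(grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]),
        method="bounded", options={"xatol": 1e-8})
    return math.exp(res.x)


def fit_neutral(spectrum: VAFSpectrum, neutral_classes=("synonymous",
                "intronic"), min_variants: int = 30,
                bin_edges=None) -> NeutralFit:
    """Fit (theta, phi) to the synonymous/intronic log-VAF spectrum.

    The empirical reverse-cumulative density on Doane-binned log-VAF edges is
    matched to the model tail in L2 (this pins phi, the shape); theta then
    follows from the total count over the observed window divided by the
    cohort size, making the amplitude per individual.  N tau = t / (2 phi)
    and mu = theta / (N tau).  Deterministic given the spectrum.
    """
    sel = spectrum.variants["vclass"].isin(neutral_classes)
    vafs = spectrum.variants.loc[sel, "vaf"].to_numpy()
    vafs = vafs[vafs >= spectrum.vaf_floor]
    if vafs.size < min_variants:
        raise ValueError(f"only {vafs.size} neutral variants above the floor "
                         f"(need >= {min_variants})")
    l_obs = np.log(vafs)
    l_floor = math.log(spectrum.vaf_floor)
    if bin_edges is None:
        k = doane_bin_count(l_obs)
        edges = np.linspace(l_floor, l_obs.max(), k + 1)
    else:
        edges = np.asarray(bin_edges, dtype=float)
    phi = _fit_phi(l_obs, edges, l_floor)
    _, _, total = _tail_grid(l_floor, phi)
    theta = vafs.size / (total * spectrum.cohort_size)
    n_tau = spectrum.age_t / (2.0 * phi)
    return NeutralFit(n_tau=n_tau, mu=theta / n_tau, theta=theta, phi=phi,
                      n_variants=int(vafs.size), age_t=spectrum.age_t)


def fit_nonsynonymous(spectrum: VAFSpectrum, neutral: NeutralFit) -> NeutralFit:
    """Non-synonymous rate with phi fixed from the neutral fit.

    Only variants below the maximum synonymous VAF (the 'neutral range',
    where even selected variants behave neutrally) inform the count;
    mu_ns = theta_ns / N tau.
    """
    sel = spectrum.variants["vclass"] == "non-synonymous"
    vafs = spectrum.variants.loc[sel, "vaf"].to_numpy()
    vafs = vafs[(vafs >= spectrum.vaf_floor)
                & (vafs < spectrum.neutral_range_max)]
    if vafs.size == 0:
        raise ValueError("no non-synonymous variants in the neutral range")
    l_floor = math.log(spectrum.vaf_floor)
    l_hi = math.log(spectrum.neutral_range_max)
    grid, tail, total = _tail_grid(l_floor, neutral.phi)
    mass = total - float(np.interp(l_hi, grid, tail))
    theta_ns = vafs.size / (mass * spectrum.cohort_size)
    return NeutralFit(n_tau=neutral.n_tau, mu=theta_ns / neutral.n_tau,
                      theta=theta_ns, phi=neutral.phi,
                      n_variants=int(vafs.size), age_t=spectrum.age_t)


# ---------------------------------------------------------------------------
# distribution of fitness effects
# ---------------------------------------------------------------------------

def _dfe_weights(scale: float, beta: float, s_max: float = 4.0,
                 n_nodes: int = 64):
    """Gauss-Legendre nodes/weights for the normalized exp-power density."""
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    s = 0.5 * s_max * (x + 1.0)
    w = 0.5 * s_max * w
    dens = np.exp(-((s / scale) ** beta))
    norm = scale / beta * math.gamma(1.0 / beta)   # int_0^inf exp(-(s/d)^b) ds
    return s, w * dens / norm


def dfe_cdf(s: float, scale: float, beta: float) -> float:
    """P(S <= s) of the exponential-power fitness distribution."""
    return float(gammainc(1.0 / beta, (s / scale) ** beta))


def _mixture_intensity(l: np.ndarray, w_nonneutral: float, scale: float,
                       beta: float, theta_ns: float, phi0: float,
                       age_t: float, n_tau: float) -> np.ndarray:
    """Per-individual intensity over l mixing rho(l | s) over the DFE."""
    out = (1.0 - w_nonneutral) * _shape(l, phi0)
    s_nodes, wts = _dfe_weights(scale, beta)
    for s, w in zip(s_nodes, wts):
        if w <= 0:
            continue
        phi_s = phi_from_params(s, age_t, n_tau)
        out = out + w_nonneutral * w * _shape(l, phi_s)
    return theta_ns * out


def fit_dfe(spectrum: VAFSpectrum, neutral: NeutralFit, ns_fit: NeutralFit,
            beta: float = 3.0, s_max: float = 4.0) -> DFEFit:
    """Maximum-likelihood exponential-power fitness landscape.

    The non-synonymous VAFs above the floor are modelled as an inhomogeneous
    Poisson point process on l with intensity theta_ns * [(1 - w) shape(phi0)
    + w int g(s; d) shape(phi(s)) ds], quadrature over s in (0, s_max].
    Fits the scale d and non-neutral fraction w with beta fixed; reports the
    fraction of non-synonymous mutations with strong effects (50-200 % annual
    growth).  With no variants above the neutral range the fraction is
    pinned to zero and the fit flagged.
    """
    sel = spectrum.variants["vclass"] == "non-synonymous"
    vafs = spectrum.variants.loc[sel, "vaf"].to_numpy()
    vafs = vafs[vafs >= spectrum.vaf_floor]
    n_supra = int((vafs >= spectrum.neutral_range_max).sum())
    if n_supra == 0:
        return DFEFit(scale_d=math.nan, beta=beta, nonneutral_frac=0.0,
                      strong_frac=0.0, loglik=math.nan,
                      n_variants=int(vafs.size), flagged=True)
    l_obs = np.log(vafs)
    l_floor = math.log(spectrum.vaf_floor)
    grid = np.linspace(l_floor, _LMAX - 1e-9, 600)
    cohort = spectrum.cohort_size

    def negll(params):
        log_d, logit_w = params
        d = math.exp(log_d)
        if not 0.1 <= d <= 2.0 * s_max:
            # scales far beyond the quadrature support are unidentifiable
            return 1e12
        w = 1.0 / (1.0 + math.exp(-logit_w))
        lam_obs = _mixture_intensity(l_obs, w, d, beta, ns_fit.theta,
                                     neutral.phi, spectrum.age_t,
                                     neutral.n_tau) * cohort
        lam_grid = _mixture_intensity(grid, w, d, beta, ns_fit.theta,
                                      neutral.phi, spectrum.age_t,
                                      neutral.n_tau) * cohort
        integral = float(np.trapezoid(lam_grid, grid))
        if np.any(lam_obs <= 0):
            return 1e12
        return -(float(np.log(lam_obs).sum()) - integral)

    best = None
    for d0 in (0.5, 1.0, 2.0, 3.0):
        for w0 in (0.05, 0.15, 0.4):
            res = optimize.minimize(
                negll, [math.log(d0), math.log(w0 / (1 - w0))],
                method="Nelder-Mead",
                options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 1500})
            if best is None or res.fun < best.fun:
                best = res
    d_hat = math.exp(best.x[0])
    w_hat = 1.0 / (1.0 + math.exp(-best.x[1]))
    strong = w_hat * (dfe_cdf(2.0, d_hat, beta) - dfe_cdf(0.5, d_hat, beta))
    return DFEFit(scale_d=d_hat, beta=beta, nonneutral_frac=w_hat,
                  strong_frac=strong, loglik=-float(best.fun),
                  n_variants=int(vafs.size), flagged=n_supra <= 5)


# ---------------------------------------------------------------------------
# conversions
# ---------------------------------------------------------------------------

def annual_to_per_division(s_annual: float, division_interval_weeks: float,
                           weeks_per_year: float = WEEKS_PER_YEAR) -> float:
    """Annual fractional growth -> per-symmetric-division advantage.

    Geometric compounding: (1 + s)^(interval / weeks_per_year) - 1, so 200 %
    per year at a 6.4-week division interval is ~15 % per division.
    """
    if s_annual <= -1:
        raise ValueError("annual growth must exceed -100 %")
    if division_interval_weeks <= 0:
        raise ValueError("division interval must be positive")
    return (1.0 + s_annual) ** (division_interval_weeks / weeks_per_year) - 1.0


def per_division_to_annual(s_division: float, division_interval_weeks: float,
                           weeks_per_year: float = WEEKS_PER_YEAR) -> float:
    """Inverse of :func:`annual_to_per_division`."""
    if s_division <= -1:
        raise ValueError("per-division advantage must exceed -100 %")
    return (1.0 + s_division) ** (weeks_per_year / division_interval_weeks) - 1.0


def drift_threshold(n: float, lam: float) -> float:
    """Drift threshold s* = lambda / N: the minimal fitness a clone needs to
    outgrow neutral fluctuation (units of lambda, e.g. per year)."""
    if n <= 0 or lam <= 0:
        raise ValueError("N and lambda must be positive")
    return lam / n


def establishment_time(s: float) -> float:
    """Years before a clone of fitness s (per year) grows deterministically:
    t > 1 / s."""
    if s <= 0:
        raise ValueError("fitness must be positive")
    return 1.0 / s


def per_bp_rate(annual_burden: float,
                genome_bp: float = DIPLOID_MOUSE_GENOME_BP) -> float:
    """Annual mutation burden -> per-bp per-year rate on the diploid genome."""
    if genome_bp <= 0:
        raise ValueError("genome size must be positive")
    return annual_burden / genome_bp


def scale_panel_rate(panel_rate_per_year: float, panel_bp: float = 61_800.0
                     ) -> float:
    """Panel-wide mutation rate (per year) -> per-bp per-year rate.

    The naive ratio; documented as such because the published genome-wide
    scaling is not reproducible from a simple ratio.
    """
    if panel_bp <= 0:
        raise ValueError("panel size must be positive")
    return panel_rate_per_year / panel_bp
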