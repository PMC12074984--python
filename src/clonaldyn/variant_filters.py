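"""Somatic-variant and colony quality control.

Two filter suites operate here. The first works on colony whole-genome
genotype matrices (per-site x per-colony read counts from single-cell-derived
haematopoietic colonies sequenced to ~14x): nine ordered filters separate true
clonal somatic variants (present at VAF ~0.5 in a subset of colonies) from
germline variants and recurrent artefacts, followed by colony-level exclusion
of low-coverage or non-clonal colonies. The second works on duplex-consensus
variant tables from targeted deep sequencing of blood (duplex depths in the
tens of thousands), where thirteen table-level filters remove consensus-read
artefacts, undersequenced loci and putative germline calls while keeping
genuine low-VAF clonal-haematopoiesis variants.

The module also estimates per-colony mutation burdens corrected for depth-
dependent detection sensitivity, and fits the burden-versus-age random-slope
mixed model whose fixed-effect slope is the annual somatic mutation rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ColonyGenotypeMatrix",
    "ColonyFilterConfig",
    "DuplexFilterConfig",
    "FilterReport",
    "betabinom_overdispersion",
    "filter_colony_variants",
    "qc_colonies",
    "correct_burden_depth",
    "fit_burden_rate",
    "filter_duplex_variants",
    "burden_at_age",
    "burden_intercept",
]

PRESENT, ABSENT, UNKNOWN = "P", "A", "U"

# Columns every duplex table must carry, mapped to the filter that reads them.
DUPLEX_REQUIRED = {
    "qual_flag": "quality_flag",
    "alt_reads": "read_support",
    "mean_mismatches": "mismatches",
    "end_repair_prob": "end_repair",
    "min_read_end_dist": "read_position",
    "is_oxo_artifact": "oxidative",
    "depth": "coverage",
    "fwd_mut": "strand_bias",
    "rev_mut": "strand_bias",
    "fwd_wt": "strand_bias",
    "rev_wt": "strand_bias",
    "sample": "recurrence",
    "batch": "recurrence",
    "indel_len": "indel_length",
    "vaf": "high_vaf",
    "vclass": "impact",
    "human_homolog": "homologous_position",
}


class ColonyGenotypeMatrix:
    """Per-site x per-colony depths and mutant-read counts with site metadata.

    Parameters
    ----------
    sites : DataFrame indexed by site id with columns ``ref``, ``alt``,
        ``vclass`` ("SNV" or "indel"), ``homopolymer_len`` (length of the
        adjacent single-nucleotide repeat), ``dist_snv`` / ``dist_indel``
        (1-based inclusive bp distance to the nearest neighbouring SNV/indel).
        An optional ``truth`` column carries simulation labels.
    depth, alt, alt_fwd : DataFrames (same site index, colony columns) of
        total depth, mutant-read depth, and forward-strand mutant depth.
    """

    def __init__(self, sites: pd.DataFrame, depth: pd.DataFrame,
                 alt: pd.DataFrame, alt_fwd: pd.DataFrame):
        if not (sites.index.equals(depth.index) and depth.index.equals(alt.index)
                and alt.index.equals(alt_fwd.index)):
            raise ValueError("site indices of sites/depth/alt/alt_fwd differ")
        if (alt.to_numpy() > depth.to_numpy()).any():
            raise ValueError("mutant depth exceeds total depth")
        if (alt_fwd.to_numpy() > alt.to_numpy()).any():
            raise ValueError("forward mutant depth exceeds mutant depth")
        self.sites = sites
        self.depth = depth
        self.alt = alt
        self.alt_fwd = alt_fwd

    @property
    def colonies(self) -> list[str]:
        return list(self.depth.columns)

    @property
    def n_colonies(self) -> int:
        return self.depth.shape[1]

    @property
    def n_sites(self) -> int:
        return self.depth.shape[0]

    def vaf(self) -> pd.DataFrame:
        d = self.depth.to_numpy(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            v = np.where(d > 0, self.alt.to_numpy(float) / np.maximum(d, 1), np.nan)
        return pd.DataFrame(v, index=self.depth.index, columns=self.depth.columns)

    def genotypes(self, min_depth: int = 6, min_alt: int = 2,
                  min_vaf: float = 0.2) -> pd.DataFrame:
        """Depth-aware Present/Absent/Unknown calls.

        Present: >= ``min_alt`` mutant reads and VAF >= ``min_vaf``.
        Absent: depth >= ``min_depth`` and VAF < ``min_vaf``.
        Otherwise Unknown (insufficient depth to call either way).
        """
        d = self.depth.to_numpy(float)
        a = self.alt.to_numpy(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            v = np.where(d > 0, a / np.maximum(d, 1), 0.0)
        present = (a >= min_alt) & (v >= min_vaf)
        absent = (~present) & (d >= min_depth) & (v < min_vaf)
        g = np.where(present, PRESENT, np.where(absent, ABSENT, UNKNOWN))
        return pd.DataFrame(g, index=self.depth.index, columns=self.depth.columns)

    def subset(self, site_ids) -> "ColonyGenotypeMatrix":
        return ColonyGenotypeMatrix(
            self.sites.loc[site_ids], self.depth.loc[site_ids],
            self.alt.loc[site_ids], self.alt_fwd.loc[site_ids])

    # -- tab-separated round trip ------------------------------------------
    def to_tsv(self, prefix: str) -> None:
        self.sites.to_csv(f"{prefix}.sites.tsv", sep="\t")
        long = pd.concat(
            {"depth": self.depth, "alt": self.alt, "alt_fwd": self.alt_fwd},
            axis=1)
        long.to_csv(f"{prefix}.counts.tsv", sep="\t")

    @classmethod
    def from_tsv(cls, prefix: str) -> "ColonyGenotypeMatrix":
        sites = pd.read_csv(f"{prefix}.sites.tsv", sep="\t", index_col=0)
        counts = pd.read_csv(f"{prefix}.counts.tsv", sep="\t",
                             header=[0, 1], index_col=0)
        return cls(sites, counts["depth"], counts["alt"], counts["alt_fwd"])


@dataclass
class ColonyFilterConfig:
    """Cutoffs for the nine colony-WGS filters (defaults as published)."""
    homopolymer_min_len: int = 5
    strand_p: float = 1e-3
    strand_frac: float = 0.8
    bb_rho_snv: float = 0.1
    bb_rho_indel: float = 0.15
    bb_rho_few_colonies: float = 0.20
    many_colony_threshold: int = 25   # "more than 25 colonies"
    vaf_binom_p: float = 1e-3
    germline_p: float = 1e-3
    germline_vaf: float = 0.45
    indel_proximity_bp: int = 10
    missing_min_depth: int = 6
    missing_max_frac: float = 1.0 / 3.0
    cluster_bp: int = 10
    clonal_vaf: float = 0.5


@dataclass
class DuplexFilterConfig:
    """Cutoffs for the thirteen duplex-table filters.

    ``drop_synonymous`` and ``require_human_homolog`` correspond to the impact
    and homologous-position filters, which are switched off for analyses that
    need synonymous variants (dN/dS-style outputs, fitness fits).
    """
    min_alt_reads: int = 2            # singletons discarded
    max_mean_mismatches: float = 3.0
    end_repair_prob_max: float = 0.5  # cutoff unstated in source; configurable
    min_read_end_dist: int = 16       # <= 15 bp from either end discarded
    min_duplex_depth: int = 20_001    # <= 20,000x considered undersequenced
    strand_fisher_p: float = 1e-3
    recurrence_batch_frac: float = 0.05
    recurrence_n_samples: int = 5
    max_indel_len: int = 14           # >= 15 bp excluded
    germline_vaf: float = 0.4         # VAF >= 0.4 putative germline
    drop_synonymous: bool = False
    require_human_homolog: bool = False


@dataclass
class FilterReport:
    """Per-site verdicts plus attrition counts, one verdict per input site."""
    verdict: pd.Series                 # site id -> "pass" or first failing filter
    counts: dict = field(default_factory=dict)
    excluded_colonies: dict = field(default_factory=dict)

    @property
    def n_pass(self) -> int:
        return int((self.verdict == "pass").sum())


# ---------------------------------------------------------------------------
# beta-binomial overdispersion
# ---------------------------------------------------------------------------

def _betabinom_negll(rho: float, alt: np.ndarray, depth: np.ndarray,
                     mean: float) -> float:
    a = mean * (1.0 - rho) / rho
    b = (1.0 - mean) * (1.0 - rho) / rho
    return -float(np.sum(stats.betabinom.logpmf(alt, depth, a, b)))


def betabinom_overdispersion(alt, depth, rho_bounds=(1e-6, 0.89)) -> float:
    """Maximum-likelihood beta-binomial overdispersion rho across colonies.

    The per-site mean is fixed at the aggregate VAF; the likelihood is
    maximised over rho alone on ``rho_bounds`` with a coarse log-spaced grid
    followed by bounded scalar refinement.  High rho corresponds to a bimodal
    present/absent pattern (true clonal variant); low rho to a uniform
    low-VAF pattern (artefact).
    """
    alt = np.asarray(alt, dtype=int)
    depth = np.asarray(depth, dtype=int)
    keep = depth > 0
    alt, depth = alt[keep], depth[keep]
    if depth.size < 2:
        raise ValueError("need >=2 colonies with nonzero depth")
    tot = depth.sum()
    if alt.sum() == 0:
        return rho_bounds[0]
    mean = min(max(alt.sum() / tot, 1e-9), 1 - 1e-9)

    grid = np.exp(np.linspace(np.log(rho_bounds[0]), np.log(rho_bounds[1]), 25))
    ll = [_betabinom_negll(r, alt, depth, mean) for r in grid]
    i = int(np.argmin(ll))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        _betabinom_negll, bounds=(lo, hi), args=(alt, depth, mean),
        method="bounded", options={"xatol": 1e-6})
    return float(res.x)


# ---------------------------------------------------------------------------
# colony-WGS filters 1-9
# ---------------------------------------------------------------------------

def _binom_p_two_sided(k: np.ndarray, n: np.ndarray, p: float) -> np.ndarray:
    lower = stats.binom.cdf(k, n, p)
    upper = stats.binom.sf(k - 1, n, p)
    return np.clip(2.0 * np.minimum(lower, upper), 0.0, 1.0)


def filter_colony_variants(matrix: ColonyGenotypeMatrix,
                           config: ColonyFilterConfig | None = None,
                           ) -> tuple[list, FilterReport]:
    """Apply the nine colony-WGS filters in their published order.

    Returns the passing site ids and a :class:`FilterReport` recording, per
    site, the first filter that failed.  Filters, in order: homopolymer,
    strand bias, beta-binomial overdispersion, VAF (binomial and half-median),
    germline aggregate VAF, indel proximity, missing sites, clustered sites,
    non-variable sites.
    """
    cfg = config or ColonyFilterConfig()
    sites = matrix.sites
    n_sites = matrix.n_sites
    if n_sites == 0:
        report = FilterReport(pd.Series(dtype=object),
                              counts={"input": 0, "pass": 0})
        return [], report

    depth = matrix.depth.to_numpy(float)
    alt = matrix.alt.to_numpy(float)
    fwd = matrix.alt_fwd.to_numpy(float)
    is_snv = (sites["vclass"] == "SNV").to_numpy()
    geno = matrix.genotypes().to_numpy()

    verdict = np.full(n_sites, "pass", dtype=object)
    active = np.ones(n_sites, dtype=bool)

    def fail(mask, name):
        hit = mask & active
        verdict[hit] = name
        active[hit] = False

    # (1) homopolymer run
    fail(sites["homopolymer_len"].to_numpy() >= cfg.homopolymer_min_len,
         "homopolymer")

    # (2) strand bias: aggregate mutant reads across colonies
    m = alt.sum(axis=1)
    f = fwd.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(m > 0, f / np.maximum(m, 1), 0.5)
    pvals = _binom_p_two_sided(f, m.astype(int), 0.5)
    biased = (pvals < cfg.strand_p) & (np.maximum(frac, 1 - frac) > cfg.strand_frac)
    fail(biased & is_snv & (m > 0), "strand_bias")

    # (3) beta-binomial overdispersion
    many = matrix.n_colonies > cfg.many_colony_threshold
    rho = np.full(n_sites, np.nan)
    for i in range(n_sites):
        if not active[i]:
            continue
        try:
            rho[i] = betabinom_overdispersion(alt[i], depth[i].astype(int))
        except ValueError:
            rho[i] = np.nan
    if many:
        thr = np.where(is_snv, cfg.bb_rho_snv, cfg.bb_rho_indel)
    else:
        thr = np.full(n_sites, cfg.bb_rho_few_colonies)
    fail(np.nan_to_num(rho, nan=1.0) < thr, "beta_binomial")

    # (4) VAF filters: aggregate VAF among mutant-genotyped colonies
    mut = geno == PRESENT
    alt_mut = np.where(mut, alt, 0.0).sum(axis=1)
    dep_mut = np.where(mut, depth, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf_mut = np.where(dep_mut > 0, alt_mut / np.maximum(dep_mut, 1), np.nan)
    p_low = stats.binom.cdf(alt_mut, dep_mut.astype(int), cfg.clonal_vaf)
    fail((dep_mut > 0) & (p_low < cfg.vaf_binom_p), "vaf_binomial")
    bb_pass_vafs = vaf_mut[active & ~np.isnan(vaf_mut)]
    if bb_pass_vafs.size:
        half_median = 0.5 * np.median(bb_pass_vafs)
        fail(np.nan_to_num(vaf_mut, nan=1.0) < half_median, "vaf_half_median")

    # (5) germline: aggregate VAF not significantly below 0.45
    alt_all = alt.sum(axis=1)
    dep_all = depth.sum(axis=1)
    p_less = stats.binom.cdf(alt_all, dep_all.astype(int), cfg.germline_vaf)
    fail((dep_all > 0) & (p_less >= cfg.germline_p), "germline")

    # (6) SNV within 10 bp of an indel
    fail(is_snv & (sites["dist_indel"].to_numpy() <= cfg.indel_proximity_bp),
         "indel_proximity")

    # (7) missing sites: low coverage in over a third of colonies
    frac_missing = (depth < cfg.missing_min_depth).mean(axis=1)
    fail(frac_missing > cfg.missing_max_frac, "missing_site")

    # (8) clustered sites (same variant class within 10 bp)
    dist_same = np.where(is_snv, sites["dist_snv"].to_numpy(),
                         sites["dist_indel"].to_numpy())
    fail(dist_same <= cfg.cluster_bp, "clustered")

    # (9) non-variable sites
    n_mut = mut.sum(axis=1)
    n_wt = (geno == ABSENT).sum(axis=1)
    fail((n_mut == matrix.n_colonies) | (n_wt == matrix.n_colonies),
         "non_variable")

    verdict = pd.Series(verdict, index=sites.index, name="verdict")
    counts = verdict.value_counts().to_dict()
    counts["input"] = n_sites
    report = FilterReport(verdict, counts=counts)
    passing = list(verdict.index[verdict == "pass"])
    return passing, report


def _kde_mode(vafs: np.ndarray, bandwidth: float = 0.05) -> float:
    grid = np.arange(0.0, 1.0 + 1e-9, 0.005)
    dens = np.exp(-0.5 * ((grid[:, None] - vafs[None, :]) / bandwidth) ** 2).sum(axis=1)
    return float(grid[int(np.argmax(dens))])


def qc_colonies(matrix: ColonyGenotypeMatrix, passing_sites,
                mean_vaf_min: float = 0.4, mode_min: float = 0.35,
                bandwidth: float = 0.05) -> dict:
    """Colony exclusion: low mean VAF or evidence of non-clonality.

    A colony is excluded when the mean VAF of its passing mutant-genotyped
    variants is below ``mean_vaf_min`` (exclusive), or when the mode of the
    kernel-density estimate of those VAFs (Gaussian kernel, fixed bandwidth)
    falls below ``mode_min`` -- the reproducible surrogate for visual
    inspection of a clonally mixed VAF distribution.

    Returns {colony id: reason} for excluded colonies.
    """
    sub = matrix.subset(passing_sites) if len(passing_sites) else None
    excluded: dict = {}
    if sub is None or sub.n_sites == 0:
        return {c: "no_variants" for c in matrix.colonies}
    geno = sub.genotypes()
    vaf = sub.vaf()
    for colony in sub.colonies:
        mask = geno[colony] == PRESENT
        v = vaf.loc[mask.to_numpy(), colony].dropna().to_numpy()
        if v.size == 0:
            excluded[colony] = "no_variants"
        elif v.mean() < mean_vaf_min:
            excluded[colony] = "low_mean_vaf"
        elif _kde_mode(v, bandwidth) < mode_min:
            excluded[colony] = "non_clonal"
    return excluded


# ---------------------------------------------------------------------------
# burden estimation
# ---------------------------------------------------------------------------

def correct_burden_depth(burdens, depths) -> tuple[np.ndarray, np.ndarray, tuple]:
    """Correct per-colony burdens for depth-dependent detection sensitivity.

    Fits the asymptotic regression y = a * (1 - exp(-k * depth)) across the
    colonies of one sample and rescales every colony to the plateau:
    corrected_i = observed_i / (1 - exp(-k * depth_i)).  The per-colony
    sensitivity 1 - exp(-k * depth_i) is also returned (it feeds branch-length
    normalisation).  A non-convergent fit falls back to no correction.
    """
    burdens = np.asarray(burdens, dtype=float)
    depths = np.asarray(depths, dtype=float)
    if burdens.size < 4:
        raise ValueError("need >=4 colonies for a stable asymptotic fit")
    try:
        (a, k), _ = optimize.curve_fit(
            lambda d, a, k: a * (1.0 - np.exp(-k * d)),
            depths, burdens,
            p0=(float(burdens.max()) * 1.2 + 1.0, 0.15),
            bounds=([1e-9, 1e-6], [np.inf, 10.0]), maxfev=20_000)
        sens = 1.0 - np.exp(-k * depths)
        return burdens / sens, sens, (float(a), float(k))
    except (RuntimeError, ValueError):
        warnings.warn("asymptotic depth fit failed; returning uncorrected burdens")
        return burdens.copy(), np.ones_like(burdens), (np.nan, np.nan)


def fit_burden_rate(burdens, ages, animals, alpha: float = 0.05) -> dict:
    """Random-slope mixed model burden ~ age + (0 + age | animal).

    Ages in years; the fixed-effect slope is the annual mutation rate and the
    intercept the burden already present at age 0 (mutations acquired in
    utero).  Fitted by maximum likelihood.  With a single animal the model is
    degenerate and an ordinary regression is used with a warning.
    """
    df = pd.DataFrame({"burden": np.asarray(burdens, float),
                       "age": np.asarray(ages, float),
                       "animal": np.asarray(animals)})
    if df["animal"].nunique() < 2:
        warnings.warn("single animal: falling back to ordinary least squares")
        import statsmodels.api as sm
        X = sm.add_constant(df["age"])
        fit = sm.OLS(df["burden"], X).fit()
        ci = fit.conf_int(alpha)
        return {"slope": float(fit.params["age"]),
                "intercept": float(fit.params["const"]),
                "slope_ci": (float(ci.loc["age", 0]), float(ci.loc["age", 1])),
                "intercept_ci": (float(ci.loc["const", 0]), float(ci.loc["const", 1])),
                "model": "ols"}
    import statsmodels.formula.api as smf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = smf.mixedlm("burden ~ age", df, groups=df["animal"],
                         re_formula="0 + age")
        fit = None
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                fit = md.fit(reml=False, method=method)
                break
            except (np.linalg.LinAlgError, ValueError):
                continue
        if fit is None:
            warnings.warn("mixed model failed to converge; using OLS")
            import statsmodels.api as sm
            X = sm.add_constant(df["age"])
            ols = sm.OLS(df["burden"], X).fit()
            ci = ols.conf_int(alpha)
            return {"slope": float(ols.params["age"]),
                    "intercept": float(ols.params["const"]),
                    "slope_ci": (float(ci.loc["age", 0]),
                                 float(ci.loc["age", 1])),
                    "intercept_ci": (float(ci.loc["const", 0]),
                                     float(ci.loc["const", 1])),
                    "model": "ols"}
    params = fit.fe_params
    ci = fit.conf_int(alpha).loc[["Intercept", "age"]]
    return {"slope": float(params["age"]),
            "intercept": float(params["Intercept"]),
            "slope_ci": (float(ci.loc["age", 0]), float(ci.loc["age", 1])),
            "intercept_ci": (float(ci.loc["Intercept", 0]),
                             float(ci.loc["Intercept", 1])),
            "model": "mixedlm"}


def burden_at_age(intercept: float, slope: float, age_years: float) -> float:
    """Linear burden extrapolation: intercept + slope * age."""
    return intercept + slope * age_years


def burden_intercept(burden: float, age_years: float, slope: float) -> float:
    """Age-0 burden implied by an observed mean burden and an annual rate."""
    return burden - slope * age_years


# ---------------------------------------------------------------------------
# duplex-table filters 1-13
# ---------------------------------------------------------------------------

def filter_duplex_variants(table: pd.DataFrame,
                           config: DuplexFilterConfig | None = None,
                           ) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the thirteen duplex-sequencing table-level filters in order.

    ``table`` must carry the columns in :data:`DUPLEX_REQUIRED`; a missing
    column raises an error naming the column and the filter that needs it.
    Returns the passing rows and a report with per-filter attrition counts.
    """
    cfg = config or DuplexFilterConfig()
    for col, filt in DUPLEX_REQUIRED.items():
        if col not in table.columns:
            raise ValueError(f"duplex table lacks column {col!r} "
                             f"required by the {filt} filter")

    n = len(table)
    verdict = np.full(n, "pass", dtype=object)
    active = np.ones(n, dtype=bool)

    def fail(mask, name):
        hit = np.asarray(mask, bool) & active
        verdict[hit] = name
        active[hit] = False

    t = table.reset_index(drop=True)
    fail(t["qual_flag"] != "PASS", "quality_flag")                       # 1
    fail(t["alt_reads"] < cfg.min_alt_reads, "read_support")             # 2
    fail(t["mean_mismatches"] > cfg.max_mean_mismatches, "mismatches")   # 3
    fail(t["end_repair_prob"] > cfg.end_repair_prob_max, "end_repair")   # 4
    fail(t["min_read_end_dist"] < cfg.min_read_end_dist, "read_position")  # 5
    fail(t["is_oxo_artifact"].astype(bool), "oxidative")                 # 6
    fail(t["depth"] < cfg.min_duplex_depth, "coverage")                  # 7

    # 8: Fisher strand bias between mutant and wild-type reads
    fisher_p = np.ones(n)
    for i in np.flatnonzero(active):
        tab = [[t.at[i, "fwd_mut"], t.at[i, "rev_mut"]],
               [t.at[i, "fwd_wt"], t.at[i, "rev_wt"]]]
        fisher_p[i] = stats.fisher_exact(tab)[1]
    fail(fisher_p < cfg.strand_fisher_p, "strand_bias")

    # 9: recurrence within batches or across independent samples.  A variant
    # seen in a single sample never counts as batch-recurrent.
    key = t["chrom"].astype(str) + ":" + t["pos"].astype(str) + ":" + t["alt"].astype(str) \
        if {"chrom", "pos", "alt"}.issubset(t.columns) else t.index.astype(str)
    t = t.assign(_key=key)
    batch_size = t.groupby("batch")["sample"].nunique()
    hits_in_batch = t.groupby(["batch", "_key"])["sample"].nunique()
    bk = pd.MultiIndex.from_frame(t[["batch", "_key"]])
    n_hits = np.asarray(bk.map(hits_in_batch), dtype=float)
    frac = n_hits / np.asarray(t["batch"].map(batch_size), dtype=float)
    recur_batch = (frac >= cfg.recurrence_batch_frac) & (n_hits >= 2)
    n_samp = t.groupby("_key")["sample"].nunique()
    recur_samp = np.asarray(t["_key"].map(n_samp) >= cfg.recurrence_n_samples)
    fail(recur_batch | recur_samp, "recurrence")

    fail(t["indel_len"].fillna(0) > cfg.max_indel_len, "indel_length")   # 10
    fail(t["vaf"] >= cfg.germline_vaf, "high_vaf")                       # 11
    if cfg.drop_synonymous:                                              # 12
        fail(t["vclass"].isin(["synonymous", "intronic"]), "impact")
    if cfg.require_human_homolog:                                        # 13
        fail(~t["human_homolog"].astype(bool), "homologous_position")

    verdict_s = pd.Series(verdict, index=table.index, name="verdict")
    counts = verdict_s.value_counts().to_dict()
    counts["input"] = n
    report = FilterReport(verdict_s, counts=counts)
    return table.loc[verdict_s == "pass"], report
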