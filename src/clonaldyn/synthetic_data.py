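"""Generators for every input the pipeline consumes.

The study system is the murine haematopoietic stem/progenitor pool: a
population founded by a single cell grows as a bounded linear birth-death
process, genealogies of sampled single-cell-derived colonies accrue Poisson
mutations per division (~1.8 per daughter per division), cell identities
(EMB -> HSC/MPP) evolve as a heritable Markov chain in molecular time, colony
genotype matrices arise by binomial read sampling at ~14x depth, and duplex
VAF spectra of blood variants follow a continuous-time branching model with
a mix of neutral and positively selected variants.

Everything here is seeded and bit-reproducible; the defaults are the study
conditions (mutation rate per division 1.8, mean depth 14, VAF floor 5e-5,
two growth epochs with the boundary at 10 weeks post-conception).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .phylotree import Phylogeny
from .variant_filters import ColonyGenotypeMatrix

__all__ = [
    "Epoch", "PopModel", "StateTransitionParams", "PopulationTrace",
    "VAFSpectrum", "simulate_population", "sample_phylogeny", "label_states",
    "simulate_genotype_matrix", "simulate_duplex_vafs", "kingman_tree",
    "trajectory_segments", "sample_coalescent_ages", "DEFAULT_ARTIFACTS",
]

WEEKS_PER_YEAR = 52.18


@dataclass(frozen=True)
class Epoch:
    """One epoch of the bounded birth-death model (rates per cell per week)."""
    duration: float            # weeks; math.inf allowed for the last epoch
    lam: float                 # symmetric division (birth) rate
    nu: float                  # death/differentiation (exit) rate
    cap: float                 # maximum population size

    def __post_init__(self):
        if not (self.lam >= self.nu >= 0):
            raise ValueError(f"need lambda >= nu >= 0, got {self.lam}, {self.nu}")
        if self.cap < 1:
            raise ValueError("cap must be >= 1")
        if self.duration <= 0:
            raise ValueError("epoch duration must be positive")


@dataclass(frozen=True)
class PopModel:
    """Bounded two-epoch (or more) birth-death population model."""
    epochs: tuple
    mutations_per_division: float = 1.8

    def __post_init__(self):
        if self.mutations_per_division < 0:
            raise ValueError("mutations_per_division must be >= 0")
        if not self.epochs:
            raise ValueError("need at least one epoch")
        object.__setattr__(self, "epochs", tuple(self.epochs))

    def epoch_at(self, t: float) -> Epoch:
        acc = 0.0
        for ep in self.epochs:
            acc += ep.duration
            if t < acc:
                return ep
        return self.epochs[-1]


def default_mouse_model(cap: float = 7e4, lam_adult: float = 1.0 / 6.0,
                        nu_adult: float = 1.0 / 18.0,
                        lam_embryo: float = 0.8, boundary: float = 10.0,
                        ) -> PopModel:
    """Two-epoch mouse HSC/MPP model: embryonic expansion until 10 weeks
    post-conception, then slow adult growth toward ~7e4 cells with symmetric
    divisions roughly every 6 weeks and exit roughly every 18 weeks."""
    return PopModel(epochs=(
        Epoch(duration=boundary, lam=lam_embryo, nu=0.0, cap=cap),
        Epoch(duration=math.inf, lam=lam_adult, nu=nu_adult, cap=cap),
    ))


@dataclass(frozen=True)
class StateTransitionParams:
    """Forward-simulation twin of the hidden Markov tree parameters."""
    p_hsc_to_mpp: float = 0.01
    p_mpp_to_hsc: float = 0.001
    p_emb_to_hsc: float = 0.02
    p_emb_to_mpp: float = 0.02
    emb_lock: int = 10
    phenotype_error: float = 0.0

    def __post_init__(self):
        probs = (self.p_hsc_to_mpp, self.p_mpp_to_hsc,
                 self.p_emb_to_hsc, self.p_emb_to_mpp, self.phenotype_error)
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.p_emb_to_hsc + self.p_emb_to_mpp > 1:
            raise ValueError("EMB exit probabilities exceed 1")


@dataclass
class PopulationTrace:
    """Weekly census plus the birth-event log of one population realisation."""
    times: np.ndarray              # weekly grid, weeks
    counts: np.ndarray             # population size at each grid time
    birth_times: np.ndarray
    birth_parents: np.ndarray
    birth_children: np.ndarray
    alive: np.ndarray              # cell ids extant at t_end
    t_end: float
    model: PopModel
    extinct: bool = False

    @property
    def final_size(self) -> int:
        return int(self.alive.size)


@dataclass
class VAFSpectrum:
    """Duplex variant list (vaf, vclass) with the cohort's study constants."""
    variants: pd.DataFrame
    age_t: float                           # years
    vaf_floor: float = 5e-5
    neutral_range_max: float = 1.99e-4
    cohort_size: int = 1

    def by_class(self, vclass: str) -> np.ndarray:
        sel = self.variants["vclass"] == vclass
        return self.variants.loc[sel, "vaf"].to_numpy()


# ---------------------------------------------------------------------------
# population simulation (Gillespie)
# ---------------------------------------------------------------------------

def simulate_population(model: PopModel, t_end: float, seed,
                        max_events: int = 5_000_000) -> PopulationTrace:
    """Exact event simulation of the bounded birth-death process.

    Starts from one cell at t = 0 with exponential birth/death clocks; births
    are suppressed while the population sits at the epoch's cap (the cap
    bounds size without killing cells).  The birth-event log records
    (time, parent id, child id) and suffices to extract genealogies of any
    subset of extant cells.  Extinction before ``t_end`` is flagged, not an
    error, so callers may resample.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    rng = np.random.default_rng(seed)
    alive = [0]
    next_id = 1
    t = 0.0
    bt, bp, bc = [], [], []
    grid = np.arange(0.0, t_end + 1e-9, 1.0)
    counts = np.zeros(grid.size, dtype=int)
    gi = 0
    n_events = 0
    while True:
        n = len(alive)
        ep = model.epoch_at(t)
        birth_rate = ep.lam * n if n < ep.cap else 0.0
        death_rate = ep.nu * n
        total = birth_rate + death_rate
        # record census up to the next event (or the end)
        t_next = t + rng.exponential(1.0 / total) if total > 0 else math.inf
        # do not step across an epoch boundary with stale rates
        acc = 0.0
        for e in model.epochs:
            acc += e.duration
            if t < acc:
                break
        t_next = min(t_next, acc) if acc > t and math.isfinite(acc) else t_next
        while gi < grid.size and grid[gi] <= min(t_next, t_end):
            counts[gi] = n
            gi += 1
        if t_next >= t_end or n == 0:
            break
        if t_next == acc and math.isfinite(acc):
            t = acc + 1e-12     # epoch boundary: refresh rates
            continue
        t = t_next
        n_events += 1
        if n_events > max_events:
            raise RuntimeError("event budget exceeded; reduce cap or t_end")
        if rng.uniform() * total < birth_rate:
            parent = alive[rng.integers(n)]
            bt.append(t)
            bp.append(parent)
            bc.append(next_id)
            alive.append(next_id)
            next_id += 1
        else:
            i = rng.integers(n)
            alive[i] = alive[-1]
            alive.pop()
    while gi < grid.size:
        counts[gi] = len(alive)
        gi += 1
    return PopulationTrace(
        times=grid, counts=counts,
        birth_times=np.asarray(bt), birth_parents=np.asarray(bp, dtype=int),
        birth_children=np.asarray(bc, dtype=int),
        alive=np.asarray(alive, dtype=int), t_end=float(t_end), model=model,
        extinct=len(alive) == 0)


# ---------------------------------------------------------------------------
# genealogy sampling
# ---------------------------------------------------------------------------

class _Lineage:
    __slots__ = ("node", "divisions")

    def __init__(self, node):
        self.node = node
        self.divisions = 0


def sample_phylogeny(trace: PopulationTrace, n_tips: int,
                     mutations_per_division: float | None = None,
                     seed=None) -> Phylogeny:
    """Genealogy of uniformly sampled extant cells with Poisson mutations.

    Tips are drawn without replacement from the cells alive at ``t_end``
    (isochronous sampling).  Walking the birth-event log backward, every
    division a lineage passes through contributes a Poisson draw of new
    mutations (mean ``mutations_per_division``) to that branch -- both
    daughters mutate independently -- so branch lengths are integer mutation
    counts and mutationless early divisions become zero-length edges.
    Chronological node times (weeks) are kept on ``node.time``.
    """
    if trace.extinct:
        raise ValueError("population went extinct; resample the trace")
    if n_tips > trace.final_size:
        raise ValueError(f"requested {n_tips} tips but only "
                         f"{trace.final_size} cells are extant")
    m = (trace.model.mutations_per_division
         if mutations_per_division is None else mutations_per_division)
    rng = np.random.default_rng(seed)

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    sampled = rng.permutation(rng.choice(trace.alive, size=n_tips,
                                         replace=False))
    active: dict[int, _Lineage] = {}
    for i, cell in enumerate(sampled):
        node = dendropy.Node()
        node.taxon = taxa.new_taxon(label=f"c{i:04d}|")
        node.time = trace.t_end
        active[int(cell)] = _Lineage(node)

    order = np.argsort(trace.birth_times)[::-1]
    for j in order:
        t = float(trace.birth_times[j])
        parent = int(trace.birth_parents[j])
        child = int(trace.birth_children[j])
        lp = active.get(parent)
        lc = active.get(child)
        if lp is None and lc is None:
            continue
        if lp is not None and lc is not None:
            # coalescence: finalise both branches at this division
            joint = dendropy.Node()
            joint.time = t
            for lin in (lp, lc):
                lin.divisions += 1
                lin.node.edge.length = int(rng.poisson(m * lin.divisions))
                joint.add_child(lin.node)
            del active[child]
            active[parent] = _Lineage(joint)
        elif lc is not None:
            lc.divisions += 1
            active[parent] = lc
            del active[child]
        else:
            lp.divisions += 1
    (root_lin,) = active.values()
    root_lin.node.edge.length = int(rng.poisson(m * root_lin.divisions))
    origin = dendropy.Node()
    origin.time = 0.0
    origin.edge.length = 0
    origin.add_child(root_lin.node)
    tree.seed_node = origin
    return Phylogeny(tree, units="mutations")


def kingman_tree(n_tips: int, n_tau: float, seed=None,
                 tip_age: float = 0.0) -> Phylogeny:
    """Constant-size Kingman coalescent tree (pairwise rate 1 / n_tau).

    Branch lengths are chronological, in the units of ``n_tau`` (e.g.
    HSC-weeks).  This is the independent oracle for skyline estimation.
    """
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for i in range(n_tips):
        node = dendropy.Node()
        node.taxon = taxa.new_taxon(label=f"c{i:04d}|")
        node.age_bk = 0.0
        nodes.append(node)
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(n_tau / (k * (k - 1) / 2.0))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = nodes[i], nodes[j]
        parent = dendropy.Node()
        parent.age_bk = t
        for c in (a, b):
            c.edge.length = t - c.age_bk
            parent.add_child(c)
        nodes = [n for q, n in enumerate(nodes) if q not in (i, j)]
        nodes.append(parent)
    tree.seed_node = nodes[0]
    tree.seed_node.edge.length = 0.0
    return Phylogeny(tree, units="time")


# ---------------------------------------------------------------------------
# hidden-state labelling
# ---------------------------------------------------------------------------

_EMB, _HSC, _MPP = 0, 1, 2
_STATE_NAMES = ("EMB", "HSC", "MPP")


def label_states(phylo: Phylogeny, params: StateTransitionParams,
                 seed=None) -> Phylogeny:
    """Evolve heritable EMB/HSC/MPP states down the tree, one mutation a step.

    The root is EMB and stays EMB for the first ``emb_lock`` mutations of
    molecular time; afterwards each mutation step applies the transition
    probabilities.  Tip phenotype equals the tip's true state, optionally
    corrupted at rate ``phenotype_error``; a tip still EMB at sampling is
    resolved to HSC or MPP in proportion to the EMB exit probabilities (the
    sorted compartments contain no embryonic cells).
    """
    rng = np.random.default_rng(seed)
    out = phylo.clone()
    P = np.array([
        [1 - params.p_emb_to_hsc - params.p_emb_to_mpp,
         params.p_emb_to_hsc, params.p_emb_to_mpp],
        [0.0, 1 - params.p_hsc_to_mpp, params.p_hsc_to_mpp],
        [0.0, params.p_mpp_to_hsc, 1 - params.p_mpp_to_hsc],
    ])
    cum = P.cumsum(axis=1)
    times = out.node_times()
    root = out.tree.seed_node
    root.state = "EMB"
    for node in out.tree.preorder_node_iter():
        if node is root:
            continue
        parent = node.parent_node
        s = _STATE_NAMES.index(parent.state)
        t0 = int(round(times[parent]))
        L = int(round(node.edge.length or 0))
        steps = np.arange(t0 + 1, t0 + L + 1)
        u = rng.uniform(size=L)
        for step, uu in zip(steps, u):
            if step <= params.emb_lock:
                continue
            s = int(np.searchsorted(cum[s], uu, side="right"))
        node.state = _STATE_NAMES[s]
        if not node.is_leaf():
            node.label = node.state
        else:
            pheno = node.state
            if pheno == "EMB":
                pe = params.p_emb_to_hsc + params.p_emb_to_mpp
                p_hsc = params.p_emb_to_hsc / pe if pe > 0 else 0.5
                pheno = "HSC" if rng.uniform() < p_hsc else "MPP"
            if params.phenotype_error > 0 and rng.uniform() < params.phenotype_error:
                pheno = "MPP" if pheno == "HSC" else "HSC"
            colony = Phylogeny.tip_colony(node)
            node.taxon.label = f"{colony}|{pheno}"
    return out


# ---------------------------------------------------------------------------
# genotype matrices with planted artefacts
# ---------------------------------------------------------------------------

DEFAULT_ARTIFACTS = {"strand_bias": 5, "low_vaf": 5, "homopolymer": 5,
                     "clustered": 4}


def simulate_genotype_matrix(phylo: Phylogeny, mean_depth: float = 14.0,
                             n_germline: int = 30,
                             artifact_spec: dict | None = None,
                             seed=None, infinite_depth: bool = False,
                             ) -> ColonyGenotypeMatrix:
    """Colony genotype matrix for a simulated phylogeny with planted truth.

    Each branch's mutations become sites present at VAF 0.5 in the branch's
    descendant colonies; reads are binomial at Poisson-distributed per-site
    depth (published average 14x).  Germline sites are mutant in every colony
    at VAF 0.5.  Artifact classes targeted by the filter suite are injected
    per ``artifact_spec`` (counts per class): 'strand_bias' (all mutant reads
    on one strand), 'low_vaf' (a ~5% VAF contaminant present across
    colonies), 'homopolymer' (adjacent repeat length 6) and 'clustered'
    (pairs of sites 5 bp apart).  The ``truth`` column keeps the labels:
    'somatic', 'somatic_truncal' (stem variants carried by every colony,
    indistinguishable from germline by construction), 'germline' or the
    artifact class.  ``infinite_depth`` gives exact VAFs (carrier 0.5,
    non-carrier 0) for clean-matrix tests.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = np.random.default_rng(seed)
    art = dict(DEFAULT_ARTIFACTS) if artifact_spec is None else dict(artifact_spec)
    colonies = [Phylogeny.tip_colony(t) for t in phylo.tips()]
    n_col = len(colonies)
    col_index = {c: i for i, c in enumerate(colonies)}

    rows = []          # (site_id, carriers mask, truth, hp_len, d_snv, d_indel)
    sid = 0

    def add(mask, truth, hp=2, d_snv=1000, d_indel=1000):
        nonlocal sid
        rows.append((f"s{sid:05d}", mask, truth, hp, d_snv, d_indel))
        sid += 1

    for node in phylo.tree.preorder_node_iter():
        L = int(round(node.edge.length or 0))
        if L == 0 or node.parent_node is None:
            continue
        mask = np.zeros(n_col, dtype=bool)
        for tip in node.leaf_iter():
            mask[col_index[Phylogeny.tip_colony(tip)]] = True
        truth = "somatic_truncal" if mask.all() else "somatic"
        for _ in range(L):
            add(mask.copy(), truth)
    all_mask = np.ones(n_col, dtype=bool)
    for _ in range(n_germline):
        add(all_mask.copy(), "germline")
    for _ in range(art.get("strand_bias", 0)):
        mask = rng.uniform(size=n_col) < 0.4
        mask[rng.integers(n_col)] = True
        add(mask, "artifact_strand")
    for _ in range(art.get("low_vaf", 0)):
        add(all_mask.copy(), "artifact_low_vaf")
    for _ in range(art.get("homopolymer", 0)):
        mask = rng.uniform(size=n_col) < 0.4
        mask[rng.integers(n_col)] = True
        add(mask, "artifact_homopolymer", hp=6)
    for _ in range(art.get("clustered", 0)):
        mask = rng.uniform(size=n_col) < 0.4
        mask[rng.integers(n_col)] = True
        add(mask, "artifact_clustered", d_snv=5)

    n_sites = len(rows)
    if infinite_depth:
        depth = np.full((n_sites, n_col), 1000, dtype=int)
    else:
        depth = rng.poisson(mean_depth, size=(n_sites, n_col))
    alt = np.zeros_like(depth)
    fwd = np.zeros_like(depth)
    for i, (_, mask, truth, *_rest) in enumerate(rows):
        if truth == "artifact_low_vaf":
            alt[i] = rng.binomial(depth[i], 0.05)
        elif infinite_depth:
            alt[i, mask] = depth[i, mask] // 2
        else:
            alt[i, mask] = rng.binomial(depth[i, mask], 0.5)
        if truth == "artifact_strand":
            fwd[i] = alt[i]
        else:
            fwd[i] = rng.binomial(alt[i], 0.5)
    sites = pd.DataFrame(
        {"ref": "C", "alt": "T", "vclass": "SNV",
         "homopolymer_len": [r[3] for r in rows],
         "dist_snv": [r[4] for r in rows],
         "dist_indel": [r[5] for r in rows],
         "truth": [r[2] for r in rows]},
        index=pd.Index([r[0] for r in rows], name="site_id"))
    mk = lambda a: pd.DataFrame(a, index=sites.index, columns=colonies)
    return ColonyGenotypeMatrix(sites, mk(depth), mk(alt), mk(fwd))


# ---------------------------------------------------------------------------
# duplex VAF spectra from the branching model
# ---------------------------------------------------------------------------

def _bd_clone_sizes(ages: np.ndarray, s: np.ndarray, tau: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Exact clone sizes of mutant lineages under linear birth-death.

    Each lineage starts from one cell with birth rate b = 1/tau + s and death
    rate d = 1/tau (all rates per year; s is the annual growth advantage).
    Sizes are drawn from the exact transition law at age a: extinct with
    probability alpha, else geometric with parameter beta.  Extinct clones
    return size 0.
    """
    b = 1.0 / tau + s
    d = np.full_like(b, 1.0 / tau)
    sizes = np.zeros(ages.size, dtype=np.int64)
    crit = np.abs(s) < 1e-12
    if crit.any():
        x = ages[crit] / tau                      # b*a for the critical case
        ab = x / (1.0 + x)
        surv = rng.uniform(size=ab.size) >= ab
        n = np.zeros(ab.size, dtype=np.int64)
        if surv.any():
            n[surv] = rng.geometric(1.0 - ab[surv])
        sizes[crit] = n
    sup = ~crit
    if sup.any():
        E = np.exp(s[sup] * ages[sup])
        denom = b[sup] * E - d[sup]
        alpha = d[sup] * (E - 1.0) / denom
        beta = b[sup] * (E - 1.0) / denom
        surv = rng.uniform(size=alpha.size) >= alpha
        n = np.zeros(alpha.size, dtype=np.int64)
        if surv.any():
            n[surv] = rng.geometric(np.clip(1.0 - beta[surv], 1e-15, 1.0))
        sizes[sup] = n
    return sizes


def sample_dfe(n: int, scale: float, beta: float,
               rng: np.random.Generator) -> np.ndarray:
    """Draw fitness effects from the exponential-power density ~ exp(-(s/d)^b).

    With y = (s/d)^b the density over y is Gamma(1/b, 1), giving the exact
    inverse transform s = d * Gamma(1/b)^(1/b).
    """
    y = rng.gamma(1.0 / beta, 1.0, size=n)
    return scale * y ** (1.0 / beta)


def simulate_duplex_vafs(n_tau: float = 16_500.0, tau_weeks: float = 6.4,
                         mu_neutral: float = 1.8e-4, mu_ns: float = 3.4e-4,
                         dfe_scale: float = 2.0, dfe_beta: float = 3.0,
                         nonneutral_frac: float = 0.12, age_t: float = 2.0,
                         vaf_floor: float = 5e-5, cohort_size: int = 60,
                         seed=None) -> VAFSpectrum:
    """Forward-simulated duplex VAF spectrum for a cohort of aged mice.

    Variants enter each animal's stem-cell pool at rate N * mu per year
    (mu is the panel-wide rate per cell per year; N = n_tau / tau) at uniform
    times over life, and each mutant lineage evolves as a conditioned linear
    birth-death process within the host population (exact transition law, see
    :func:`_bd_clone_sizes`).  Synonymous/intronic variants are neutral
    (s = 0); a fraction ``nonneutral_frac`` of non-synonymous variants draw s
    from the exponential-power fitness distribution (scale ``dfe_scale``,
    shape ``dfe_beta``).  VAF = clone size / 2N; VAFs below ``vaf_floor`` are
    censored, emulating the duplex detection limit.
    """
    if min(n_tau, tau_weeks, age_t) <= 0:
        raise ValueError("n_tau, tau_weeks and age_t must be positive")
    if min(mu_neutral, mu_ns) < 0:
        raise ValueError("mutation rates must be >= 0")
    rng = np.random.default_rng(seed)
    tau = tau_weeks / WEEKS_PER_YEAR        # years between symmetric divisions
    N = n_tau / tau
    frames = []
    for vclass, mu, w_sel in (("synonymous", mu_neutral, 0.0),
                              ("non-synonymous", mu_ns, nonneutral_frac)):
        if mu == 0:
            continue
        k = rng.poisson(N * mu * age_t * cohort_size)
        if k == 0:
            continue
        ages = age_t - rng.uniform(0.0, age_t, size=k)
        s = np.zeros(k)
        if w_sel > 0:
            sel = rng.uniform(size=k) < w_sel
            s[sel] = sample_dfe(int(sel.sum()), dfe_scale, dfe_beta, rng)
        sizes = _bd_clone_sizes(ages, s, tau, rng)
        vaf = np.minimum(sizes / (2.0 * N), 0.5)
        keep = vaf >= vaf_floor
        frames.append(pd.DataFrame({"vaf": vaf[keep], "vclass": vclass,
                                    "s_true": s[keep]}))
    variants = (pd.concat(frames, ignore_index=True) if frames
                else pd.DataFrame(columns=["vaf", "vclass", "s_true"]))
    return VAFSpectrum(variants=variants, age_t=age_t, vaf_floor=vaf_floor,
                       cohort_size=cohort_size)


# ---------------------------------------------------------------------------
# deterministic trajectory + time-rescaled coalescent (fast path for ABC)
# ---------------------------------------------------------------------------

def trajectory_segments(model: PopModel, t_end: float) -> list:
    """Deterministic piecewise-exponential population trajectory.

    Returns segments (t0, t1, n0, r, b): within [t0, t1] the population is
    n0 * exp(r (t - t0)) and each cell divides at rate b per week.  Growth
    r = lambda - nu until the epoch cap is reached; at the cap the size is
    flat and divisions only replace exits (b = nu), matching birth
    suppression in the event simulator.
    """
    segs = []
    t, n = 0.0, 1.0
    acc = 0.0
    for ep in model.epochs:
        acc = acc + ep.duration
        t_stop = min(acc, t_end)
        while t < t_stop - 1e-12:
            r = ep.lam - ep.nu
            if n >= ep.cap - 1e-9:
                segs.append((t, t_stop, ep.cap, 0.0, ep.nu))
                n = ep.cap
                t = t_stop
            elif r <= 0:
                segs.append((t, t_stop, n, 0.0, ep.lam))
                t = t_stop
            else:
                t_hit = t + math.log(ep.cap / n) / r
                if t_hit >= t_stop:
                    segs.append((t, t_stop, n, r, ep.lam))
                    n = n * math.exp(r * (t_stop - t))
                    t = t_stop
                else:
                    segs.append((t, t_hit, n, r, ep.lam))
                    n = ep.cap
                    t = t_hit
        if t >= t_end - 1e-12:
            break
    return segs


def sample_coalescent_ages(segments: list, n_tips: int, t_sample: float,
                           rng: np.random.Generator,
                           rate_factor: float = 2.0) -> np.ndarray:
    """Backward coalescent ages (before ``t_sample``) within a trajectory.

    The pairwise coalescence rate at forward time t is
    ``rate_factor * b(t) / N(t)`` -- the exact genealogy rate of a forward
    birth-death/Moran population is 2 b / N (each division event creates one
    daughter pair).  Waiting times are drawn by exact time rescaling within
    each piecewise-exponential segment.  Lineages that fail to coalesce by
    the founding time are merged there (the population starts from one cell).
    Returns the n_tips - 1 coalescence ages, sorted ascending.
    """
    segs = [s for s in segments if s[0] < t_sample]
    ages = []
    k = n_tips
    age = 0.0                      # time before t_sample
    si = len(segs) - 1
    while k > 1 and si >= 0:
        t0, t1, n0, r, b = segs[si]
        t1 = min(t1, t_sample)
        # backward position within the segment: forward time t_sample - age
        x = (t_sample - age) - t0     # backward room left in this segment
        if x <= 0:
            si -= 1
            continue
        # N at forward time u = n0 exp(r (u - t0)); pair rate c(u) = f*b/N(u)
        # going backward from forward position t0 + x with age increment a:
        # c(a) = f*b/n0 * exp(-r (x - a)); integrated inverse is closed-form.
        pair = k * (k - 1) / 2.0
        if b <= 0:
            age += x
            si -= 1
            continue
        base = rate_factor * b / (n0 * math.exp(r * x))   # rate at entry
        E = rng.exponential()
        if r == 0:
            wait = E / (pair * base)
        else:
            arg = 1.0 + E * r / (pair * base)
            wait = math.log(arg) / r
        if wait < x:
            age += wait
            ages.append(age)
            k -= 1
        else:
            age += x
            si -= 1
    while k > 1:                   # founding cell: force remaining merges
        ages.append(t_sample)
        k -= 1
    return np.asarray(ages)
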