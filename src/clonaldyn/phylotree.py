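"""Colony phylogenies and molecular-time analytics.

A :class:`Phylogeny` is a rooted tree whose branch lengths count somatic
mutations ("molecular time"): every tip is a single-cell-derived colony
labelled ``colonyID|PHENOTYPE`` (phenotype HSC or MPP), and every filtered
variant is assigned to exactly one branch.  On top of this container the
module provides:

* a perfect-phylogeny tree builder with likelihood-based variant placement
  (maximum-parsimony search is upstream and out of scope; filtered colony
  matrices are near conflict-free),
* sensitivity normalisation of branch lengths,
* clade partitions at a molecular-time cutoff and their Shannon diversity,
* the early-life polytomy estimator of mutations per cell division,
* the HSC/MPP clade mixing metric with its label-reshuffling null,
* directional ("HSC-first"/"MPP-first") state-change parsimony counts,
* blood/colonic-crypt shared-variant positivity, and
* aggregate lineage VAF trajectories from targeted recapture of tree
  variants in blood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .variant_filters import ColonyGenotypeMatrix, PRESENT, ABSENT

__all__ = [
    "Phylogeny", "CladePartition", "build_tree", "normalize_branch_lengths",
    "clades_at_time", "shannon_diversity", "polytomy_mutation_rate",
    "mutation_rate_from_counts", "mixing_metric", "mixing_null",
    "count_state_changes", "crypt_sharing", "lineage_vaf_trajectory",
    "collapse_zero_branches",
]


class Phylogeny:
    """Rooted tree with mutation-count branch lengths and annotated tips.

    Thin wrapper around a :class:`dendropy.Tree`.  Tip taxa are labelled
    ``colonyID|PHENOTYPE``; node annotations may carry the chronological time
    (``time``, weeks), the true or decoded hidden state (``state``) and
    per-branch variant id lists (``node.variants``).  ``units`` records
    whether edge lengths are mutation counts or chronological time.
    """

    def __init__(self, tree: dendropy.Tree, units: str = "mutations"):
        self.tree = tree
        self.units = units

    # -- construction ------------------------------------------------------
    @classmethod
    def from_newick(cls, src: str, units: str = "mutations") -> "Phylogeny":
        if "\n" not in src and not src.strip().endswith(";"):
            with open(src) as fh:
                src = fh.read()
        tree = dendropy.Tree.get(data=src, schema="newick",
                                 suppress_internal_node_taxa=True,
                                 extract_comment_metadata=True)
        return cls(tree, units=units)

    def to_newick(self, path: str | None = None) -> str:
        s = self.tree.as_string(schema="newick", suppress_annotations=False,
                                suppress_rooting=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    def clone(self) -> "Phylogeny":
        return Phylogeny(self.tree.clone(depth=1), units=self.units)

    # -- basic accessors ---------------------------------------------------
    @property
    def root(self):
        return self.tree.seed_node

    def tips(self):
        return self.tree.leaf_node_iter()

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    @staticmethod
    def tip_colony(node) -> str:
        return node.taxon.label.split("|")[0]

    @staticmethod
    def tip_phenotype(node) -> str:
        label = node.taxon.label
        return label.split("|")[1] if "|" in label else ""

    def phenotypes(self) -> dict:
        return {self.tip_colony(t): self.tip_phenotype(t) for t in self.tips()}

    def node_times(self) -> dict:
        """Molecular (or chronological) time of each node measured from root."""
        times = {}
        for node in self.tree.preorder_node_iter():
            parent = node.parent_node
            edge = node.edge.length or 0.0
            times[node] = edge if parent is None else times[parent] + edge
        return times

    def total_branch_length(self) -> float:
        return sum(n.edge.length or 0.0 for n in self.tree.preorder_node_iter())


@dataclass
class CladePartition:
    """Clades whose stem branch crosses molecular time t (inclusive of t).

    Tips whose own path ends before t form singleton clades, so the clades
    always partition the tips.
    """
    cutoff: float
    clades: list          # list of lists of tip nodes
    phylogeny: Phylogeny

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.clades]

    def phenotype_counts(self) -> list[dict]:
        out = []
        for clade in self.clades:
            counts: dict = {}
            for tip in clade:
                ph = Phylogeny.tip_phenotype(tip)
                counts[ph] = counts.get(ph, 0) + 1
            out.append(counts)
        return out


# ---------------------------------------------------------------------------
# tree building
# ---------------------------------------------------------------------------

def _laminar_compatible(a: frozenset, b: frozenset) -> bool:
    return a.isdisjoint(b) or a <= b or b <= a


def build_tree(matrix: ColonyGenotypeMatrix, max_conflict_frac: float = 0.05,
               placement_error: float = 1e-3, het_vaf: float = 0.5,
               ) -> Phylogeny:
    """Build a colony phylogeny from a filtered genotype matrix.

    The topology is the perfect phylogeny implied by the laminar family of
    variant carrier sets (Present calls); conflicting carrier sets (four-
    gamete violations) are resolved by keeping, in decreasing order of
    supporting-variant count, only sets compatible with those already kept.
    If more than ``max_conflict_frac`` of variants sit on discarded sets an
    error advises supplying an externally built Newick tree instead.

    Every variant (including those on discarded sets) is then assigned to the
    branch maximising a per-colony binomial read-count likelihood: carrier
    colonies at heterozygous VAF, non-carriers at ``placement_error``;
    colonies with zero depth are uninformative and never veto a placement.
    Branch length = number of variants assigned to the branch.
    """
    geno = matrix.genotypes()
    colonies = matrix.colonies
    n_col = len(colonies)
    if n_col < 2:
        raise ValueError("need at least two colonies to build a tree")

    carrier_sets: dict[frozenset, list] = {}
    for sid in matrix.sites.index:
        carriers = frozenset(c for c in colonies if geno.at[sid, c] == PRESENT)
        if 0 < len(carriers):
            carrier_sets.setdefault(carriers, []).append(sid)

    # keep a laminar subfamily, largest variant support first
    full = frozenset(colonies)
    ranked = sorted(carrier_sets.items(),
                    key=lambda kv: (-len(kv[1]), -len(kv[0]), sorted(kv[0])))
    kept: list[frozenset] = []
    n_conflict = 0
    for cset, sids in ranked:
        if all(_laminar_compatible(cset, k) for k in kept):
            kept.append(cset)
        else:
            n_conflict += len(sids)
    n_total = sum(len(s) for s in carrier_sets.values())
    if n_total and n_conflict / n_total > max_conflict_frac:
        raise ValueError(
            f"{n_conflict}/{n_total} variants sit on conflicting carrier sets; "
            "matrix is not close to a perfect phylogeny -- supply an external "
            "Newick tree instead")

    # nest the laminar family into a tree
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    clades = sorted(set(kept) | {full} | {frozenset([c]) for c in colonies},
                    key=lambda s: (-len(s), sorted(s)))
    node_of: dict[frozenset, dendropy.Node] = {}
    for cset in clades:
        node = tree.seed_node if cset == full else dendropy.Node()
        node.edge.length = 0
        node.variants = []
        node_of[cset] = node
        if cset != full:
            parent = min((k for k in node_of if cset < k), key=len)
            node_of[parent].add_child(node)
    for c in colonies:
        node = node_of[frozenset([c])]
        node.taxon = taxa.new_taxon(label=f"{c}|")
    tree.encode_bipartitions(suppress_unifurcations=False)

    # likelihood placement of every variant on a branch
    branch_nodes = [n for n in tree.preorder_node_iter() if n is not tree.seed_node]
    branch_sets = []
    for n in branch_nodes:
        tipset = frozenset(t.taxon.label.split("|")[0] for t in n.leaf_iter())
        branch_sets.append(tipset)
    depth = matrix.depth.to_numpy(float)
    alt = matrix.alt.to_numpy(float)
    col_index = {c: i for i, c in enumerate(colonies)}
    masks = np.zeros((len(branch_nodes), n_col), dtype=bool)
    for bi, tipset in enumerate(branch_sets):
        for c in tipset:
            masks[bi, col_index[c]] = True
    for si, sid in enumerate(matrix.sites.index):
        d, a = depth[si], alt[si]
        with np.errstate(divide="ignore"):
            ll_mut = stats.binom.logpmf(a, d, het_vaf)
            ll_wt = stats.binom.logpmf(a, d, placement_error)
        ll_mut = np.where(d > 0, ll_mut, 0.0)
        ll_wt = np.where(d > 0, ll_wt, 0.0)
        scores = masks @ ll_mut + (~masks) @ ll_wt
        best = branch_nodes[int(np.argmax(scores))]
        best.variants.append(sid)
    for n in branch_nodes:
        n.edge.length = len(n.variants)
    tree.seed_node.variants = []
    tree.seed_node.edge.length = 0
    return Phylogeny(tree, units="mutations")


def normalize_branch_lengths(phylo: Phylogeny, sensitivity: dict) -> Phylogeny:
    """Divide branch lengths by mutation-detection sensitivity.

    Terminal branches use the colony's own sensitivity (in (0, 1]); internal
    branches the mean sensitivity of their descendant colonies.  Lengths are
    rounded to the nearest integer so molecular-time operations stay on the
    per-mutation lattice.
    """
    for s in sensitivity.values():
        if not (0 < s <= 1):
            raise ValueError(f"sensitivity must be in (0, 1], got {s}")
    out = phylo.clone()
    for node in out.tree.preorder_node_iter():
        if node is out.tree.seed_node:
            continue
        cols = [Phylogeny.tip_colony(t) for t in node.leaf_iter()]
        s = float(np.mean([sensitivity[c] for c in cols]))
        node.edge.length = int(round((node.edge.length or 0) / s))
    return out


def collapse_zero_branches(phylo: Phylogeny, tol: float = 0.0) -> Phylogeny:
    """Collapse internal edges of length <= tol into polytomies."""
    out = phylo.clone()
    out.tree.collapse_unweighted_edges(threshold=tol)
    return out


# ---------------------------------------------------------------------------
# clades, diversity, polytomies
# ---------------------------------------------------------------------------

def clades_at_time(phylo: Phylogeny, t: float) -> CladePartition:
    """Partition tips into the clades whose stem crosses molecular time t.

    A clade is rooted at the first node whose parent branch crosses t
    (crossing inclusive of t); tips whose total path length is below t form
    singleton clades.
    """
    if t < 0:
        raise ValueError("cutoff must be non-negative")
    times = phylo.node_times()
    clades = []
    stack = [phylo.root]
    while stack:
        node = stack.pop()
        nt = times[node]
        parent = node.parent_node
        pt = times[parent] if parent is not None else 0.0
        if (parent is not None and pt < t <= nt) or (node.is_leaf() and nt < t):
            clades.append(list(node.leaf_iter()))
        elif node.is_leaf() and nt >= t and parent is None:
            clades.append([node])
        else:
            stack.extend(node.child_nodes())
    # root-degenerate case: whole tree below t
    if not clades:
        clades = [list(phylo.tips())]
    return CladePartition(cutoff=t, clades=clades, phylogeny=phylo)


def shannon_diversity(partition: CladePartition) -> float:
    """Shannon index H = -sum p_i ln p_i over clade tip shares."""
    sizes = np.asarray(partition.sizes, dtype=float)
    p = sizes / sizes.sum()
    return float(-(p * np.log(p)).sum())


def mutation_rate_from_counts(n_silent: int, n_divisions: int,
                              conf: float = 0.95) -> dict:
    """Poisson mutations-per-division estimate from silent-division counts.

    With z of n ancestral symmetric divisions mutationally silent, the
    Poisson zero-class identity gives m = -ln(z/n).  The interval maps the
    Wilson score CI for the silent proportion through -ln.
    """
    if not 0 <= n_silent <= n_divisions or n_divisions <= 0:
        raise ValueError("need 0 <= n_silent <= n_divisions, n_divisions > 0")
    if n_silent == 0:
        z = stats.norm.ppf(0.5 + conf / 2)
        lo_p = 0.0  # unbounded point estimate; report lower CI only
        hi_p = (z * z / 2) / (n_divisions + z * z)
        return {"m": math.inf, "ci": (-math.log(hi_p), math.inf),
                "unbounded": True, "n_silent": 0, "n_divisions": n_divisions}
    p = n_silent / n_divisions
    lo_p, hi_p = stats.binomtest(n_silent, n_divisions).proportion_ci(
        confidence_level=conf, method="wilson")
    return {"m": -math.log(p), "ci": (-math.log(hi_p), -math.log(lo_p)),
            "unbounded": False, "n_silent": n_silent,
            "n_divisions": n_divisions}


def polytomy_mutation_rate(phylo: Phylogeny, t_max: float = 12,
                           min_lineages: int = 10, conf: float = 0.95) -> dict:
    """Early-life mutations-per-division estimate from polytomies.

    Counting L lineages by molecular time ``t_max`` implies L - 1 binary
    symmetric divisions; a polytomy of degree d stands for d - 2 mutationally
    silent divisions (zero-length edges under binary resolution).  The Poisson
    rate and its CI come from :func:`mutation_rate_from_counts`.  Trees with
    fewer than ``min_lineages`` lineages by ``t_max`` are rejected.
    """
    collapsed = collapse_zero_branches(phylo)
    times = collapsed.node_times()
    lineages = len(clades_at_time(collapsed, t_max).clades)
    if lineages < min_lineages:
        raise ValueError(
            f"only {lineages} lineages by {t_max} mutations "
            f"(need >= {min_lineages}): insufficient early-life diversity")
    n_divisions = lineages - 1
    n_silent = 0
    for node in collapsed.tree.preorder_internal_node_iter():
        if times[node] <= t_max:
            n_silent += max(0, len(node.child_nodes()) - 2)
    n_silent = min(n_silent, n_divisions)
    out = mutation_rate_from_counts(n_silent, n_divisions, conf=conf)
    out["n_lineages"] = lineages
    return out


# ---------------------------------------------------------------------------
# HSC/MPP mixing
# ---------------------------------------------------------------------------

def _clade_matrix(partition: CladePartition, phenotype: str = "HSC"):
    """Indicator matrix (clades x tips) and the binary phenotype vector."""
    tips = [t for clade in partition.clades for t in clade]
    labels = np.array([1.0 if Phylogeny.tip_phenotype(t) == phenotype else 0.0
                       for t in tips])
    M = np.zeros((len(partition.clades), len(tips)))
    j = 0
    for i, clade in enumerate(partition.clades):
        M[i, j:j + len(clade)] = 1.0
        j += len(clade)
    return M, labels


def mixing_metric(phylo: Phylogeny, t: float = 25.0,
                  phenotype: str = "HSC") -> float:
    """Mean absolute deviation of clade HSC fraction from the sampled fraction.

    For clades established by molecular time t, computes the unweighted mean
    over clades of |fraction(HSC in clade) - overall sampled HSC fraction|.
    0 means perfect intermixing; the maximum (phenotype-pure clades at 50:50
    sampling) is 0.5.
    """
    part = clades_at_time(phylo, t)
    M, labels = _clade_matrix(part, phenotype)
    sizes = M.sum(axis=1)
    frac = (M @ labels) / sizes
    expected = labels.mean()
    return float(np.abs(frac - expected).mean())


def mixing_null(phylo: Phylogeny, t: float = 25.0, n_perm: int = 1000,
                seed: int | None = None, phenotype: str = "HSC",
                tie_break: str = "conservative") -> dict:
    """Tip-label reshuffling null for the mixing metric with one-tailed p.

    ``tie_break='conservative'`` uses p = (1 + #{null >= obs}) / (n_perm + 1);
    ``'random'`` breaks ties uniformly, which makes the p-value exactly
    uniform under the null (useful for calibration checks).  A single clade
    leaves the metric defined but the p-value degenerate (flagged).
    """
    rng = np.random.default_rng(seed)
    part = clades_at_time(phylo, t)
    M, labels = _clade_matrix(part, phenotype)
    sizes = M.sum(axis=1)
    expected = labels.mean()

    def metric(lab_matrix):
        frac = (M @ lab_matrix) / sizes[:, None]
        return np.abs(frac - expected).mean(axis=0)

    obs = float(metric(labels[:, None])[0])
    perms = np.empty((labels.size, n_perm))
    for k in range(n_perm):
        perms[:, k] = rng.permutation(labels)
    null = metric(perms)
    greater = int((null > obs + 1e-12).sum())
    equal = int((np.abs(null - obs) <= 1e-12).sum())
    if tie_break == "random":
        p = (greater + rng.uniform() * (equal + 1)) / (n_perm + 1)
    else:
        p = (1 + greater + equal) / (n_perm + 1)
    return {"observed": obs, "null": null, "p": float(p),
            "degenerate": len(part.clades) < 2}


# ---------------------------------------------------------------------------
# directional state-change parsimony
# ---------------------------------------------------------------------------

def count_state_changes(phylo: Phylogeny, model: str = "HSC-first") -> dict:
    """Minimal irreversible identity changes explaining the tip phenotypes.

    Under the ``X-first`` model every lineage starts as X and may switch to Y
    exactly once (irreversibly); the minimal number of conversions equals the
    number of maximal all-Y subtrees.  Returns the total, the per-colony
    changes (1 for tips inside a converted subtree), and the per-colony rate.
    """
    if model == "HSC-first":
        start, derived = "HSC", "MPP"
    elif model == "MPP-first":
        start, derived = "MPP", "HSC"
    else:
        raise ValueError("model must be 'HSC-first' or 'MPP-first'")

    pure: dict = {}
    for node in phylo.tree.postorder_node_iter():
        if node.is_leaf():
            pure[node] = Phylogeny.tip_phenotype(node) == derived
        else:
            pure[node] = all(pure[c] for c in node.child_nodes())
    total = 0
    per_tip = {}
    stack = [(phylo.root, False)]
    while stack:
        node, converted = stack.pop()
        # the root is constrained to the starting state, so a conversion can
        # only occur on a branch (nodes with a parent)
        if pure[node] and not converted and node.parent_node is not None:
            total += 1
            converted = True
        if node.is_leaf():
            per_tip[Phylogeny.tip_colony(node)] = 1 if converted else 0
        else:
            stack.extend((c, converted) for c in node.child_nodes())
    n = len(per_tip)
    return {"total": total, "per_colony": per_tip,
            "per_colony_rate": total / n if n else math.nan, "model": model}


# ---------------------------------------------------------------------------
# cross-tissue sharing and blood VAF trajectories
# ---------------------------------------------------------------------------

def crypt_sharing(phylo: Phylogeny, crypt_alt: pd.DataFrame,
                  crypt_depth: pd.DataFrame, vaf_threshold: dict,
                  rescue_reads: int = 2) -> pd.Series:
    """Fraction of colonic crypts positive for each truncal branch.

    Two-tier positivity per variant: a crypt is positive when the variant's
    VAF reaches the crypt's minimum VAF threshold (half the median VAF of its
    passing variants); then, for variants represented in at least one crypt,
    any remaining crypt with more than ``rescue_reads`` mutant reads is also
    marked positive.  Zero-coverage crypts are treated as absent at that
    site.  A branch is positive in a crypt when any of its variants is.
    """
    crypts = list(crypt_alt.columns)
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = crypt_alt / crypt_depth.replace(0, np.nan)
    thr = pd.Series({c: vaf_threshold[c] for c in crypts})
    tier1 = vaf.ge(thr, axis=1).fillna(False)
    seen = tier1.any(axis=1)
    rescue = crypt_alt.gt(rescue_reads) & (crypt_depth > 0)
    positive = tier1 | rescue.loc[seen].reindex(crypt_alt.index, fill_value=False)

    out = {}
    for node in phylo.tree.preorder_node_iter():
        variants = [v for v in getattr(node, "variants", [])
                    if v in positive.index]
        if not variants:
            continue
        branch_pos = positive.loc[variants].any(axis=0)
        label = (node.taxon.label if node.is_leaf()
                 else f"branch_{id(node) % 10_000}")
        out[label] = float(branch_pos.mean())
    return pd.Series(out, name="crypt_fraction")


def vaf_posterior_mean(alt: int, depth: int) -> float:
    """Conjugate Beta(alt + 1/2, depth - alt + 1/2) posterior mean for a VAF."""
    return (alt + 0.5) / (depth + 1.0)


def lineage_vaf_trajectory(phylo: Phylogeny, branch_vafs: dict,
                           t_grid, classify=None) -> pd.DataFrame:
    """Aggregate blood VAF of tree lineages as a function of molecular time.

    ``branch_vafs`` maps a node to the estimated VAFs of its targeted
    variants.  Within a branch, variants are arranged in descending VAF at
    equally spaced molecular times down the branch and the VAF at time t is
    linearly interpolated; the aggregate at t sums the interpolated VAFs of
    all branches overlapping t.  ``classify(node) -> str`` optionally splits
    the aggregate by lineage class (for example the decoded phenotype);
    branches without targeted variants are excluded and counted.
    """
    times = phylo.node_times()
    t_grid = np.asarray(t_grid, dtype=float)
    rows: dict = {}
    n_skipped = 0
    for node, vafs in branch_vafs.items():
        if node is phylo.root:
            continue
        vafs = sorted(vafs, reverse=True)
        if not vafs:
            n_skipped += 1
            continue
        top = times[node.parent_node]
        bottom = times[node]
        if bottom <= top:
            continue
        pos = (np.linspace(top, bottom, len(vafs)) if len(vafs) > 1
               else np.array([(top + bottom) / 2.0]))
        cls = classify(node) if classify else "all"
        # np.interp clamps beyond the end positions; the overlap mask then
        # restricts the contribution to the branch's molecular-time span
        interp = np.interp(t_grid, pos, vafs)
        overlap = (t_grid >= top) & (t_grid <= bottom)
        contrib = np.where(overlap, interp, 0.0)
        rows[cls] = rows.get(cls, np.zeros_like(t_grid)) + contrib
    df = pd.DataFrame(rows, index=pd.Index(t_grid, name="molecular_time"))
    df.attrs["n_branches_without_variants"] = n_skipped
    return df
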