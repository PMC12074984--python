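"""Three-state hidden Markov tree model of haematopoietic ontogeny.

Ancestral cells carry one of three hidden identities -- embryonic precursor
(EMB), haematopoietic stem cell (HSC) or multipotent progenitor (MPP) -- and
the identity evolves down the phylogeny as a discrete-time Markov chain with
one step per somatic mutation of molecular time.  The zygote (root) is EMB
and remains EMB for the first ``emb_lock`` mutations; afterwards transitions
follow the per-mutation matrix

    EMB -> HSC, EMB -> MPP          (embryonic specification)
    HSC -> MPP, MPP -> HSC          (adult interconversion)

with EMB unreachable again (its column is zero for HSC/MPP rows).  Observed
tip phenotypes are emitted with error ``epsilon`` (match 1 - eps, mismatch
eps / 2).  The module provides branch transition matrices, the upward
(pruning) likelihood, Viterbi-style decoding of end-of-branch states,
maximum-likelihood fitting of the four transition probabilities with model
comparison, and forward state-probability trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, logsumexp, logit

from .phylotree import Phylogeny

__all__ = [
    "HiddenStateModel", "DecodedTree", "STATES", "branch_transition",
    "tree_loglikelihood", "viterbi_decode", "fit_transition_rates",
    "compare_nested", "state_trajectory",
]

# fixed state order; also the tie-break order for decoding
STATES = ("EMB", "HSC", "MPP")
EMB, HSC, MPP = 0, 1, 2


@dataclass(frozen=True)
class HiddenStateModel:
    """Per-mutation transition probabilities, emission error and root prior."""
    p_hsc_to_mpp: float
    p_mpp_to_hsc: float
    p_emb_to_hsc: float
    p_emb_to_mpp: float
    epsilon: float = 1e-12
    emb_lock: int = 10

    def __post_init__(self):
        for name in ("p_hsc_to_mpp", "p_mpp_to_hsc",
                     "p_emb_to_hsc", "p_emb_to_mpp", "epsilon"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.p_emb_to_hsc + self.p_emb_to_mpp > 1.0 + 1e-12:
            raise ValueError("EMB exit probabilities exceed 1")

    @property
    def matrix(self) -> np.ndarray:
        """Row-stochastic per-mutation transition matrix in STATES order."""
        pHM, pMH = self.p_hsc_to_mpp, self.p_mpp_to_hsc
        pEH, pEM = self.p_emb_to_hsc, self.p_emb_to_mpp
        return np.array([
            [1.0 - pEH - pEM, pEH, pEM],
            [0.0, 1.0 - pHM, pHM],
            [0.0, pMH, 1.0 - pMH],
        ])

    @property
    def root_prior(self) -> np.ndarray:
        return np.array([1.0, 0.0, 0.0])   # EMB with probability one


@dataclass
class DecodedTree:
    """Most likely end-of-branch states with the path log-probability."""
    states: dict                      # node -> state name
    log_prob: float
    transitions: dict                 # (from, to) -> branch count


def branch_transition(model: HiddenStateModel, length: int) -> np.ndarray:
    """Transition matrix over a branch of ``length`` mutations, M^length.

    The caller supplies the effective length, already excluding any overlap
    with the EMB-locked first ``emb_lock`` mutations (the locked stretch is
    an identity step because the root prior pins the state to EMB there).
    """
    if length < 0:
        raise ValueError("branch length must be >= 0")
    return np.linalg.matrix_power(model.matrix, int(length))


def _effective_lengths(phylo: Phylogeny, lock: int) -> dict:
    """Integer branch lengths minus their overlap with molecular time < lock."""
    times = phylo.node_times()
    out = {}
    for node in phylo.tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        top, bottom = times[parent], times[node]
        eff = max(0.0, bottom - max(top, lock))
        out[node] = int(round(eff))
    return out


def _tip_emission_log(phylo: Phylogeny, eps: float) -> dict:
    out = {}
    for tip in phylo.tips():
        pheno = Phylogeny.tip_phenotype(tip)
        if pheno not in ("HSC", "MPP"):
            raise ValueError(f"tip {tip.taxon.label!r} lacks an HSC/MPP phenotype")
        obs = STATES.index(pheno)
        e = np.full(3, 0.5 * eps)
        e[obs] = 1.0 - eps
        with np.errstate(divide="ignore"):
            out[tip] = np.log(e)
    return out


def tree_loglikelihood(phylo: Phylogeny, model: HiddenStateModel) -> float:
    """Upward (pruning) log-likelihood of the observed tip phenotypes.

    log P = log sum_i pi_i P_root(D_root | i), computed in log space by
    postorder recursion; independent of child-visit order.
    """
    eff = _effective_lengths(phylo, model.emb_lock)
    emis = _tip_emission_log(phylo, model.epsilon)
    # unique branch lengths share one matrix power
    powers = {L: branch_transition(model, L) for L in set(eff.values())}
    logP: dict = {}
    with np.errstate(divide="ignore"):
        for node in phylo.tree.postorder_node_iter():
            if node.is_leaf():
                logP[node] = emis[node]
            else:
                acc = 0.0
                for child in node.child_nodes():
                    lp = logP[child]
                    c = lp.max()
                    # log(M @ exp(lp)) with scaling; exact log-sum-exp
                    acc = acc + np.log(powers[eff[child]]
                                       @ np.exp(lp - c)) + c
                logP[node] = acc
        log_pi = np.log(model.root_prior)
        return float(logsumexp(log_pi + logP[phylo.root]))


def viterbi_decode(phylo: Phylogeny, model: HiddenStateModel) -> DecodedTree:
    """Most likely assignment of end-of-branch hidden states.

    Runs the max-product analogue of the upward algorithm (delta / psi
    recursion) and backtracks from the root, whose state is fixed by the
    prior (EMB).  Ties are broken toward the lower state index in
    EMB < HSC < MPP order.
    """
    eff = _effective_lengths(phylo, model.emb_lock)
    emis = _tip_emission_log(phylo, model.epsilon)
    with np.errstate(divide="ignore"):
        logM = {node: np.log(branch_transition(model, L))
                for node, L in eff.items()}
    delta: dict = {}
    psi: dict = {}
    for node in phylo.tree.postorder_node_iter():
        if node.is_leaf():
            delta[node] = emis[node]
        else:
            acc = np.zeros(3)
            for child in node.child_nodes():
                scores = logM[child] + delta[child][None, :]   # (i, k)
                psi[child] = np.argmax(scores, axis=1)
                acc = acc + np.max(scores, axis=1)
            delta[node] = acc
    with np.errstate(divide="ignore"):
        log_pi = np.log(model.root_prior)
    root_scores = log_pi + delta[phylo.root]
    root_state = int(np.argmax(root_scores))
    states = {phylo.root: STATES[root_state]}
    transitions: dict = {}
    stack = [(phylo.root, root_state)]
    while stack:
        node, i = stack.pop()
        for child in node.child_nodes():
            k = int(psi[child][i]) if child in psi else int(
                np.argmax(logM[child][i] + emis[child]))
            states[child] = STATES[k]
            if i != k:
                key = (STATES[i], STATES[k])
                transitions[key] = transitions.get(key, 0) + 1
            stack.append((child, k))
    return DecodedTree(states=states, log_prob=float(np.max(root_scores)),
                       transitions=transitions)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _model_from_vector(x: np.ndarray, constraint: str, base: HiddenStateModel
                       ) -> HiddenStateModel:
    p = expit(x)
    if constraint == "hsc_first":
        return replace(base, p_hsc_to_mpp=p[0], p_mpp_to_hsc=p[1],
                       p_emb_to_hsc=p[2], p_emb_to_mpp=0.0)
    return replace(base, p_hsc_to_mpp=p[0], p_mpp_to_hsc=p[1],
                   p_emb_to_hsc=p[2], p_emb_to_mpp=p[3])


def fit_transition_rates(trees, grouping: dict | None = None,
                         constraint: str = "none", n_restarts: int = 8,
                         seed: int = 0, epsilon: float = 1e-12,
                         emb_lock: int = 10, maxiter: int = 2000) -> dict:
    """Maximum-likelihood transition probabilities, optionally per group.

    ``trees`` is a list of phylogenies; ``grouping`` maps group label to the
    indices of its trees (default one pooled group).  Probabilities are
    optimised on the logit scale with multi-start L-BFGS (boundary MLEs near
    zero are expected).  ``constraint='hsc_first'`` pins p_emb_to_mpp = 0 so
    embryonic cells must specify HSC before any MPP appears.  Returns per
    group the fitted model, log-likelihood and AIC.
    """
    if grouping is None:
        grouping = {"pooled": list(range(len(trees)))}
    if constraint not in ("none", "hsc_first"):
        raise ValueError("constraint must be 'none' or 'hsc_first'")
    n_par = 3 if constraint == "hsc_first" else 4
    base = HiddenStateModel(0.01, 0.01, 0.01, 0.01, epsilon=epsilon,
                            emb_lock=emb_lock)
    rng = np.random.default_rng(seed)
    results = {}
    for label, idx in grouping.items():
        group = [trees[i] for i in idx]

        def negll(x):
            try:
                m = _model_from_vector(x, constraint, base)
                return -sum(tree_loglikelihood(t, m) for t in group)
            except (ValueError, FloatingPointError):
                return 1e12   # infeasible region (e.g. EMB exits > 1)

        best = None
        x0s = [np.full(n_par, logit(0.02))]
        x0s += [logit(0.02) + rng.normal(0, 2.0, n_par)
                for _ in range(n_restarts - 1)]
        for x0 in x0s:
            res = optimize.minimize(negll, x0, method="Nelder-Mead",
                                    options={"xatol": 1e-6, "fatol": 1e-8,
                                             "maxiter": maxiter})
            if best is None or res.fun < best.fun:
                best = res
        model = _model_from_vector(best.x, constraint, base)
        logl = -float(best.fun)
        results[label] = {
            "model": model, "loglik": logl, "aic": 2 * n_par - 2 * logl,
            "n_params": n_par, "converged": bool(best.success),
        }
    return results


def compare_nested(full: dict, restricted: dict) -> dict:
    """Likelihood-ratio comparison of nested fits (e.g. free vs HSC-first).

    The p-value uses the chi-square reference with df = difference in
    parameter count; with the restricted parameter on its boundary this is
    conservative.
    """
    lr = 2.0 * (full["loglik"] - restricted["loglik"])
    df = full["n_params"] - restricted["n_params"]
    p = float(stats.chi2.sf(max(lr, 0.0), df)) if df > 0 else math.nan
    return {"lr": float(lr), "df": df, "p": p,
            "delta_aic": restricted["aic"] - full["aic"]}


def state_trajectory(model: HiddenStateModel, t_grid) -> np.ndarray:
    """State probabilities pi . M^(t - lock) over molecular time.

    For t below the EMB lock the distribution is the root prior (all EMB);
    rows sum to one at every t.  Useful for plotting cell-type probability
    trajectories from the fitted model.
    """
    t_grid = np.asarray(t_grid, dtype=int)
    if (t_grid < 0).any():
        raise ValueError("molecular times must be non-negative")
    out = np.zeros((t_grid.size, 3))
    pi = model.root_prior
    M = model.matrix
    for j, t in enumerate(t_grid):
        steps = max(0, int(t) - model.emb_lock)
        out[j] = pi @ np.linalg.matrix_power(M, steps)
    return out
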