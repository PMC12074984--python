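"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import dendropy
import numpy as np
import pytest

from clonaldyn.hmm_tree import branch_transition
from clonaldyn.hmm_tree import _effective_lengths, _tip_emission_log
from clonaldyn.phylotree import Phylogeny
from clonaldyn.synthetic_data import Epoch, PopModel


@pytest.fixture
def small_model():
    """Small bounded two-epoch population: fast to simulate exactly."""
    return PopModel(epochs=(
        Epoch(duration=10.0, lam=0.8, nu=0.0, cap=500),
        Epoch(duration=float("inf"), lam=0.2, nu=0.05, cap=500),
    ))


def random_labeled_tree(rng: np.random.Generator, n_tips: int,
                        max_len: int = 30) -> Phylogeny:
    """Random binary tree with integer branch lengths and HSC/MPP tips."""
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for i in range(n_tips):
        node = dendropy.Node()
        pheno = "HSC" if rng.uniform() < 0.5 else "MPP"
        node.taxon = taxa.new_taxon(label=f"c{i:03d}|{pheno}")
        node.edge.length = int(rng.integers(0, max_len))
        nodes.append(node)
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        parent = dendropy.Node()
        parent.edge.length = int(rng.integers(0, max_len))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for q, n in enumerate(nodes) if q not in (i, j)]
        nodes.append(parent)
    tree.seed_node = nodes[0]
    tree.seed_node.edge.length = 0
    return Phylogeny(tree)


def enumerate_hmm(phylo: Phylogeny, model) -> tuple[float, float]:
    """Exhaustive-sum and exhaustive-max log-probabilities over all
    end-of-branch state assignments (vectorized; independent of the
    upward/Viterbi recursions it checks)."""
    nodes = [n for n in phylo.tree.preorder_node_iter()
             if n.parent_node is not None]
    eff = _effective_lengths(phylo, model.emb_lock)
    emis = _tip_emission_log(phylo, model.epsilon)
    K = len(nodes)
    assign = np.stack(np.meshgrid(*([np.arange(3)] * K),
                                  indexing="ij")).reshape(K, -1)
    with np.errstate(divide="ignore"):
        logp = np.zeros(assign.shape[1])
        node_col = {n: i for i, n in enumerate(nodes)}
        for n in nodes:
            M = np.log(branch_transition(model, eff[n]))
            parent = n.parent_node
            par_states = (np.zeros(assign.shape[1], dtype=int)
                          if parent is phylo.root
                          else assign[node_col[parent]])
            logp += M[par_states, assign[node_col[n]]]
            if n.is_leaf():
                logp += emis[n][assign[node_col[n]]]
    from scipy.special import logsumexp
    return float(logsumexp(logp)), float(logp.max())
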