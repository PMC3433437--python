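"""Independent brute-force oracles used by the test suite.

These enumerate every ancestral state assignment directly from transition
matrices and never touch the pruning/outside-pass code they check.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from rnacoevo.evomodel import GtrGammaModel
from rnacoevo.seqdata import PhyloTree


def _edge_matrices(tree: PhyloTree, model: GtrGammaModel, rate: float):
    return {v: model.transition_matrix(tree.lengths[v], rate)
            for v in range(tree.n_nodes) if tree.parent[v] >= 0}


def site_likelihood_by_enumeration(tree: PhyloTree, model: GtrGammaModel,
                                   leaf_states: dict[int, int | None],
                                   rate: float = 1.0) -> float:
    """P(leaf data) summed over every internal (and missing-leaf) assignment."""
    P = _edge_matrices(tree, model, rate)
    pi = model.stationary_freqs
    free = [v for v in range(tree.n_nodes)
            if not tree.is_leaf(v) or leaf_states.get(v) is None]
    total = 0.0
    for combo in product(range(4), repeat=len(free)):
        state = dict(zip(free, combo))
        for v, s in leaf_states.items():
            if s is not None:
                state[v] = s
        p = pi[state[tree.root]]
        for v in range(tree.n_nodes):
            if tree.parent[v] >= 0:
                p *= P[v][state[int(tree.parent[v])], state[v]]
        total += p
    return total


def gamma_site_likelihood_by_enumeration(tree, model, leaf_states) -> float:
    return float(np.mean([
        site_likelihood_by_enumeration(tree, model, leaf_states, r)
        for r in model.category_rates]))


def marginal_posterior_by_enumeration(tree: PhyloTree, model: GtrGammaModel,
                                      leaf_states: dict[int, int],
                                      node: int) -> np.ndarray:
    """Gamma-averaged marginal posterior at one internal node, from the joint."""
    per_cat = []
    weights = []
    for r in model.category_rates:
        P = _edge_matrices(tree, model, r)
        pi = model.stationary_freqs
        free = [v for v in range(tree.n_nodes) if not tree.is_leaf(v)]
        joint = np.zeros(4)
        for combo in product(range(4), repeat=len(free)):
            state = dict(zip(free, combo))
            state.update(leaf_states)
            p = pi[state[tree.root]]
            for v in range(tree.n_nodes):
                if tree.parent[v] >= 0:
                    p *= P[v][state[int(tree.parent[v])], state[v]]
            joint[state[node]] += p
        per_cat.append(joint / joint.sum())
        weights.append(joint.sum())
    w = np.array(weights)
    w = w / w.sum()
    return np.einsum("k,ks->s", w, np.array(per_cat))


def switch_class_by_path_walk(states: np.ndarray, tree: PhyloTree,
                              u: int, v: int, i: int, j: int) -> str | None:
    """Classify a candidate switch by walking the explicit state sequence.

    Returns 'terminal'/'intermediate' for an exactly-two-substitution path
    between distinct Watson-Crick endpoints, else None.
    """
    from rnacoevo.seqdata import ALPHABET, WATSON_CRICK

    def dinuc(n):
        a, b = states[n, i], states[n, j]
        if a < 0 or b < 0:
            return None
        return ALPHABET[a] + ALPHABET[b]

    path = tree.path_nodes(u, v)
    x, y = dinuc(u), dinuc(v)
    if x is None or y is None or x == y:
        return None
    if x not in WATSON_CRICK or y not in WATSON_CRICK:
        return None
    nsub = 0
    for a, b in zip(path[:-1], path[1:]):
        for s in (i, j):
            if states[a, s] >= 0 and states[b, s] >= 0 \
                    and states[a, s] != states[b, s]:
                nsub += 1
    if nsub != 2:
        return None
    lca = tree.lca(u, v)
    ds = dinuc(lca)
    return "terminal" if ds in (x, y) else "intermediate"
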