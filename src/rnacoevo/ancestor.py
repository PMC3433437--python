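"""Empirical-Bayes marginal ancestral state reconstruction and substitution mapping.

Marginal posteriors at each internal node combine the inside ("down", pruning)
partial likelihoods with outside ("up") partials, per discrete-gamma category,
then average categories weighted by each site's category posterior.  MAP ties
are broken in fixed alphabet order A < C < G < U.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .evomodel import GtrGammaModel, _pruning_pass, leaf_partials
from .seqdata import ALPHABET, PhyloTree, RnaAlignment, RnacoevoError, decode_sequence


class ReconstructionError(RnacoevoError):
    pass


@dataclass
class AncestralReconstruction:
    """Per-internal-node, per-site posteriors and MAP states.

    ``posteriors`` has shape (n_internal, n_sites, 4) in the order of
    ``internal_nodes`` (tree node indices); ``map_states`` the argmax codes.
    """

    internal_nodes: np.ndarray
    posteriors: np.ndarray
    map_states: np.ndarray
    all_gap_sites: np.ndarray  # 0-based sites where every taxon is gapped

    def __post_init__(self) -> None:
        self._row_of = {int(v): k for k, v in enumerate(self.internal_nodes)}

    def posterior(self, node: int, site: int) -> np.ndarray:
        return self.posteriors[self._row_of[node], site]

    def map_state(self, node: int, site: int) -> int:
        return int(self.map_states[self._row_of[node], site])

    def node_row(self, node: int) -> int:
        return self._row_of[node]

    @property
    def map_posteriors(self) -> np.ndarray:
        """Posterior probability of the MAP state, shape (n_internal, n_sites)."""
        return np.take_along_axis(
            self.posteriors, self.map_states[:, :, None], axis=2)[:, :, 0]

    @property
    def mean_map_posterior(self) -> float:
        return float(self.map_posteriors.mean())

    def to_table(self) -> pd.DataFrame:
        rows = []
        for k, v in enumerate(self.internal_nodes):
            for s in range(self.posteriors.shape[1]):
                p = self.posteriors[k, s]
                rows.append({
                    "node": int(v), "site": s + 1,
                    "p_A": p[0], "p_C": p[1], "p_G": p[2], "p_U": p[3],
                    "map_state": ALPHABET[self.map_states[k, s]],
                })
        return pd.DataFrame(rows)

    def map_sequences(self) -> dict[int, str]:
        return {int(v): decode_sequence(self.map_states[k])
                for k, v in enumerate(self.internal_nodes)}

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for node, seq in self.map_sequences().items():
                fh.write(f">node{node}\n{seq}\n")


def reconstruct_ancestors(aln: RnaAlignment, tree: PhyloTree,
                          model: GtrGammaModel) -> AncestralReconstruction:
    """Marginal (empirical-Bayes) reconstruction at every internal node."""
    tip, _ = leaf_partials(aln, tree)
    L = aln.n_sites
    pi = model.stationary_freqs
    internal = tree.internal_nodes
    n_int = internal.size
    row_of = {int(v): k for k, v in enumerate(internal)}

    site_ll = np.empty((model.n_categories, L))
    post_by_cat = np.empty((model.n_categories, n_int, L, 4))

    for k, r in enumerate(model.category_rates):
        down, log_scale = _pruning_pass(tree, model, tip, r)
        site_ll[k] = np.log(down[tree.root] @ pi) + log_scale[tree.root]

        # outside pass; per-site scale factors cancel on normalisation
        up = np.empty((tree.n_nodes, L, 4))
        up[tree.root] = pi
        P_edge: dict[int, np.ndarray] = {}
        for v in tree.preorder:
            kids = tree.children[v]
            if not kids:
                continue
            msgs = {}
            for c in kids:
                P = model.transition_matrix(tree.lengths[c], r)
                P_edge[c] = P
                msgs[c] = down[c] @ P.T
            for c in kids:
                prod = up[v].copy()
                for s in kids:
                    if s != c:
                        prod *= msgs[s]
                u = prod @ P_edge[c]
                norm = u.sum(axis=1, keepdims=True)
                norm[norm == 0] = 1.0
                up[c] = u / norm

        for v in internal:
            joint = up[v] * down[v]
            z = joint.sum(axis=1, keepdims=True)
            z[z == 0] = 1.0
            post_by_cat[k, row_of[int(v)]] = joint / z

    w = np.exp(site_ll - logsumexp(site_ll, axis=0, keepdims=True))  # (K, L)
    posteriors = np.einsum("kl,knls->nls", w, post_by_cat)
    posteriors /= posteriors.sum(axis=2, keepdims=True)
    map_states = posteriors.argmax(axis=2)  # first max => A<C<G<U tie-break

    all_gap = np.flatnonzero((aln.codes < 0).all(axis=0))
    return AncestralReconstruction(internal, posteriors, map_states, all_gap)


# ---------------------------------------------------------------------------
# Accuracy against simulated truth
# ---------------------------------------------------------------------------

def reconstruction_accuracy(truth_states: np.ndarray, truth_nodes: np.ndarray,
                            recon: AncestralReconstruction) -> pd.DataFrame:
    """Fraction of node x site MAP states matching simulated truth.

    ``truth_states`` holds state codes with rows ordered by ``truth_nodes``
    (tree node indices); both must cover the reconstruction's internal nodes.
    """
    truth_nodes = np.asarray(truth_nodes)
    row_of_truth = {int(v): k for k, v in enumerate(truth_nodes)}
    missing = [int(v) for v in recon.internal_nodes if int(v) not in row_of_truth]
    if missing:
        raise ReconstructionError(f"truth lacks nodes {missing[:5]}")
    if truth_states.shape[1] != recon.posteriors.shape[1]:
        raise ReconstructionError("truth and reconstruction site counts differ")
    idx = np.array([row_of_truth[int(v)] for v in recon.internal_nodes])
    truth = truth_states[idx]
    match = truth == recon.map_states
    mp = recon.map_posteriors
    return pd.DataFrame([{
        "n_nodes": int(recon.internal_nodes.size),
        "n_sites": int(truth.shape[1]),
        "accuracy": float(match.mean()),
        "mean_map_posterior": float(mp.mean()),
        "frac_map_posterior_ge_0.9": float((mp >= 0.9).mean()),
    }])


# ---------------------------------------------------------------------------
# Substitution mapping
# ---------------------------------------------------------------------------

@dataclass
class SubstitutionMap:
    """Per-site indicator of a state change on each edge.

    ``counts`` has shape (n_nodes, n_sites); row v is the edge above node v
    (the root row is zero).  ``valid`` marks edges whose endpoint states are
    both known for that site (a leaf gap masks its edge).
    """

    counts: np.ndarray
    valid: np.ndarray
    node_states: np.ndarray  # (n_nodes, n_sites) codes; -1 unknown

    @property
    def per_site_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def site_vector(self, site: int) -> np.ndarray:
        """Substitution indicator across edges (rows = child node index)."""
        return self.counts[:, site]


def node_state_matrix(recon: AncestralReconstruction, aln: RnaAlignment,
                      tree: PhyloTree) -> np.ndarray:
    """MAP states at internal nodes plus observed states at leaves."""
    binding = tree.bind(aln)
    states = np.full((tree.n_nodes, aln.n_sites), -1, dtype=np.int64)
    for v in tree.leaves:
        states[v] = aln.codes[binding[v]]
    for k, v in enumerate(recon.internal_nodes):
        states[int(v)] = recon.map_states[k]
    return states


def map_substitutions(recon: AncestralReconstruction, aln: RnaAlignment,
                      tree: PhyloTree) -> SubstitutionMap:
    """Indicator substitution mapping from MAP/observed endpoint states."""
    states = node_state_matrix(recon, aln, tree)
    counts = np.zeros_like(states, dtype=np.int64)
    valid = np.zeros(states.shape, dtype=bool)
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p < 0:
            continue
        ok = (states[v] >= 0) & (states[p] >= 0)
        valid[v] = ok
        counts[v, ok] = (states[v, ok] != states[p, ok]).astype(np.int64)
    return SubstitutionMap(counts, valid, states)
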