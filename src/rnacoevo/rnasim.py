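"""Sequence-evolution simulation along trees and the 5S-like benchmark generator.

Two regimes are provided:

* ``simulate_neutral`` — independent sites under GTR+G (Seq-Gen-style): the
  null model for all significance machinery.
* ``simulate_paired`` — stem base pairs evolve jointly on a 7-state pair
  alphabet (six canonical/wobble pairs plus one pooled mismatch class, the
  RNA7 convention); ``selection_strength`` scales the stationary mass of the
  mismatch class, penalising transitions into mismatches.  Loop sites evolve
  under GTR+G.

The benchmark generator emulates a 5S rRNA-like molecule: ~120 nt, five
helices (I-V) and five loops (A-E), 30-160 taxa on a Yule tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .evomodel import GtrGammaModel, ParameterError
from .seqdata import (ALPHABET, PhyloTree, RnaAlignment, SecondaryStructure,
                      StructureParseError, decode_sequence)

PAIR_STATES = ("AU", "GC", "GU", "UA", "CG", "UG", "MM")
_CANONICAL_AND_WOBBLE = PAIR_STATES[:6]
#: the ten non-canonical, non-wobble dinucleotides pooled into MM
MISMATCH_DINUCS = tuple(sorted(
    a + b for a in ALPHABET for b in ALPHABET
    if a + b not in _CANONICAL_AND_WOBBLE))

_CODE = {c: i for i, c in enumerate(ALPHABET)}


def _dinuc_codes(d: str) -> tuple[int, int]:
    return _CODE[d[0]], _CODE[d[1]]


def default_pair_frequencies() -> np.ndarray:
    """Stationary pair frequencies echoing canonical-pair dominance (ours)."""
    return np.array([0.17, 0.24, 0.07, 0.17, 0.24, 0.07, 0.04])


def default_pair_exchangeabilities() -> np.ndarray:
    """Symmetric 7x7 exchangeabilities (ours; no published values exist).

    Concerted double substitutions between complementary Watson-Crick pairs
    (AU<->GC, UA<->CG) get the largest weight — the hallmark of compensatory
    stem evolution; single-step wobble paths are moderate; everything through
    the mismatch class is slow.
    """
    s = np.zeros((7, 7))

    def set_(a: str, b: str, v: float) -> None:
        i, j = PAIR_STATES.index(a), PAIR_STATES.index(b)
        s[i, j] = s[j, i] = v

    # wobble-mediated single-nucleotide steps
    set_("AU", "GU", 3.0)
    set_("GU", "GC", 3.0)
    set_("UA", "UG", 3.0)
    set_("UG", "CG", 3.0)
    # concerted Watson-Crick switches
    set_("AU", "GC", 6.0)
    set_("UA", "CG", 6.0)
    set_("AU", "UA", 2.0)
    set_("GC", "CG", 2.0)
    set_("AU", "CG", 2.0)
    set_("UA", "GC", 2.0)
    # remaining double steps between canonical/wobble states
    for a in range(6):
        for b in range(a + 1, 6):
            if s[a, b] == 0:
                s[a, b] = s[b, a] = 0.5
    # through the mismatch class
    for a in range(6):
        s[a, 6] = s[6, a] = 1.0
    return s


def _pair_hamming(i: int, j: int) -> int:
    """Nucleotide changes between pair states; MM transitions count as 1."""
    if i == 6 or j == 6:
        return 1
    a, b = PAIR_STATES[i], PAIR_STATES[j]
    return (a[0] != b[0]) + (a[1] != b[1])


@dataclass
class PairModel:
    """Reversible 7-state pair substitution process."""

    frequencies: np.ndarray = field(default_factory=default_pair_frequencies)
    exchangeabilities: np.ndarray = field(default_factory=default_pair_exchangeabilities)
    selection_strength: float = 1.0

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        if self.frequencies.shape != (7,) or np.any(self.frequencies <= 0):
            raise ParameterError("need 7 positive pair frequencies")
        if not np.isclose(self.frequencies.sum(), 1.0, atol=1e-6):
            raise ParameterError("pair frequencies must sum to 1")
        if self.selection_strength < 0:
            raise ParameterError("selection_strength must be >= 0")
        pi = self.frequencies.copy()
        pi[6] *= max(self.selection_strength, 1e-12)
        pi /= pi.sum()
        self.stationary = pi
        Q = self.exchangeabilities * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        # normalise to one expected nucleotide substitution per site:
        # each pair event changes 1-2 of the 2 nucleotides it covers
        ham = np.array([[_pair_hamming(i, j) for j in range(7)] for i in range(7)])
        nt_rate = float((pi[:, None] * Q * ham).sum()) / 2.0
        np.fill_diagonal(Q, -Q.sum(axis=1))
        self.Q = Q / nt_rate
        w, U = np.linalg.eig(self.Q)  # small matrix; generic eig is fine
        self._w, self._U, self._Uinv = w, U, np.linalg.inv(U)

    def transition_matrix(self, t: float, rate_scalar: float = 1.0) -> np.ndarray:
        P = (self._U * np.exp(self._w * t * rate_scalar)) @ self._Uinv
        P = np.real(P)
        np.clip(P, 0.0, 1.0, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


# ---------------------------------------------------------------------------
# 5S-like structure template
# ---------------------------------------------------------------------------

_TEMPLATE_SEGMENTS = (
    ("I", 10, "("), ("A", 4, "."), ("II", 9, "("), ("B", 4, "."),
    ("III", 9, "("), ("C", 6, "."), ("III", 9, ")"), ("B", 3, "."),
    ("II", 9, ")"), ("A", 2, "."), ("V", 8, "("), ("E", 3, "."),
    ("IV", 8, "("), ("D", 5, "."), ("IV", 8, ")"), ("E", 3, "."),
    ("V", 8, ")"), ("A", 2, "."), ("I", 10, ")"),
)


def five_s_template() -> SecondaryStructure:
    """120-nt consensus template: five helices I-V and five loops A-E."""
    db = []
    regions = []
    pos = 1
    for label, n, ch in _TEMPLATE_SEGMENTS:
        db.append(ch * n)
        regions.append((pos, pos + n - 1, label))
        pos += n
    return SecondaryStructure.from_dotbracket("".join(db), regions)


# ---------------------------------------------------------------------------
# Yule trees
# ---------------------------------------------------------------------------

def yule_tree(n_taxa: int, depth: float, rng: np.random.Generator) -> PhyloTree:
    """Pure-birth ultrametric tree with ``n_taxa`` tips scaled to tip depth."""
    if n_taxa < 2:
        raise ParameterError("need at least 2 taxa")
    parent = [-1, 0, 0]
    birth = [0.0, 0.0, 0.0]
    active = [1, 2]
    t = 0.0
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / k)
        idx = int(rng.integers(k))
        v = active.pop(idx)
        for _ in range(2):
            parent.append(v)
            birth.append(t)
            active.append(len(parent) - 1)
    t += rng.exponential(1.0 / len(active))
    n = len(parent)
    lengths = np.zeros(n)
    end = np.full(n, t)
    for v in range(n):
        for c in range(n):
            if parent[c] == v:
                end[v] = birth[c]
    for v in range(1, n):
        lengths[v] = end[v] - birth[v]
    scale = depth / t if t > 0 else 1.0
    lengths *= scale
    labels: list[str | None] = [None] * n
    tip_no = 1
    for v in range(n):
        if all(parent[c] != v for c in range(n)):
            labels[v] = f"t{tip_no}"
            tip_no += 1
    return PhyloTree(np.array(parent), lengths, labels, root=0)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study conditions for one benchmark data set.

    Defaults mirror the emulated study: a 5S-like 120-nt molecule with five
    helices and loops, ~100-150 taxa, tree depth 0.5 expected subs/site,
    GTR+G loop evolution and 7-state paired-stem evolution.
    """

    n_taxa: int = 100
    depth: float = 0.5
    tree: PhyloTree | None = None
    structure: SecondaryStructure | None = None
    model: GtrGammaModel = field(default_factory=GtrGammaModel)
    pair_model: PairModel = field(default_factory=PairModel)
    selection_strength: float = 1.0
    n_coevolving: int | None = None  # None = all template pairs coevolve
    seed: int = 0

    def resolved_structure(self) -> SecondaryStructure:
        return self.structure if self.structure is not None else five_s_template()

    def resolved_pair_model(self) -> PairModel:
        pm = self.pair_model
        if pm.selection_strength != self.selection_strength:
            pm = PairModel(pm.frequencies, pm.exchangeabilities,
                           self.selection_strength)
        return pm


@dataclass
class SimResult:
    """Simulated truth: leaf alignment plus every ancestral sequence."""

    tree: PhyloTree
    alignment: RnaAlignment
    node_states: np.ndarray        # (n_nodes, n_sites) codes, no gaps
    site_categories: np.ndarray    # discrete-gamma category per site
    coevolving_pairs: list[tuple[int, int]]  # 0-based (i, j) truly paired sites
    structure: SecondaryStructure | None = None

    @property
    def internal_truth(self) -> tuple[np.ndarray, np.ndarray]:
        nodes = self.tree.internal_nodes
        return self.node_states[nodes], nodes

    def edge_change_matrix(self) -> np.ndarray:
        """Indicator (n_nodes, n_sites): state change on the edge above v."""
        out = np.zeros_like(self.node_states)
        for v in range(self.tree.n_nodes):
            p = self.tree.parent[v]
            if p >= 0:
                out[v] = self.node_states[v] != self.node_states[p]
        return out

    def edge_events(self) -> list[tuple[int, int, str, str]]:
        """(child_node, site_1based, from, to) for every endpoint change."""
        events = []
        for v in range(self.tree.n_nodes):
            p = self.tree.parent[v]
            if p < 0:
                continue
            diff = np.flatnonzero(self.node_states[v] != self.node_states[p])
            for s in diff:
                events.append((v, int(s) + 1, ALPHABET[self.node_states[p, s]],
                               ALPHABET[self.node_states[v, s]]))
        return events


def _leaf_alignment(tree: PhyloTree, node_states: np.ndarray) -> RnaAlignment:
    leaves = tree.leaves
    names = [tree.labels[v] or f"leaf{v}" for v in leaves]
    return RnaAlignment(names, node_states[leaves].astype(np.int8))


def _sample_markov(parent_states: np.ndarray, P: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Vector draw of child states given parent states and one P matrix."""
    cum = P.cumsum(axis=1)
    u = rng.random(parent_states.size)
    return (u[:, None] > cum[parent_states]).sum(axis=1)


def simulate_neutral(tree: PhyloTree, model: GtrGammaModel, L: int,
                     seed: int) -> SimResult:
    """Independent-sites GTR+G simulation; root drawn from stationary freqs."""
    if L < 1:
        raise ParameterError("need at least one site")
    rng = np.random.default_rng(seed)
    K = model.n_categories
    cats = rng.integers(K, size=L)
    states = np.zeros((tree.n_nodes, L), dtype=np.int64)
    states[tree.root] = rng.choice(4, size=L, p=model.stationary_freqs)
    for v in tree.preorder:
        p = tree.parent[v]
        if p < 0:
            continue
        for k in range(K):
            sites = np.flatnonzero(cats == k)
            if sites.size == 0:
                continue
            P = model.transition_matrix(tree.lengths[v], model.category_rates[k])
            states[v, sites] = _sample_markov(states[p, sites], P, rng)
    return SimResult(tree, _leaf_alignment(tree, states), states, cats, [])


def _expand_pair_state(state: int, rng: np.random.Generator) -> tuple[int, int]:
    if state < 6:
        return _dinuc_codes(PAIR_STATES[state])
    return _dinuc_codes(MISMATCH_DINUCS[int(rng.integers(len(MISMATCH_DINUCS)))])


def simulate_paired(tree: PhyloTree, cfg: SimConfig, seed: int | None = None) -> SimResult:
    """Joint stem-pair + independent loop simulation on one tree.

    Coevolving stem pairs follow the 7-state pair process; a mismatch state is
    expanded to a concrete non-canonical dinucleotide when first entered and
    inherited until the pair state changes again.
    """
    ss = cfg.resolved_structure()
    pm = cfg.resolved_pair_model()
    model = cfg.model
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    L = ss.n_sites
    pairs = ss.pairs
    if cfg.n_coevolving is not None:
        if cfg.n_coevolving > len(pairs):
            raise StructureParseError(
                f"n_coevolving={cfg.n_coevolving} exceeds {len(pairs)} template pairs")
        # deterministic, spread across helices
        take = np.linspace(0, len(pairs) - 1, cfg.n_coevolving).round().astype(int)
        pairs = [pairs[k] for k in take]
    pair_sites = {s for ij in pairs for s in ij}
    if len(pair_sites) != 2 * len(pairs):
        raise StructureParseError("overlapping pair assignments")
    free_sites = np.array(sorted(set(range(L)) - pair_sites), dtype=np.int64)

    K = model.n_categories
    cats = rng.integers(K, size=L)
    for i, j in pairs:  # a pair shares one rate category
        cats[j] = cats[i]

    n = tree.n_nodes
    states = np.zeros((n, L), dtype=np.int64)
    pstate = np.zeros((n, len(pairs)), dtype=np.int64)

    # root
    pstate[tree.root] = rng.choice(7, size=len(pairs), p=pm.stationary)
    for k, (i, j) in enumerate(pairs):
        a, b = _expand_pair_state(pstate[tree.root, k], rng)
        states[tree.root, i], states[tree.root, j] = a, b
    if free_sites.size:
        states[tree.root, free_sites] = rng.choice(
            4, size=free_sites.size, p=model.stationary_freqs)

    pair_cats = cats[[i for i, _ in pairs]]
    for v in tree.preorder:
        p = tree.parent[v]
        if p < 0:
            continue
        t = tree.lengths[v]
        # stems
        for k in range(K):
            idx = np.flatnonzero(pair_cats == k)
            if idx.size:
                P = pm.transition_matrix(t, model.category_rates[k])
                pstate[v, idx] = _sample_markov(pstate[p, idx], P, rng)
        for k, (i, j) in enumerate(pairs):
            if pstate[v, k] == pstate[p, k]:
                states[v, i], states[v, j] = states[p, i], states[p, j]
            else:
                states[v, i], states[v, j] = _expand_pair_state(pstate[v, k], rng)
        # loops / independent sites
        for k in range(K):
            idx = free_sites[cats[free_sites] == k]
            if idx.size:
                P = model.transition_matrix(t, model.category_rates[k])
                states[v, idx] = _sample_markov(states[p, idx], P, rng)

    return SimResult(tree, _leaf_alignment(tree, states), states, cats,
                     list(pairs), ss)


def generate_benchmark(cfg: SimConfig, mode: str = "paired",
                       out_dir=None) -> SimResult:
    """Build one benchmark data set; optionally write all artefacts.

    ``mode='paired'`` evolves stems jointly (with ``cfg.selection_strength``);
    ``mode='neutral'`` evolves every site independently under GTR+G.
    """
    rng = np.random.default_rng(cfg.seed)
    tree = cfg.tree if cfg.tree is not None else yule_tree(
        cfg.n_taxa, cfg.depth, rng)
    evo_seed = int(rng.integers(2 ** 31 - 1))
    ss = cfg.resolved_structure()
    if mode == "paired":
        cfg2 = replace(cfg, tree=tree, structure=ss)
        result = simulate_paired(tree, cfg2, seed=evo_seed)
    elif mode == "neutral":
        result = simulate_neutral(tree, cfg.model, ss.n_sites, evo_seed)
        result.structure = ss
    else:
        raise ParameterError(f"unknown simulation mode {mode!r}")

    if out_dir is not None:
        from pathlib import Path

        from . import seqdata
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        seqdata.write_alignment(result.alignment, out / "alignment.fasta")
        seqdata.write_tree(tree, out / "tree.nwk")
        seqdata.write_structure(ss, out / "structure.txt")
        with open(out / "true_ancestors.fasta", "w") as fh:
            for v in tree.internal_nodes:
                fh.write(f">node{int(v)}\n{decode_sequence(result.node_states[v])}\n")
        import pandas as pd
        truth = pd.DataFrame(
            [{"site_i": i + 1, "site_j": j + 1} for i, j in result.coevolving_pairs])
        seqdata.write_table(truth, out / "true_pairs.tsv")
    return result
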