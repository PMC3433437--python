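"""Compensatory Watson-Crick switch detection, TIR, and the paired-difference test.

A *switch* is recorded when two lineages carry different Watson-Crick
dinucleotides at a structurally interacting site pair and the two states are
separated by exactly two substitutions along the tree path between the
lineages (judged from reconstructed ancestral states).  The lowest common
ancestor of the two lineages then carries either a *terminal* state (one of
the two Watson-Crick endpoints: the two substitutions clustered on a single
lineage segment) or an *intermediate* state (each substitution on its own
descendant lineage).  The terminal-to-intermediate ratio (TIR) is ~1 when
substitutions accrue independently and grows when they cluster, as expected
under selection for maintained pairing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .ancestor import AncestralReconstruction, node_state_matrix
from .seqdata import (ALPHABET, WATSON_CRICK, WOBBLE, PhyloTree, RnaAlignment,
                      RnacoevoError, SecondaryStructure)

SWITCH_TYPES = ("AU<->GC", "AU<->UA", "GC<->CG", "AU<->CG")

_TYPE_ENDPOINTS = {
    "AU<->GC": frozenset({"AU", "GC"}),
    "AU<->UA": frozenset({"AU", "UA"}),
    "GC<->CG": frozenset({"GC", "CG"}),
    "AU<->CG": frozenset({"AU", "CG"}),
}

#: intermediate dinucleotides of each switch type, in the type's own orientation
TYPE_INTERMEDIATES = {
    "AU<->GC": frozenset({"AC", "GU"}),
    "AU<->UA": frozenset({"AA", "UU"}),
    "GC<->CG": frozenset({"CC", "GG"}),
    "AU<->CG": frozenset({"AG", "UC"}),
}


class SwitchError(RnacoevoError):
    pass


def switch_type_of(x: str, y: str) -> str:
    """Canonical type label for two distinct Watson-Crick endpoint dinucs.

    Orientation-swapped switches (e.g. UA<->CG) map onto the same type as
    their reversed form.
    """
    pair = frozenset({x, y})
    for label, eps in _TYPE_ENDPOINTS.items():
        if pair == eps:
            return label
    rev = frozenset({x[::-1], y[::-1]})
    for label, eps in _TYPE_ENDPOINTS.items():
        if rev == eps:
            return label
    raise SwitchError(f"no switch type for endpoints {x}/{y}")


def intermediates_of(x: str, y: str) -> frozenset[str]:
    """The two one-substitution-away dinucleotides between endpoints x and y."""
    return frozenset({y[0] + x[1], x[0] + y[1]})


@dataclass
class SwitchRecord:
    pair: tuple[int, int]          # 0-based alignment sites (i, j)
    switch_type: str
    node_u: int
    node_v: int
    lca_node: int
    lca_state: str
    lca_class: str                 # terminal | intermediate | multiple
    n_substitutions: int
    multiple_flag: bool
    low_confidence: bool = False
    edges: tuple[int, int] = (-1, -1)  # child-node ids of the two change edges
    dataset: str = "all"

    def to_row(self) -> dict:
        i, j = self.pair
        return {
            "dataset": self.dataset, "site_i": i + 1, "site_j": j + 1,
            "switch_type": self.switch_type, "node_u": self.node_u,
            "node_v": self.node_v, "lca_node": self.lca_node,
            "lca_state": self.lca_state, "lca_class": self.lca_class,
            "n_substitutions": self.n_substitutions,
            "multiple": self.multiple_flag, "low_confidence": self.low_confidence,
        }


def records_to_table(records: list[SwitchRecord]) -> pd.DataFrame:
    cols = ["dataset", "site_i", "site_j", "switch_type", "node_u", "node_v",
            "lca_node", "lca_state", "lca_class", "n_substitutions",
            "multiple", "low_confidence"]
    if not records:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([r.to_row() for r in records])[cols]


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def _dinuc(states: np.ndarray, v: int, i: int, j: int) -> str | None:
    a, b = states[v, i], states[v, j]
    if a < 0 or b < 0:
        return None
    return ALPHABET[a] + ALPHABET[b]


def _change_counts_from_root(states: np.ndarray, tree: PhyloTree) -> np.ndarray:
    """cnt[v, s] = substitutions at site s on the root->v path (known states)."""
    change = np.zeros_like(states)
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p < 0:
            continue
        ok = (states[v] >= 0) & (states[p] >= 0)
        change[v, ok] = (states[v, ok] != states[p, ok]).astype(states.dtype)
    cnt = np.zeros_like(change)
    for v in tree.preorder:
        p = tree.parent[v]
        cnt[v] = change[v] + (cnt[p] if p >= 0 else 0)
    return cnt


_WC_CODES = {a * 4 + b for a in range(4) for b in range(4)
             if ALPHABET[a] + ALPHABET[b] in WATSON_CRICK}


def detect_switches_from_states(states: np.ndarray, tree: PhyloTree,
                                ss: SecondaryStructure,
                                map_posterior: np.ndarray | None = None,
                                posterior_cutoff: float = 0.7,
                                dataset: str = "all",
                                collapse_events: bool = False,
                                endpoints: str = "leaves"
                                ) -> list[SwitchRecord]:
    """Switch detection on an explicit node-state matrix.

    ``states`` has shape (n_nodes, n_sites) with -1 for unknown;
    ``map_posterior`` (same shape) drives the low-confidence flag.

    Every qualifying pair of lineages — by default a pair of extant species
    (``endpoints="leaves"``; ``"all"`` admits internal nodes) with distinct
    Watson-Crick dinucleotides separated by exactly two substitutions —
    yields one record; the clustering signal in the TIR comes precisely from
    how many lineage pairs flank each underlying event.
    ``collapse_events=True`` instead reports each unique pair of
    substitution-bearing edges once (one record per event, anchored at the
    minimal subtree).  Switches separated by more than two substitutions are
    always tallied at event level, as a deduplicated residual category.
    """
    cnt = _change_counts_from_root(states, tree)
    lca_m = tree.lca_matrix()
    n = tree.n_nodes
    records: list[SwitchRecord] = []
    wc_codes = np.array(sorted(_WC_CODES))
    endpoint_ok = np.zeros(n, dtype=bool)
    if endpoints == "leaves":
        endpoint_ok[tree.leaves] = True
    elif endpoints == "all":
        endpoint_ok[:] = True
    else:
        raise SwitchError(f"unknown endpoints mode {endpoints!r}")
    for i, j in ss.pairs:
        si, sj = states[:, i], states[:, j]
        known = (si >= 0) & (sj >= 0)
        d = np.where(known, si * 4 + sj, -1)
        is_wc = np.isin(d, wc_codes) & known & endpoint_ok
        if is_wc.sum() < 2:
            continue
        # path substitution counts for all node pairs at both sites
        ci, cj = cnt[:, i], cnt[:, j]
        path_i = ci[:, None] + ci[None, :] - 2 * ci[lca_m]
        path_j = cj[:, None] + cj[None, :] - 2 * cj[lca_m]
        nsub = path_i + path_j
        qual = (is_wc[:, None] & is_wc[None, :]
                & (d[:, None] != d[None, :]) & (nsub == 2))
        qual &= np.triu(np.ones((n, n), dtype=bool), 1)
        for u, v in np.argwhere(qual):
            u, v = int(u), int(v)
            x, y = _dinuc(states, u, i, j), _dinuc(states, v, i, j)
            lca = int(lca_m[u, v])
            lca_state = _dinuc(states, lca, i, j)
            if lca_state is None:
                continue
            if lca_state in (x, y):
                lca_class = "terminal"
            elif lca_state in intermediates_of(x, y):
                lca_class = "intermediate"
            else:  # state unknown on path; defensively skip
                continue
            lowconf = False
            if map_posterior is not None:
                for nd in tree.path_nodes(u, v):
                    if (map_posterior[nd, i] < posterior_cutoff
                            or map_posterior[nd, j] < posterior_cutoff):
                        lowconf = True
                        break
            records.append(SwitchRecord(
                pair=(i, j), switch_type=switch_type_of(x, y),
                node_u=u, node_v=v, lca_node=lca, lca_state=lca_state,
                lca_class=lca_class, n_substitutions=2, multiple_flag=False,
                low_confidence=lowconf, dataset=dataset))
        records.extend(_multiple_switch_events(states, tree, cnt, i, j, dataset))
    if collapse_events:
        records = _collapse_to_events(records, states, tree)
    return records


def _multiple_switch_events(states, tree, cnt, i, j, dataset) -> list[SwitchRecord]:
    """Deduplicated >2-substitution switches between Watson-Crick endpoints."""
    ei = _changed_edges(states, tree, i)
    ej = _changed_edges(states, tree, j)
    out = []
    seen: set[frozenset[int]] = set()
    clean_edges: set[int] = set()
    cands = []
    for a in ei:
        for b in ej:
            key = frozenset({a, b})
            if key in seen:
                continue
            seen.add(key)
            cand = _evaluate_candidate(states, tree, cnt, i, j, a, b)
            if cand is not None:
                cands.append(cand)
                if cand[3] == 2:
                    clean_edges.update((a, b))
    for (u, v, lca, nsub, a, b) in cands:
        if nsub <= 2 or a in clean_edges or b in clean_edges:
            continue  # clean switches are counted per lineage pair above
        x, y = _dinuc(states, u, i, j), _dinuc(states, v, i, j)
        out.append(SwitchRecord(
            pair=(i, j), switch_type=switch_type_of(x, y), node_u=u, node_v=v,
            lca_node=lca, lca_state=_dinuc(states, lca, i, j),
            lca_class="multiple", n_substitutions=int(nsub),
            multiple_flag=True, edges=(a, b), dataset=dataset))
    return out


def _collapse_to_events(records: list[SwitchRecord], states: np.ndarray,
                        tree: PhyloTree) -> list[SwitchRecord]:
    """One record per unique (pair, flanking change-edge set)."""
    by_event: dict[tuple, SwitchRecord] = {}
    for r in records:
        if r.multiple_flag:
            key = (r.pair, frozenset(r.edges))
        else:
            i, j = r.pair
            changed = [nd for nd in tree.path_nodes(r.node_u, r.node_v)
                       for s in (i, j)
                       if tree.parent[nd] >= 0
                       and states[nd, s] >= 0 and states[tree.parent[nd], s] >= 0
                       and states[nd, s] != states[tree.parent[nd], s]
                       and nd != tree.lca(r.node_u, r.node_v)]
            key = (r.pair, frozenset(changed))
        best = by_event.get(key)
        if best is None or (tree.depth[r.node_u] + tree.depth[r.node_v]
                            > tree.depth[best.node_u] + tree.depth[best.node_v]):
            by_event[key] = r
    return list(by_event.values())


def _changed_edges(states: np.ndarray, tree: PhyloTree, site: int) -> list[int]:
    out = []
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p < 0:
            continue
        if states[v, site] >= 0 and states[p, site] >= 0 \
                and states[v, site] != states[p, site]:
            out.append(v)
    return out


def _evaluate_candidate(states, tree, cnt, i, j, a, b):
    """Geometry of one (edge at i, edge at j) candidate.

    Returns (u, v, lca, n_substitutions, a, b) for candidates whose flanking
    endpoints carry distinct Watson-Crick dinucleotides, else None.  Nested
    edge pairs anchor a terminal switch (both substitutions on one lineage
    segment); edges in sibling subtrees anchor at their common ancestor.
    """
    if a == b:
        u, v = int(tree.parent[a]), a
    elif tree.is_ancestor(a, b):
        u, v = int(tree.parent[a]), b
    elif tree.is_ancestor(b, a):
        u, v = int(tree.parent[b]), a
    else:
        u, v = a, b
    x, y = _dinuc(states, u, i, j), _dinuc(states, v, i, j)
    if x is None or y is None or x == y:
        return None
    if x not in WATSON_CRICK or y not in WATSON_CRICK:
        return None
    lca = tree.lca(u, v)
    nsub = int(cnt[u, i] + cnt[v, i] - 2 * cnt[lca, i]
               + cnt[u, j] + cnt[v, j] - 2 * cnt[lca, j])
    if nsub < 2 or nsub > 4:
        return None
    return (u, v, lca, nsub, a, b)


def detect_switches(recon: AncestralReconstruction, aln: RnaAlignment,
                    tree: PhyloTree, ss: SecondaryStructure,
                    posterior_cutoff: float = 0.7, dataset: str = "all",
                    collapse_events: bool = False,
                    endpoints: str = "leaves") -> list[SwitchRecord]:
    """Watson-Crick switch detection from MAP ancestral + observed tip states."""
    if ss.n_sites != aln.n_sites:
        raise SwitchError("structure and alignment lengths differ")
    states = node_state_matrix(recon, aln, tree)
    posterior = np.ones(states.shape)
    for k, v in enumerate(recon.internal_nodes):
        posterior[int(v)] = recon.map_posteriors[k]
    return detect_switches_from_states(states, tree, ss, posterior,
                                       posterior_cutoff, dataset,
                                       collapse_events, endpoints)


# ---------------------------------------------------------------------------
# TIR
# ---------------------------------------------------------------------------

@dataclass
class TirResult:
    n_terminal: int
    n_intermediate: int
    n_multiple: int
    breakdown: pd.DataFrame = field(repr=False)

    @property
    def tir(self) -> float:
        if self.n_intermediate == 0:
            return float("inf")
        return self.n_terminal / self.n_intermediate

    @property
    def undefined(self) -> bool:
        return self.n_intermediate == 0

    @property
    def n_switches(self) -> int:
        """Clean (exactly-two-substitution) switches."""
        return self.n_terminal + self.n_intermediate

    def type_counts(self, switch_type: str) -> int:
        b = self.breakdown
        sel = b[(b["switch_type"] == switch_type)
                & (b["lca_class"] != "multiple")]
        return int(sel["count"].sum())

    def summary(self) -> pd.DataFrame:
        rows = []
        for st in SWITCH_TYPES:
            n = self.type_counts(st)
            rows.append({"switch_type": st, "n_switches": n,
                         "fraction": n / self.n_switches if self.n_switches else 0.0})
        rows.append({"switch_type": "total", "n_switches": self.n_switches,
                     "fraction": 1.0 if self.n_switches else 0.0})
        return pd.DataFrame(rows)


def compute_tir(records: list[SwitchRecord],
                include_low_confidence: bool = False) -> TirResult:
    """Aggregate switch records into terminal/intermediate counts and TIR."""
    import logging
    rows = []
    for r in records:
        if r.low_confidence and not include_low_confidence:
            continue
        rows.append({"dataset": r.dataset, "switch_type": r.switch_type,
                     "lca_state": r.lca_state,
                     "lca_class": "multiple" if r.multiple_flag else r.lca_class})
    if not rows:
        logging.getLogger("rnacoevo").warning("no switch records to aggregate")
        empty = pd.DataFrame(columns=["dataset", "switch_type", "lca_state",
                                      "lca_class", "count"])
        return TirResult(0, 0, 0, empty)
    df = pd.DataFrame(rows)
    breakdown = (df.groupby(["dataset", "switch_type", "lca_state", "lca_class"])
                 .size().reset_index(name="count"))
    return tir_from_breakdown(breakdown)


def tir_from_breakdown(breakdown: pd.DataFrame) -> TirResult:
    """Build a TirResult from a long-format count table.

    Expected columns: dataset, switch_type, lca_state, lca_class, count —
    the layout of the published per-taxon switch tables, so printed counts
    can be fed straight through the same aggregation path as detected records.
    """
    def total(cls: str) -> int:
        sel = breakdown[breakdown["lca_class"] == cls]
        return int(sel["count"].sum())

    return TirResult(total("terminal"), total("intermediate"),
                     total("multiple"), breakdown.copy())


# ---------------------------------------------------------------------------
# Paired-difference (one-third rule) test
# ---------------------------------------------------------------------------

@dataclass
class PairedDiffTest:
    """Chi-square test of double changes against the neutral 1/3-2/3 split.

    When both members of an interacting pair change, only one of the three
    possible second-site states restores canonical pairing, so neutral
    evolution predicts one third of double changes to end base-paired.
    """

    observed_paired: int
    observed_unpaired: int

    @property
    def total(self) -> int:
        return self.observed_paired + self.observed_unpaired

    @property
    def expected_paired(self) -> float:
        return self.total / 3.0

    @property
    def expected_unpaired(self) -> float:
        return 2.0 * self.total / 3.0

    @property
    def expected_display(self) -> tuple[int, int]:
        """Nearest-integer display of the expected counts."""
        return (round(self.expected_paired), round(self.expected_unpaired))

    @property
    def chi2(self) -> float:
        if self.total == 0:
            return float("nan")
        ep, eu = self.expected_paired, self.expected_unpaired
        return ((self.observed_paired - ep) ** 2 / ep
                + (self.observed_unpaired - eu) ** 2 / eu)

    @property
    def p_value(self) -> float:
        if self.total == 0:
            return float("nan")
        return float(chi2_dist.sf(self.chi2, df=1))

    @property
    def undefined(self) -> bool:
        return self.total == 0

    def to_row(self, dataset: str = "all") -> dict:
        ep, eu = self.expected_display
        return {"dataset": dataset,
                "observed_paired": self.observed_paired,
                "observed_unpaired": self.observed_unpaired,
                "expected_paired": ep, "expected_unpaired": eu,
                "chi2": self.chi2, "p_value": self.p_value}


def paired_difference_events(states: np.ndarray, tree: PhyloTree,
                             ss: SecondaryStructure) -> tuple[int, int]:
    """Count per-edge double changes ending paired vs unpaired.

    Only edges whose parental dinucleotide is Watson-Crick enter the tally:
    the neutral one-third rule reasons about second changes that restore a
    pairing that was there to begin with.
    """
    paired = unpaired = 0
    for i, j in ss.pairs:
        for v in range(tree.n_nodes):
            p = tree.parent[v]
            if p < 0:
                continue
            if min(states[v, i], states[v, j], states[p, i], states[p, j]) < 0:
                continue
            parent = ALPHABET[states[p, i]] + ALPHABET[states[p, j]]
            if parent not in WATSON_CRICK:
                continue
            if states[v, i] != states[p, i] and states[v, j] != states[p, j]:
                child = ALPHABET[states[v, i]] + ALPHABET[states[v, j]]
                if child in WATSON_CRICK:
                    paired += 1
                else:
                    unpaired += 1
    return paired, unpaired


def paired_difference_test(recon: AncestralReconstruction, aln: RnaAlignment,
                           tree: PhyloTree, ss: SecondaryStructure) -> PairedDiffTest:
    import logging
    states = node_state_matrix(recon, aln, tree)
    paired, unpaired = paired_difference_events(states, tree, ss)
    test = PairedDiffTest(paired, unpaired)
    if test.undefined:
        logging.getLogger("rnacoevo").warning(
            "no double-change events: paired-difference test undefined")
    return test


# ---------------------------------------------------------------------------
# Compensation mechanisms
# ---------------------------------------------------------------------------

DIRECT_WC = "direct-WC"
MULTI_SITE = "multi-site-same-helix"
NEW_PAIR = "new-pair-created"
STEM_LOOP = "stem-loop-boundary-change"
UNCOMPENSATED = "uncompensated"


def classify_compensation_mechanisms(states: np.ndarray, tree: PhyloTree,
                                     ss: SecondaryStructure) -> pd.DataFrame:
    """Label every stem-pair disruption with its compensation route.

    For each edge on which a pair leaves the Watson-Crick set, the subtree
    below is scanned for the first compensating gain: restoration of the same
    pair (direct-WC), or a different pair of the same helix turning canonical
    — classed stem-loop-boundary-change when that pair adjoins a loop/bulge,
    multi-site-same-helix when it re-establishes a pair canonical earlier in
    the lineage's history, else new-pair-created.
    """
    rows = []
    helix_pairs: dict[str, list[tuple[int, int]]] = {}
    for i, j in ss.pairs:
        h = ss.helix_of(i) or ss.helix_of(j) or "?"
        helix_pairs.setdefault(h, []).append((i, j))

    def is_wc(v: int, i: int, j: int) -> bool:
        d = _dinuc(states, v, i, j)
        return d is not None and d in WATSON_CRICK

    for i, j in ss.pairs:
        helix = ss.helix_of(i) or ss.helix_of(j) or "?"
        for v in range(tree.n_nodes):
            p = tree.parent[v]
            if p < 0 or not is_wc(p, i, j) or is_wc(v, i, j):
                continue
            # disruption on edge above v; breadth-first scan below for a gain
            label = UNCOMPENSATED
            frontier = [v]
            seen_depth = 0
            while frontier and label == UNCOMPENSATED and seen_depth <= 6:
                nxt = []
                for w in frontier:
                    if is_wc(w, i, j) and w != v:
                        label = DIRECT_WC
                        break
                    for qi, qj in helix_pairs.get(helix, []):
                        if (qi, qj) == (i, j):
                            continue
                        pw = tree.parent[w]
                        if pw >= 0 and not is_wc(pw, qi, qj) and is_wc(w, qi, qj):
                            near = (ss.position_class[qi] in ("near-loop", "near-bulge")
                                    or ss.position_class[qj] in ("near-loop", "near-bulge"))
                            if near:
                                label = STEM_LOOP
                            elif _was_wc_on_lineage(states, tree, pw, qi, qj):
                                label = MULTI_SITE
                            else:
                                label = NEW_PAIR
                            break
                    if label != UNCOMPENSATED:
                        break
                    nxt.extend(tree.children[w])
                frontier = nxt
                seen_depth += 1
            rows.append({"site_i": i + 1, "site_j": j + 1, "helix": helix,
                         "disruption_edge": v, "mechanism": label})
    df = pd.DataFrame(rows, columns=["site_i", "site_j", "helix",
                                     "disruption_edge", "mechanism"])
    return df


def _was_wc_on_lineage(states: np.ndarray, tree: PhyloTree, v: int,
                       i: int, j: int) -> bool:
    while v >= 0:
        d = _dinuc(states, v, i, j)
        if d is not None and d in WATSON_CRICK:
            return True
        v = int(tree.parent[v])
    return False


# ---------------------------------------------------------------------------
# Stem integrity trajectories
# ---------------------------------------------------------------------------

def stem_integrity_trajectory(states: np.ndarray, ss: SecondaryStructure,
                              tree: PhyloTree, wobble_ok: bool = True) -> pd.DataFrame:
    """Per-node count of stem pairs outside the allowed pairing set.

    ``wobble_ok`` admits GU/UG as paired (structural tolerance); the
    Watson-Crick switch machinery above never does — two distinct notions.
    """
    allowed = WATSON_CRICK | WOBBLE if wobble_ok else WATSON_CRICK
    depths = tree.node_depths()
    rows = []
    for v in range(tree.n_nodes):
        n_bad = 0
        for i, j in ss.pairs:
            d = _dinuc(states, v, i, j)
            if d is not None and d not in allowed:
                n_bad += 1
        rows.append({"node": v, "depth": depths[v],
                     "is_leaf": tree.is_leaf(v), "n_unpaired_in_stems": n_bad})
    return pd.DataFrame(rows)
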