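"""Watson-Crick switch detection, TIR aggregation, and the one-third-rule test."""

import numpy as np
import pytest
from oracles import switch_class_by_path_walk

from rnacoevo import compute_tir, simulate_neutral, tir_from_breakdown, yule_tree
from rnacoevo.compswitch import (PairedDiffTest, SwitchError,
                                 classify_compensation_mechanisms,
                                 detect_switches_from_states, intermediates_of,
                                 paired_difference_events, records_to_table,
                                 stem_integrity_trajectory, switch_type_of)
from rnacoevo.refdata import load_reference_switch_counts
from rnacoevo.rnasim import five_s_template
from rnacoevo.seqdata import (ALPHABET, SecondaryStructure, parse_tree_string)

CODE = {c: k for k, c in enumerate(ALPHABET)}


def balanced_tree():
    return parse_tree_string("((L1:1,L2:1)n1:1,(L3:1,L4:1)n2:1);")


def node_ids(tree):
    return {tree.labels[v]: v for v in range(tree.n_nodes) if tree.labels[v]}


def states_for(tree, assignment: dict[str, str], n_sites=2) -> np.ndarray:
    """Node-state matrix from label -> dinucleotide strings (root via index)."""
    ids = node_ids(tree)
    out = np.full((tree.n_nodes, n_sites), -1, dtype=np.int64)
    for label, dinuc in assignment.items():
        v = ids[label] if label != "root" else tree.root
        out[v] = [CODE[c] for c in dinuc]
    return out


PAIR_SS = SecondaryStructure.from_dotbracket("()")


class TestSwitchTyping:
    @pytest.mark.parametrize("x,y,stype,inter", [
        ("AU", "GC", "AU<->GC", {"AC", "GU"}),
        ("UA", "CG", "AU<->GC", {"CA", "UG"}),   # orientation-swapped form
        ("AU", "UA", "AU<->UA", {"AA", "UU"}),
        ("GC", "CG", "GC<->CG", {"CC", "GG"}),
        ("AU", "CG", "AU<->CG", {"CU", "AG"}),
        ("UA", "GC", "AU<->CG", {"GA", "UC"}),
    ])
    def test_types_and_intermediates(self, x, y, stype, inter):
        assert switch_type_of(x, y) == stype
        assert intermediates_of(x, y) == frozenset(inter)

    def test_non_watson_crick_endpoints_rejected(self):
        with pytest.raises(SwitchError):
            switch_type_of("GU", "AU")


class TestDetection:
    def test_intermediate_lca_between_sibling_lineages(self):
        # GU at the ancestor; one lineage -> AU, the other -> GC
        tree = balanced_tree()
        states = states_for(tree, {
            "root": "GU", "n1": "AU", "L1": "AU", "L2": "AU",
            "n2": "GC", "L3": "GC", "L4": "GC"})
        recs = detect_switches_from_states(states, tree, PAIR_SS)
        assert len(recs) == 4  # every cross-subtree leaf pair
        assert {r.lca_class for r in recs} == {"intermediate"}
        assert {r.lca_state for r in recs} == {"GU"}
        assert {r.switch_type for r in recs} == {"AU<->GC"}

    def test_terminal_lca_for_clustered_double_change(self):
        tree = balanced_tree()
        states = states_for(tree, {
            "root": "GC", "n1": "GC", "L1": "AU", "L2": "GC",
            "n2": "GC", "L3": "GC", "L4": "GC"})
        recs = detect_switches_from_states(states, tree, PAIR_SS)
        assert len(recs) == 3  # L1 against each other leaf
        assert {r.lca_class for r in recs} == {"terminal"}
        tir = compute_tir(recs)
        assert tir.n_terminal == 3 and tir.n_intermediate == 0
        assert tir.undefined and tir.tir == float("inf")

    def test_disruption_then_compensation_on_one_lineage(self):
        # GC -> GU (one edge) -> AU (next edge): nested changes, terminal LCA
        tree = balanced_tree()
        states = states_for(tree, {
            "root": "GC", "n1": "GU", "L1": "AU", "L2": "GU",
            "n2": "GC", "L3": "GC", "L4": "GC"})
        recs = detect_switches_from_states(states, tree, PAIR_SS)
        assert len(recs) == 2  # L1 vs L3 and L1 vs L4
        assert {r.lca_class for r in recs} == {"terminal"}
        assert {r.lca_state for r in recs} == {"GC"}

    def test_no_difference_no_record(self):
        tree = balanced_tree()
        states = states_for(tree, {lbl: "GC" for lbl in
                                   ("root", "n1", "n2", "L1", "L2", "L3", "L4")})
        assert detect_switches_from_states(states, tree, PAIR_SS) == []

    def test_three_substitution_path_flagged_multiple(self):
        tree = balanced_tree()
        states = states_for(tree, {
            "root": "AU", "n1": "CU", "L1": "GC", "L2": "CU",
            "n2": "AU", "L3": "AU", "L4": "AU"})
        recs = detect_switches_from_states(states, tree, PAIR_SS)
        assert all(r.multiple_flag for r in recs)
        assert {r.n_substitutions for r in recs} == {3}
        tir = compute_tir(recs)
        assert tir.n_switches == 0 and tir.n_multiple == len(recs)

    def test_unpaired_sites_never_scanned(self):
        tree = balanced_tree()
        ss = SecondaryStructure.from_dotbracket("..")
        states = states_for(tree, {
            "root": "GU", "n1": "AU", "L1": "AU", "L2": "AU",
            "n2": "GC", "L3": "GC", "L4": "GC"})
        assert detect_switches_from_states(states, tree, ss) == []

    def test_collapse_events_reports_each_event_once(self):
        tree = balanced_tree()
        states = states_for(tree, {
            "root": "GU", "n1": "AU", "L1": "AU", "L2": "AU",
            "n2": "GC", "L3": "GC", "L4": "GC"})
        recs = detect_switches_from_states(states, tree, PAIR_SS,
                                           collapse_events=True)
        assert len(recs) == 1
        assert recs[0].lca_class == "intermediate"

    def test_low_confidence_flagging(self):
        tree = balanced_tree()
        states = states_for(tree, {
            "root": "GU", "n1": "AU", "L1": "AU", "L2": "AU",
            "n2": "GC", "L3": "GC", "L4": "GC"})
        post = np.ones(states.shape)
        post[node_ids(tree)["L1"], 0] = 0.5
        recs = detect_switches_from_states(states, tree, PAIR_SS, post, 0.7)
        flagged = [r for r in recs if r.low_confidence]
        assert len(flagged) == 2  # the two pairs with L1 as an endpoint
        tir = compute_tir(recs)
        assert tir.n_switches == 2  # flagged records excluded by default
        assert compute_tir(recs, include_low_confidence=True).n_switches == 4


class TestAgainstPathWalkOracle:
    def test_every_record_and_no_extra_on_simulated_data(self, default_model):
        ss = five_s_template()
        for rep in range(8):
            rng = np.random.default_rng(500 + rep)
            tree = yule_tree(25, 0.8, rng)
            sim = simulate_neutral(tree, default_model, ss.n_sites, 500 + rep)
            recs = detect_switches_from_states(sim.node_states, tree, ss)
            clean = [r for r in recs if not r.multiple_flag]
            got = {(r.pair, r.node_u, r.node_v): r.lca_class for r in clean}
            leaves = [int(v) for v in tree.leaves]
            expected = {}
            for i, j in ss.pairs:
                for a in range(len(leaves)):
                    for b in range(a + 1, len(leaves)):
                        u, v = leaves[a], leaves[b]
                        cls = switch_class_by_path_walk(
                            sim.node_states, tree, u, v, i, j)
                        if cls is not None:
                            key = ((i, j), min(u, v), max(u, v))
                            expected[key] = cls
            assert got == expected


class TestTirAggregation:
    def test_simple_ratio(self):
        tree = balanced_tree()
        rows = [{"dataset": "x", "switch_type": "AU<->GC", "lca_state": "AU",
                 "lca_class": "terminal", "count": 10},
                {"dataset": "x", "switch_type": "AU<->GC", "lca_state": "GU",
                 "lca_class": "intermediate", "count": 10}]
        import pandas as pd
        tir = tir_from_breakdown(pd.DataFrame(rows))
        assert tir.tir == 1.0

    def test_reference_table_reproduces_published_totals(self):
        tir = tir_from_breakdown(load_reference_switch_counts())
        assert tir.n_terminal == 255
        assert tir.n_intermediate == 44
        assert tir.n_switches == 299
        assert round(tir.tir, 1) == 5.8
        assert tir.type_counts("AU<->GC") == 199

    def test_empty_records_warn(self):
        tir = compute_tir([])
        assert tir.n_switches == 0 and tir.n_multiple == 0

    def test_per_type_counts_conserve_record_total(self, default_model):
        ss = five_s_template()
        rng = np.random.default_rng(123)
        tree = yule_tree(30, 0.8, rng)
        sim = simulate_neutral(tree, default_model, ss.n_sites, 123)
        recs = detect_switches_from_states(sim.node_states, tree, ss)
        tir = compute_tir(recs)
        assert tir.breakdown["count"].sum() == len(recs)
        by_type = sum(tir.type_counts(st) for st in
                      ("AU<->GC", "AU<->UA", "GC<->CG", "AU<->CG"))
        assert by_type + tir.n_multiple == len(recs)


class TestPairedDifference:
    def test_exactly_neutral_counts(self):
        t = PairedDiffTest(10, 20)
        assert t.chi2 == 0.0 and t.p_value == 1.0

    def test_closed_form_chi2(self):
        t = PairedDiffTest(20, 5)
        assert t.chi2 == pytest.approx(24.5, abs=1e-12)
        assert t.p_value == pytest.approx(7.431e-7, rel=0.01)
        assert t.expected_display == (8, 17)

    def test_expected_follows_one_third_rule(self):
        t = PairedDiffTest(7, 5)
        assert t.expected_paired == pytest.approx(4.0)
        assert t.expected_unpaired == pytest.approx(8.0)

    def test_zero_events_undefined(self):
        t = PairedDiffTest(0, 0)
        assert t.undefined and np.isnan(t.chi2)

    def test_event_counting_conditions_on_paired_parent(self):
        tree = balanced_tree()
        # L1 edge: double change from WC parent, restoring (GC -> AU): paired
        # L3 edge: double change from WC parent, breaking (GC -> AG): unpaired
        # L4 edge: double change from non-WC parent: not counted
        states = states_for(tree, {
            "root": "GC", "n1": "GC", "L1": "AU", "L2": "GC",
            "n2": "GG", "L3": "GG", "L4": "AU"})
        states[node_ids(tree)["n1"]] = [CODE["G"], CODE["C"]]
        paired, unpaired = paired_difference_events(states, tree, PAIR_SS)
        assert (paired, unpaired) == (1, 0)
        states2 = states_for(tree, {
            "root": "GC", "n1": "GC", "L1": "AU", "L2": "GC",
            "n2": "GC", "L3": "AG", "L4": "GC"})
        paired, unpaired = paired_difference_events(states2, tree, PAIR_SS)
        assert (paired, unpaired) == (1, 1)


class TestStemIntegrity:
    def test_perfect_stems_zero_everywhere(self):
        tree = balanced_tree()
        states = states_for(tree, {lbl: "GC" for lbl in
                                   ("root", "n1", "n2", "L1", "L2", "L3", "L4")})
        df = stem_integrity_trajectory(states, PAIR_SS, tree)
        assert (df["n_unpaired_in_stems"] == 0).all()

    def test_single_mismatch_increments_by_one(self):
        tree = balanced_tree()
        ids = node_ids(tree)
        states = states_for(tree, {lbl: "GC" for lbl in
                                   ("root", "n1", "n2", "L1", "L2", "L3", "L4")})
        states[ids["L1"]] = [CODE["G"], CODE["G"]]
        df = stem_integrity_trajectory(states, PAIR_SS, tree).set_index("node")
        assert df.loc[ids["L1"], "n_unpaired_in_stems"] == 1
        assert df.loc[ids["n1"], "n_unpaired_in_stems"] == 0

    def test_wobble_configurable(self):
        tree = balanced_tree()
        states = states_for(tree, {lbl: "GU" for lbl in
                                   ("root", "n1", "n2", "L1", "L2", "L3", "L4")})
        ok = stem_integrity_trajectory(states, PAIR_SS, tree, wobble_ok=True)
        strict = stem_integrity_trajectory(states, PAIR_SS, tree, wobble_ok=False)
        assert (ok["n_unpaired_in_stems"] == 0).all()
        assert (strict["n_unpaired_in_stems"] == 1).all()

    def test_hand_tallied_three_node_path(self):
        tree = parse_tree_string("((L1:1)n1:1)root;")
        ss = SecondaryStructure.from_dotbracket("(())")
        ids = node_ids(tree)
        states = np.zeros((tree.n_nodes, 4), dtype=np.int64)
        seqs = {"root": "GCGC", "n1": "GGGC", "L1": "GGGG"}
        for lbl, s in seqs.items():
            v = ids[lbl] if lbl != "root" else tree.root
            states[v] = [CODE[c] for c in s]
        df = stem_integrity_trajectory(states, ss, tree).set_index("node")
        # pairs are (1,4) and (2,3) 1-based: root GC/CG->ok,ok; n1 GC/GG; L1 GG/GG
        assert df.loc[tree.root, "n_unpaired_in_stems"] == 0
        assert df.loc[ids["n1"], "n_unpaired_in_stems"] == 1
        assert df.loc[ids["L1"], "n_unpaired_in_stems"] == 2


class TestMechanisms:
    def test_direct_wc_restoration(self):
        tree = parse_tree_string("((L1:1)n1:1)root;")
        ss = SecondaryStructure.from_dotbracket("()")
        ids = node_ids(tree)
        states = np.zeros((tree.n_nodes, 2), dtype=np.int64)
        for lbl, d in {"root": "GC", "n1": "GU", "L1": "GC"}.items():
            v = ids[lbl] if lbl != "root" else tree.root
            states[v] = [CODE[c] for c in d]
        df = classify_compensation_mechanisms(states, tree, ss)
        assert list(df["mechanism"]) == ["direct-WC"]

    def test_multi_site_and_uncompensated(self):
        tree = parse_tree_string("((L1:1)n1:1)root;")
        # two pairs in one helix: (1,8),(2,7) sites 3..6 are an inner loop
        ss = SecondaryStructure.from_dotbracket("((....))")
        ids = node_ids(tree)
        states = np.zeros((tree.n_nodes, 8), dtype=np.int64)
        seqs = {"root": "GCAAAAGC", "n1": "GUAAAAGC", "L1": "GUAAAAGC"}
        for lbl, s in seqs.items():
            v = ids[lbl] if lbl != "root" else tree.root
            states[v] = [CODE[c] for c in s]
        df = classify_compensation_mechanisms(states, tree, ss)
        assert list(df["mechanism"]) == ["uncompensated"]

    def test_records_table_columns(self):
        assert list(records_to_table([]).columns)[:4] == \
            ["dataset", "site_i", "site_j", "switch_type"]
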