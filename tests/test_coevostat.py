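"""Mutual information, MIp, substitution-vector correlation and bootstrap null."""

import numpy as np
import pytest
from scipy.stats import kstest

from conftest import alignment_from_columns
from rnacoevo import (GtrGammaModel, RnaAlignment, consensus_pairs, mip_matrix,
                      mutual_information, parametric_bootstrap_null,
                      simulate_neutral, vector_correlation, yule_tree)
from rnacoevo.ancestor import SubstitutionMap
from rnacoevo.coevostat import (CoevolutionError, CoevolutionScore,
                                attach_vector_pvalues, scores_to_table)
from rnacoevo.rnasim import five_s_template
from rnacoevo.seqdata import parse_tree_string


class TestMutualInformation:
    def test_invariant_columns_zero(self):
        aln = alignment_from_columns(["AAAA", "CCCC"])
        assert mutual_information(aln, 0, 1)[0] == 0.0

    def test_perfect_two_state_covariation_ln2(self):
        aln = alignment_from_columns(["AAGG", "UUCC"])
        mi, joint = mutual_information(aln, 0, 1)
        assert mi == pytest.approx(np.log(2), abs=1e-12)
        assert joint.sum() == 4

    def test_six_taxon_hand_computation(self):
        aln = alignment_from_columns(["AAAGGG", "UUCCCC"])
        mi, _ = mutual_information(aln, 0, 1)
        expected = ((2 / 6) * np.log((2 / 6) / (0.5 * (1 / 3)))
                    + (1 / 6) * np.log((1 / 6) / (0.5 * (2 / 3)))
                    + (3 / 6) * np.log((3 / 6) / (0.5 * (2 / 3))))
        assert mi == pytest.approx(expected, abs=1e-12)

    def test_symmetry(self):
        aln = alignment_from_columns(["AAGC", "UGCC", "ACGU"])
        assert mutual_information(aln, 0, 2)[0] == \
            pytest.approx(mutual_information(aln, 2, 0)[0], abs=1e-15)

    def test_pairwise_gap_deletion(self):
        aln = alignment_from_columns(["AAG-", "UU-C", "ACGU"])
        # taxa 3 and 4 dropped for pair (1,2): joint over (A,U),(A,U)
        mi, joint = mutual_information(aln, 0, 1)
        assert joint.sum() == 2

    def test_undefined_below_two_taxa(self):
        aln = alignment_from_columns(["A--", "-CC", "GGG"])
        with pytest.raises(CoevolutionError):
            mutual_information(aln, 0, 1)


class TestMipMatrix:
    def test_three_site_toy_matches_definition(self):
        aln = alignment_from_columns(["AAGG", "UUCC", "AGAG"])
        scores = mip_matrix(aln, [0, 1, 2], n_permutations=0, seed=0)
        mi = {}
        for sc in scores:
            mi[sc.pair] = sc.mi
        m01, m02, m12 = mi[(0, 1)], mi[(0, 2)], mi[(1, 2)]
        grand = (m01 + m02 + m12) / 3
        row = {0: (m01 + m02) / 2, 1: (m01 + m12) / 2, 2: (m02 + m12) / 2}
        for sc in scores:
            i, j = sc.pair
            assert sc.apc == pytest.approx(row[i] * row[j] / grand, abs=1e-12)
            assert sc.mip == pytest.approx(sc.mi - sc.apc, abs=1e-12)

    def test_duplicated_column_attains_max_mip(self):
        rng = np.random.default_rng(0)
        cols = ["".join(rng.choice(list("ACGU"), 50)) for _ in range(10)]
        cols.append(cols[4])  # perfect dependence with column 4
        aln = alignment_from_columns(cols)
        scores = mip_matrix(aln, range(11), n_permutations=0, seed=0)
        best = max(scores, key=lambda s: s.mip)
        assert best.pair == (4, 10)

    def test_all_invariant_apc_zero(self):
        aln = alignment_from_columns(["AAAA", "CCCC", "GGGG"])
        scores = mip_matrix(aln, [0, 1, 2], n_permutations=0, seed=0)
        assert all(sc.apc == 0.0 and sc.mi == 0.0 for sc in scores)

    def test_needs_three_sites(self):
        aln = alignment_from_columns(["AAGG", "UUCC"])
        with pytest.raises(CoevolutionError):
            mip_matrix(aln, [0, 1])

    def test_iid_calibration(self):
        rng = np.random.default_rng(42)
        codes = rng.integers(0, 4, size=(200, 20)).astype(np.int8)
        aln = RnaAlignment([f"t{k}" for k in range(200)], codes)
        scores = mip_matrix(aln, range(20), n_permutations=300, seed=1)
        fp_z = np.mean([sc.p_mip < 0.05 for sc in scores])
        fp_perm = np.mean([sc.p_perm < 0.05 for sc in scores])
        assert 0.02 <= fp_z <= 0.08
        assert 0.02 <= fp_perm <= 0.08


class TestVectorCorrelation:
    def _smap(self, counts):
        counts = np.asarray(counts)
        return SubstitutionMap(counts, np.ones(counts.shape, dtype=bool),
                               np.zeros(counts.shape, dtype=np.int64))

    def test_identical_vectors(self):
        counts = np.array([[0, 0], [1, 1], [0, 0], [1, 1], [0, 0]])
        assert vector_correlation(self._smap(counts), 0, 1) == pytest.approx(1.0)

    def test_disjoint_support_minus_one_third(self):
        counts = np.array([[1, 0], [0, 1], [0, 0], [0, 0]])
        assert vector_correlation(self._smap(counts), 0, 1) == \
            pytest.approx(-1 / 3, abs=1e-12)

    def test_invariant_site_flagged(self):
        counts = np.array([[0, 1], [0, 0], [0, 1]])
        with pytest.raises(CoevolutionError):
            vector_correlation(self._smap(counts), 0, 1)


@pytest.fixture(scope="module")
def small_null():
    tree = yule_tree(20, 0.6, np.random.default_rng(3))
    model = GtrGammaModel()
    null = parametric_bootstrap_null(tree, model, 40, n_replicates=150,
                                     seed=5, reconstruct=False)
    return tree, model, null


class TestBootstrapNull:
    def test_deterministic_under_seed(self):
        tree = yule_tree(10, 0.5, np.random.default_rng(1))
        m = GtrGammaModel()
        a = parametric_bootstrap_null(tree, m, 20, 100, seed=9, reconstruct=False)
        b = parametric_bootstrap_null(tree, m, 20, 100, seed=9, reconstruct=False)
        assert np.array_equal(a.stats, b.stats)
        assert np.array_equal(a.min_subs, b.min_subs)

    def test_refuses_tiny_replicate_count(self):
        tree = yule_tree(6, 0.5, np.random.default_rng(1))
        with pytest.raises(CoevolutionError):
            parametric_bootstrap_null(tree, GtrGammaModel(), 10, 50)

    def test_below_median_gives_large_p(self, small_null):
        _, _, null = small_null
        med = np.median(null.stats)
        assert null.p_value(med - 0.2, 0.0) >= 0.5

    def test_monotone_in_statistic_within_stratum(self, small_null):
        _, _, null = small_null
        for v in (0.0, 2.0, 5.0):
            ps = [null.p_value(s, v) for s in np.linspace(-0.5, 1.0, 12)]
            assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))

    def test_null_pvalues_approximately_uniform(self, small_null):
        tree, model, null = small_null
        rng = np.random.default_rng(17)
        pvals = []
        for rep in range(150):
            sim = simulate_neutral(tree, model, 40, int(rng.integers(2**31)))
            counts = sim.edge_change_matrix()
            totals = counts[1:].sum(axis=0)
            x = counts[1:, 0].astype(float)
            y = counts[1:, 1].astype(float)
            if x.std() == 0 or y.std() == 0:
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            pvals.append(null.p_value(r, float(min(totals[0], totals[1]))))
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestConsensus:
    def _scores(self):
        return [
            CoevolutionScore((0, 1), 1.0, 0.2, 0.8, vector_r=0.9,
                             p_mip=0.001, p_vector=0.002),
            CoevolutionScore((0, 2), 0.5, 0.2, 0.3, vector_r=0.1,
                             p_mip=0.01, p_vector=0.9),   # MIp only
            CoevolutionScore((1, 2), 0.1, 0.1, 0.0, vector_r=0.2,
                             p_mip=0.8, p_vector=0.01),   # vector only
        ]

    def test_intersection_rule(self):
        out = consensus_pairs(self._scores(), alpha=0.05, use_fdr=False)
        assert len(out) == 1
        assert (out["site_i"][0], out["site_j"][0]) == (1, 2)  # 1-based

    def test_alpha_zero_empty(self):
        assert len(consensus_pairs(self._scores(), alpha=1e-12,
                                   use_fdr=False)) == 0

    def test_position_class_annotation(self):
        ss = five_s_template()
        i, j = ss.pairs[0]
        sc = [CoevolutionScore((i, j), 1.0, 0.1, 0.9, vector_r=0.9,
                               p_mip=0.001, p_vector=0.001),
              CoevolutionScore((i, ss.pairs[1][1]), 0.1, 0.1, 0.0,
                               vector_r=0.0, p_mip=0.9, p_vector=0.9),
              CoevolutionScore((j, ss.pairs[1][0]), 0.1, 0.1, 0.0,
                               vector_r=0.0, p_mip=0.9, p_vector=0.9)]
        out = consensus_pairs(sc, alpha=0.05, ss=ss, use_fdr=False)
        assert len(out) == 1
        assert out["helix"][0] == "I"
        assert out["position_class"][0] in ("near-loop", "near-bulge", "other")

    def test_attach_handles_invariant_sites(self):
        counts = np.zeros((5, 3), dtype=np.int64)
        counts[1, 0] = counts[2, 1] = 1
        smap = SubstitutionMap(counts, np.ones(counts.shape, dtype=bool),
                               np.zeros(counts.shape, dtype=np.int64))
        tree = yule_tree(10, 0.5, np.random.default_rng(0))
        null = parametric_bootstrap_null(tree, GtrGammaModel(), 10, 100,
                                         seed=1, reconstruct=False)
        scores = [CoevolutionScore((0, 2), 0.5, 0.1, 0.4),
                  CoevolutionScore((0, 1), 0.5, 0.1, 0.4)]
        attach_vector_pvalues(scores, smap, null)
        assert scores[0].p_vector is None      # site 2 never substitutes
        assert scores[1].p_vector is not None

    def test_scores_table_has_fdr_columns(self):
        df = scores_to_table(self._scores())
        assert {"q_mip", "q_vector"} <= set(df.columns)
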