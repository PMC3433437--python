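"""Coevolution detection: APC-corrected mutual information and substitution-vector
correlation with a parametric-bootstrap null.

Two independent detectors are combined:

* **MIp** — mutual information between alignment columns (natural log) minus
  the average-product correction (APC), which absorbs shared background and
  phylogenetic signal without assuming a tree.  Significance comes from a
  within-column permutation null.
* **Vector correlation** — Pearson correlation between per-branch substitution
  indicator vectors from ancestral reconstruction; significance from a
  parametric bootstrap simulating independent-site evolution on the same tree
  and model, stratified on minimum site variability.

Only pairs significant under both detectors are reported as coevolving.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from .ancestor import SubstitutionMap, map_substitutions, reconstruct_ancestors
from .evomodel import GtrGammaModel
from .rnasim import simulate_neutral
from .seqdata import PhyloTree, RnaAlignment, RnacoevoError, SecondaryStructure


class CoevolutionError(RnacoevoError):
    pass


# ---------------------------------------------------------------------------
# Mutual information
# ---------------------------------------------------------------------------

def _joint_counts(ci: np.ndarray, cj: np.ndarray) -> np.ndarray:
    return np.bincount(ci * 4 + cj, minlength=16).reshape(4, 4).astype(float)


def _mi_from_counts(joint: np.ndarray) -> float:
    n = joint.sum()
    if n == 0:
        return 0.0
    p = joint / n
    pi = p.sum(axis=1, keepdims=True)
    pj = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log(p / (pi * pj))
    return float(np.nansum(terms))


def mutual_information(aln: RnaAlignment, i: int, j: int
                       ) -> tuple[float, np.ndarray]:
    """MI (nats) between columns i and j with pairwise gap deletion.

    Returns the MI and the 4x4 joint count table.  Frequencies are plug-in
    counts without pseudocounts.
    """
    ci, cj = aln.column(i), aln.column(j)
    ok = (ci >= 0) & (cj >= 0)
    if ok.sum() < 2:
        raise CoevolutionError(
            f"fewer than 2 ungapped taxa for site pair ({i + 1},{j + 1})")
    joint = _joint_counts(ci[ok].astype(np.int64), cj[ok].astype(np.int64))
    return _mi_from_counts(joint), joint


def _perm_mi_null(ci: np.ndarray, cj: np.ndarray, n_perm: int,
                  rng: np.random.Generator) -> np.ndarray:
    """MI under within-column permutation of cj, vectorised over permutations."""
    n = ci.size
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    cj_perm = cj[order]  # (n_perm, n)
    cells = (np.arange(n_perm)[:, None] * 16 + ci[None, :] * 4 + cj_perm)
    counts = np.bincount(cells.ravel(), minlength=n_perm * 16).reshape(n_perm, 4, 4)
    p = counts / n
    pi = p.sum(axis=2, keepdims=True)
    pj = p.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log(p / (pi * pj))
    return np.nansum(terms, axis=(1, 2))


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------

@dataclass
class CoevolutionScore:
    pair: tuple[int, int]          # 0-based (i, j)
    mi: float
    apc: float
    mip: float
    vector_r: float | None = None
    p_mip: float | None = None     # background-standardised MIp tail probability
    z_mip: float | None = None
    p_perm: float | None = None    # within-column permutation p (no tree correction)
    p_vector: float | None = None

    def to_row(self) -> dict:
        i, j = self.pair
        return {"site_i": i + 1, "site_j": j + 1, "mi": self.mi,
                "apc": self.apc, "mip": self.mip,
                "vector_r": self.vector_r, "p_mip": self.p_mip,
                "z_mip": self.z_mip, "p_perm": self.p_perm,
                "p_vector": self.p_vector}


def _mi_all_pairs(aln: RnaAlignment, sites: np.ndarray) -> np.ndarray:
    """Symmetric MI matrix over a site set.

    Gap-free alignments take a one-hot tensor fast path; otherwise each pair
    is computed with pairwise gap deletion.
    """
    m = sites.size
    codes = aln.codes[:, sites]
    if (codes >= 0).all():
        X = np.eye(4)[codes]                       # (n_taxa, m, 4)
        joint = np.einsum("tax,tby->abxy", X, X)   # (m, m, 4, 4)
        n = codes.shape[0]
        p = joint / n
        pi = p.sum(axis=3, keepdims=True)
        pj = p.sum(axis=2, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = p * np.log(p / (pi * pj))
        mi = np.nansum(terms, axis=(2, 3))
        np.fill_diagonal(mi, 0.0)
        return mi
    mi = np.zeros((m, m))
    for a in range(m):
        for b in range(a + 1, m):
            mi[a, b] = mi[b, a] = mutual_information(
                aln, int(sites[a]), int(sites[b]))[0]
    return mi


def mip_matrix(aln: RnaAlignment, sites: np.ndarray | list[int],
               n_permutations: int = 1000, seed: int = 0
               ) -> list[CoevolutionScore]:
    """MI, APC and MIp for every pair of the given sites.

    APC(i,j) = MI(i,.) * MI(.,j) / mean(MI) over the site set.  Two
    significance measures are attached:

    * ``p_mip`` / ``z_mip`` — MIp standardised against the empirical
      mean and spread of MIp over all scored pairs (one-sided normal tail).
      Because the background pairs share the alignment's phylogenetic
      structure, this is the tree-robust measure.
    * ``p_perm`` — within-column permutation of one column
      (``n_permutations`` shuffles; 0 skips it).  Exact for exchangeable
      taxa, anticonservative when taxa are related.
    """
    import logging

    from scipy.stats import norm
    sites = np.asarray(list(sites), dtype=np.int64)
    m = sites.size
    if m < 3:
        raise CoevolutionError("APC needs at least 3 sites")
    rng = np.random.default_rng(seed)
    mi = _mi_all_pairs(aln, sites)
    row_mean = mi.sum(axis=1) / (m - 1)
    grand = mi[np.triu_indices(m, 1)].mean()
    if grand == 0:
        logging.getLogger("rnacoevo").warning(
            "all columns invariant: APC set to 0 by convention")
    scores = []
    for a in range(m):
        for b in range(a + 1, m):
            apc = row_mean[a] * row_mean[b] / grand if grand > 0 else 0.0
            i, j = int(sites[a]), int(sites[b])
            obs = mi[a, b]
            p_perm = None
            if n_permutations > 0:
                ci, cj = aln.column(i), aln.column(j)
                ok = (ci >= 0) & (cj >= 0)
                null = _perm_mi_null(ci[ok].astype(np.int64),
                                     cj[ok].astype(np.int64),
                                     n_permutations, rng)
                p_perm = (1.0 + float((null >= obs - 1e-12).sum())) \
                    / (n_permutations + 1.0)
            scores.append(CoevolutionScore(
                pair=(i, j), mi=obs, apc=apc, mip=obs - apc, p_perm=p_perm))
    mips = np.array([sc.mip for sc in scores])
    mu = mips.mean()
    sd = mips.std()
    for sc in scores:
        z = (sc.mip - mu) / sd if sd > 0 else 0.0
        sc.z_mip = float(z)
        sc.p_mip = float(norm.sf(z))
    return scores


# ---------------------------------------------------------------------------
# Substitution-vector correlation
# ---------------------------------------------------------------------------

def vector_correlation(smap: SubstitutionMap, i: int, j: int) -> float:
    """Pearson correlation of the two per-branch substitution vectors.

    Raises when either site has no substitutions (zero-variance vector).
    """
    ok = smap.valid[:, i] & smap.valid[:, j]
    vi = smap.counts[ok, i].astype(float)
    vj = smap.counts[ok, j].astype(float)
    if vi.std() == 0 or vj.std() == 0:
        raise CoevolutionError(
            f"site {i + 1} or {j + 1} has a constant substitution vector")
    return float(np.corrcoef(vi, vj)[0, 1])


def _all_pair_correlations(counts: np.ndarray, sites: np.ndarray
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Correlation matrix and per-site substitution totals for a site set."""
    X = counts[1:, sites].astype(float)  # drop root row (always zero)
    totals = X.sum(axis=0)
    sd = X.std(axis=0)
    Xc = X - X.mean(axis=0)
    denom = np.outer(sd, sd) * X.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (Xc.T @ Xc) / denom
    return corr, totals


# ---------------------------------------------------------------------------
# Parametric bootstrap null
# ---------------------------------------------------------------------------

@dataclass
class BootstrapNull:
    """Joint null of (minimum site substitution count, pair statistic)."""

    stats: np.ndarray      # statistic per null pair, flattened over replicates
    min_subs: np.ndarray   # matching minimum per-site substitution totals
    n_replicates: int
    stratum_size: int = 50_000  # target size of the locally matched pool

    def _buckets(self):
        """Sorted null stats bucketed by integer minimum-substitution count."""
        if not hasattr(self, "_bucket_cache"):
            v = np.minimum(self.min_subs, 1_000).astype(np.int64)
            order = np.argsort(v, kind="stable")
            sv, ss = v[order], self.stats[order]
            starts = np.searchsorted(sv, np.arange(sv[-1] + 2))
            sorted_by_bucket = [np.sort(ss[starts[k]:starts[k + 1]])
                                for k in range(sv[-1] + 1)]
            self._bucket_cache = sorted_by_bucket
        return self._bucket_cache

    def p_value(self, observed_stat: float, observed_min_subs: float) -> float:
        """Fraction of comparable null pairs at least as extreme as observed.

        Comparable = the null pairs closest in minimum site variability to
        the observed pair: the window around the observed value grows until
        it holds ``stratum_size`` entries (or the whole null), so p-values
        stay locally matched yet fine-grained enough for multiple-testing
        control.  Ties in window growth prefer the higher-variability side.
        """
        buckets = self._buckets()
        v = int(min(max(observed_min_subs, 0), len(buckets) - 1))
        lo = hi = v
        pool = buckets[v].size
        while pool < min(self.stratum_size, self.stats.size):
            grow_hi = hi + 1 < len(buckets)
            grow_lo = lo > 0
            if grow_hi:
                hi += 1
                pool += buckets[hi].size
            if pool >= self.stratum_size:
                break
            if grow_lo:
                lo -= 1
                pool += buckets[lo].size
            if not (grow_hi or grow_lo):
                break
        ge = sum(b.size - np.searchsorted(b, observed_stat - 1e-12, side="left")
                 for b in buckets[lo:hi + 1])
        return (1.0 + float(ge)) / (pool + 1.0)

    def quantile(self, q: float) -> float:
        return float(np.quantile(self.stats, q))


def parametric_bootstrap_null(tree: PhyloTree, model: GtrGammaModel,
                              n_sites: int, n_replicates: int = 500,
                              seed: int = 0, reconstruct: bool = True
                              ) -> BootstrapNull:
    """Null distribution of pairwise vector correlation under independent sites.

    Each replicate simulates a neutral alignment on the analysis tree and
    model, runs the same reconstruction + substitution mapping as the real
    analysis (``reconstruct=False`` short-cuts to the simulated true states),
    and records every site pair's correlation together with the pair's
    minimum substitution total.
    """
    if n_replicates < 100:
        raise CoevolutionError(
            "parametric bootstrap needs >= 100 replicates for p-values; "
            "raise n_replicates")
    rng = np.random.default_rng(seed)
    all_stats: list[np.ndarray] = []
    all_min: list[np.ndarray] = []
    sites = np.arange(n_sites)
    for rep in range(n_replicates):
        rep_seed = int(rng.integers(2 ** 31 - 1))
        sim = simulate_neutral(tree, model, n_sites, rep_seed)
        if reconstruct:
            recon = reconstruct_ancestors(sim.alignment, tree, model)
            smap = map_substitutions(recon, sim.alignment, tree)
            counts = smap.counts
        else:
            counts = sim.edge_change_matrix()
        corr, totals = _all_pair_correlations(counts, sites)
        iu = np.triu_indices(n_sites, 1)
        stat = corr[iu]
        keep = np.isfinite(stat)
        pair_min = np.minimum(totals[iu[0]], totals[iu[1]])
        all_stats.append(stat[keep])
        all_min.append(pair_min[keep])
    return BootstrapNull(np.concatenate(all_stats), np.concatenate(all_min),
                         n_replicates)


def attach_vector_pvalues(scores: list[CoevolutionScore], smap: SubstitutionMap,
                          null: BootstrapNull) -> list[CoevolutionScore]:
    """Fill vector_r and its bootstrap p-value for each scored pair in place."""
    totals = smap.counts[1:].sum(axis=0)
    for sc in scores:
        i, j = sc.pair
        try:
            r = vector_correlation(smap, i, j)
        except CoevolutionError:
            sc.vector_r = None
            sc.p_vector = None
            continue
        sc.vector_r = r
        sc.p_vector = null.p_value(r, float(min(totals[i], totals[j])))
    return scores


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

def scores_to_table(scores: list[CoevolutionScore],
                    ss: SecondaryStructure | None = None) -> pd.DataFrame:
    rows = [sc.to_row() for sc in scores]
    df = pd.DataFrame(rows, columns=["site_i", "site_j", "mi", "apc", "mip",
                                     "vector_r", "p_mip", "z_mip", "p_perm",
                                     "p_vector"])
    if len(df):
        for col in ("p_mip", "p_vector"):
            vals = df[col].to_numpy(dtype=float)
            ok = np.isfinite(vals)
            q = np.full(vals.shape, np.nan)
            if ok.sum():
                q[ok] = false_discovery_control(vals[ok])
            df[col.replace("p_", "q_")] = q
    if ss is not None and len(df):
        df["position_class"] = [
            ss.position_class[i - 1] if ss.pair_table[i - 1] >= 0 else None
            for i in df["site_i"]]
        df["helix"] = [ss.helix_of(i - 1) for i in df["site_i"]]
    return df


def consensus_pairs(scores: list[CoevolutionScore], alpha: float = 0.05,
                    ss: SecondaryStructure | None = None,
                    use_fdr: bool = True) -> pd.DataFrame:
    """Pairs significant under BOTH MIp and vector-correlation at ``alpha``.

    By default the threshold is applied to Benjamini-Hochberg adjusted
    p-values of each detector (thousands of candidate pairs are scored, so
    raw per-pair thresholds would drown the consensus in false positives);
    ``use_fdr=False`` applies ``alpha`` to the raw p-values instead.
    """
    scored = [sc for sc in scores
              if sc.p_mip is not None and sc.p_vector is not None]
    if not scored:
        return scores_to_table([], ss)
    if use_fdr:
        q_mip = false_discovery_control(np.array([sc.p_mip for sc in scored]))
        q_vec = false_discovery_control(np.array([sc.p_vector for sc in scored]))
        hits = [sc for sc, qm, qv in zip(scored, q_mip, q_vec)
                if qm <= alpha and qv <= alpha]
    else:
        hits = [sc for sc in scored
                if sc.p_mip <= alpha and sc.p_vector <= alpha]
    return scores_to_table(hits, ss)
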