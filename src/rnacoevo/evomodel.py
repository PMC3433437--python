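"""GTR+G nucleotide substitution model and pruning-based likelihood machinery.

The general time-reversible (GTR) model is parameterised by six symmetric
exchangeabilities (AC, AG, AU, CG, CU, GU) and four stationary frequencies.
Rate variation across sites follows a discrete gamma with ``n_categories``
equal-probability bins represented by their means (mean rate 1).  The rate
matrix is normalised so branch lengths are expected substitutions per site at
equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammainc, logsumexp
from scipy.stats import gamma as gamma_dist
from scipy.stats import mannwhitneyu

from .seqdata import BindingError, PhyloTree, RnaAlignment, RnacoevoError

_EXCH_ORDER = ("AC", "AG", "AU", "CG", "CU", "GU")
_EXCH_IDX = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


class ParameterError(RnacoevoError):
    pass


def discrete_gamma_rates(alpha: float, n_categories: int) -> np.ndarray:
    """Mean rates of equal-probability gamma bins (shape=rate=alpha), mean 1."""
    if alpha <= 0:
        raise ParameterError("gamma shape alpha must be > 0")
    k = n_categories
    if k == 1:
        return np.ones(1)
    # bin boundaries on the rate scale, then bin means via the incomplete
    # gamma identity E[r | a<r<b] * P(a<r<b) = I(b*alpha; alpha+1) - I(a*alpha; alpha+1)
    bounds = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    upper = np.concatenate([gammainc(alpha + 1, bounds * alpha), [1.0]])
    lower = np.concatenate([[0.0], gammainc(alpha + 1, bounds * alpha)])
    rates = k * (upper - lower)
    return rates / rates.mean()


@dataclass
class GtrGammaModel:
    """GTR+G model; defaults are an arbitrary-but-reasonable rRNA-like setting."""

    exchangeabilities: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 1.5, 1.0, 1.0, 1.5, 1.0]))
    stationary_freqs: np.ndarray = field(
        default_factory=lambda: np.array([0.26, 0.24, 0.27, 0.23]))
    alpha: float = 1.0
    n_categories: int = 4

    def __post_init__(self) -> None:
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.stationary_freqs = np.asarray(self.stationary_freqs, dtype=float)
        if self.exchangeabilities.shape != (6,) or np.any(self.exchangeabilities <= 0):
            raise ParameterError("need 6 positive exchangeabilities (AC AG AU CG CU GU)")
        if self.stationary_freqs.shape != (4,) or np.any(self.stationary_freqs <= 0):
            raise ParameterError("need 4 positive stationary frequencies")
        if not np.isclose(self.stationary_freqs.sum(), 1.0, atol=1e-6):
            raise ParameterError("stationary frequencies must sum to 1")
        self.stationary_freqs = self.stationary_freqs / self.stationary_freqs.sum()
        if self.n_categories < 1:
            raise ParameterError("n_categories must be >= 1")
        self._decompose()

    @classmethod
    def jukes_cantor(cls, alpha: float = 1.0, n_categories: int = 1) -> "GtrGammaModel":
        return cls(np.ones(6), np.full(4, 0.25), alpha=alpha, n_categories=n_categories)

    # -- rate matrix -----------------------------------------------------
    def _decompose(self) -> None:
        self.Q = build_rate_matrix(self)
        pi = self.stationary_freqs
        sq = np.sqrt(pi)
        B = self.Q * sq[:, None] / sq[None, :]
        B = (B + B.T) / 2.0  # symmetric by reversibility; enforce numerically
        w, U = np.linalg.eigh(B)
        self._eigvals = w
        self._left = U * (1.0 / sq)[:, None]      # D^{-1/2} U
        self._right = (U * sq[:, None]).T         # U^T D^{1/2}
        self.category_rates = discrete_gamma_rates(self.alpha, self.n_categories)

    def transition_matrix(self, t: float, rate_scalar: float = 1.0) -> np.ndarray:
        """P(t) = exp(Q * t * rate_scalar); rows sum to 1."""
        if t < 0:
            raise ParameterError("branch length must be non-negative")
        e = np.exp(self._eigvals * (t * rate_scalar))
        P = (self._left * e) @ self._right
        np.clip(P, 0.0, 1.0, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def config_dict(self) -> dict:
        return {
            "exchangeabilities": {k: float(v) for k, v in
                                  zip(_EXCH_ORDER, self.exchangeabilities)},
            "frequencies": {b: float(f) for b, f in
                            zip("ACGU", self.stationary_freqs)},
            "alpha": float(self.alpha),
            "n_categories": int(self.n_categories),
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "GtrGammaModel":
        ex = cfg.get("exchangeabilities", {})
        fr = cfg.get("frequencies", {})
        if isinstance(ex, dict):
            ex = [ex[k] for k in _EXCH_ORDER]
        if isinstance(fr, dict):
            fr = [fr[b] for b in "ACGU"]
        return cls(np.asarray(ex, float), np.asarray(fr, float),
                   alpha=float(cfg.get("alpha", 0.7)),
                   n_categories=int(cfg.get("n_categories", 4)))


def build_rate_matrix(model: GtrGammaModel) -> np.ndarray:
    """GTR generator: Q_ij = s_ij * pi_j, rows sum to 0, unit mean rate."""
    pi = model.stationary_freqs
    S = np.zeros((4, 4))
    for rate, (i, j) in zip(model.exchangeabilities, _EXCH_IDX):
        S[i, j] = S[j, i] = rate
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -np.dot(pi, np.diag(Q))
    return Q / mu


def transition_probabilities(model: GtrGammaModel, t: float,
                             rate_scalar: float = 1.0) -> np.ndarray:
    return model.transition_matrix(t, rate_scalar)


# ---------------------------------------------------------------------------
# Pruning likelihood
# ---------------------------------------------------------------------------

def leaf_partials(aln: RnaAlignment, tree: PhyloTree) -> tuple[np.ndarray, np.ndarray]:
    """Tip conditional likelihoods, shape (n_nodes, n_sites, 4).

    Gaps and ambiguous characters give all-ones rows (missing data).  Internal
    node slots are allocated but unset.  Also returns the leaf->row binding.
    """
    binding = tree.bind(aln)
    L = aln.n_sites
    partials = np.ones((tree.n_nodes, L, 4))
    eye = np.eye(4)
    for v in tree.leaves:
        codes = aln.codes[binding[v]]
        known = codes >= 0
        partials[v, known] = eye[codes[known]]
    return partials, binding


def _pruning_pass(tree: PhyloTree, model: GtrGammaModel, tip_partials: np.ndarray,
                  rate: float) -> tuple[np.ndarray, np.ndarray]:
    """One postorder pass at a fixed rate multiplier.

    Returns (partials, log_scale) where ``partials[v]`` are per-site
    conditionals at v scaled to max 1, and ``log_scale[v]`` the per-site log of
    the factor removed from the subtree rooted at v.
    """
    n, L = tree.n_nodes, tip_partials.shape[1]
    partials = tip_partials.copy()
    log_scale = np.zeros((n, L))
    for v in tree.postorder:
        kids = tree.children[v]
        if not kids:
            continue
        acc = np.ones((L, 4))
        sc = np.zeros(L)
        for c in kids:
            P = model.transition_matrix(tree.lengths[c], rate)
            acc *= partials[c] @ P.T
            sc += log_scale[c]
        m = acc.max(axis=1)
        m[m == 0] = 1.0
        partials[v] = acc / m[:, None]
        log_scale[v] = sc + np.log(m)
    return partials, log_scale


def site_log_likelihoods(aln: RnaAlignment, tree: PhyloTree,
                         model: GtrGammaModel) -> np.ndarray:
    """Per-site, per-category log-likelihoods, shape (n_categories, n_sites)."""
    tip, _ = leaf_partials(aln, tree)
    pi = model.stationary_freqs
    out = np.empty((model.n_categories, aln.n_sites))
    for k, r in enumerate(model.category_rates):
        partials, log_scale = _pruning_pass(tree, model, tip, r)
        root_like = partials[tree.root] @ pi
        out[k] = np.log(root_like) + log_scale[tree.root]
    return out


def log_likelihood(aln: RnaAlignment, tree: PhyloTree, model: GtrGammaModel) -> float:
    """Alignment log-likelihood, gamma categories averaged with equal weights."""
    per_cat = site_log_likelihoods(aln, tree, model)
    site_ll = logsumexp(per_cat, axis=0) - np.log(model.n_categories)
    return float(site_ll.sum())


def category_posteriors(aln: RnaAlignment, tree: PhyloTree,
                        model: GtrGammaModel) -> np.ndarray:
    """P(category k | site data), shape (n_categories, n_sites)."""
    per_cat = site_log_likelihoods(aln, tree, model)
    w = per_cat - logsumexp(per_cat, axis=0, keepdims=True)
    return np.exp(w)


# ---------------------------------------------------------------------------
# Site-specific rates
# ---------------------------------------------------------------------------

@dataclass
class SiteRates:
    """Posterior-mean relative rate per site (dimensionless, mean ~ 1)."""

    rates: np.ndarray

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)


def site_rates(aln: RnaAlignment, tree: PhyloTree, model: GtrGammaModel) -> SiteRates:
    """Posterior mean of the discrete-gamma category rate at each site."""
    if model.n_categories == 1:
        import logging
        logging.getLogger("rnacoevo").warning(
            "site_rates with a single gamma category is degenerate (all rates 1)")
        return SiteRates(np.ones(aln.n_sites))
    w = category_posteriors(aln, tree, model)
    return SiteRates(model.category_rates @ w)


def compare_rate_groups(rates: SiteRates, group_a: np.ndarray,
                        group_b: np.ndarray) -> pd.DataFrame:
    """Mann-Whitney U comparison of per-site rates between two site groups.

    Sites are 0-based indices into the rate vector; groups must be disjoint
    and non-empty.
    """
    a = np.asarray(list(group_a), dtype=np.int64)
    b = np.asarray(list(group_b), dtype=np.int64)
    if a.size == 0 or b.size == 0:
        raise ParameterError("rate groups must be non-empty")
    if np.intersect1d(a, b).size:
        raise ParameterError("rate groups must be disjoint")
    ra, rb = rates.rates[a], rates.rates[b]
    stat, p = mannwhitneyu(ra, rb, alternative="two-sided")
    return pd.DataFrame([{
        "n_a": a.size, "n_b": b.size,
        "mean_a": ra.mean(), "mean_b": rb.mean(),
        "mean_difference": ra.mean() - rb.mean(),
        "mannwhitney_u": float(stat), "p_value": float(p),
    }])


# ---------------------------------------------------------------------------
# Parameter fitting (direct likelihood maximisation)
# ---------------------------------------------------------------------------

def empirical_frequencies(aln: RnaAlignment) -> np.ndarray:
    counts = np.bincount(aln.codes[aln.codes >= 0].ravel(), minlength=4).astype(float)
    if counts.sum() == 0:
        raise ParameterError("alignment contains no unambiguous bases")
    return counts / counts.sum()


def fit_model(aln: RnaAlignment, tree: PhyloTree, n_categories: int = 4,
              ) -> GtrGammaModel:
    """Fit GTR+G exchangeabilities and alpha by direct likelihood maximisation.

    Stationary frequencies are fixed at empirical counts; the AU
    exchangeability is the unit of the relative rates.
    """
    from scipy.optimize import minimize

    freqs = empirical_frequencies(aln)

    def unpack(x: np.ndarray) -> GtrGammaModel:
        ex = np.exp(np.concatenate([x[:2], [0.0], x[2:5]]))  # AU fixed to 1
        return GtrGammaModel(ex, freqs, alpha=float(np.exp(x[5])),
                             n_categories=n_categories)

    def nll(x: np.ndarray) -> float:
        try:
            return -log_likelihood(aln, tree, unpack(x))
        except (ParameterError, FloatingPointError):
            return 1e12

    x0 = np.zeros(6)
    res = minimize(nll, x0, method="Nelder-Mead",
                   options={"maxiter": 400, "xatol": 1e-3, "fatol": 1e-3})
    return unpack(res.x)
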