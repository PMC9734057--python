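"""Causal inference test (CIT) for the SNP -> gene -> diagnosis ordering.

An intersection-union test: the causal ordering L -> G -> T (genotype ->
trans-eGene expression -> binary diagnosis) is supported only if four
component conditions hold simultaneously, so the omnibus p-value is the
maximum of the four component p-values:

    p1  L and T are associated              (logistic LRT, T ~ L vs T ~ 1)
    p2  L and G are associated given T      (linear F, G ~ L + T vs G ~ T)
    p3  G and T are associated given L      (logistic LRT, T ~ G + L vs T ~ L)
    p4  L and T are INDEPENDENT given G     (permutation equivalence test)

p4 is the delicate one: absence of evidence for conditional dependence is
not evidence of independence, so it is built as an equivalence test.  The
observed statistic is the partial F for L in the linear model T ~ L + G.
The reference distribution retains the L -> G link but severs the
mediator's information: each permutation rebuilds the mediator as
G* = fitted(G ~ L) + permuted residuals and recomputes the partial F for
L in T ~ L + G*.  Under a true mediation chain the real G absorbs the
L -> T association while G* cannot, so the observed F sits far below the
permuted ones and p4 = (1 + #{F* <= F_obs}) / (n_perm + 1) is small.

FDR over a collection of triples is permutation-based: the genotype
vector is permuted (severing every L link), the omnibus p recomputed per
triple, and q(t) estimated as the ratio of the mean permuted discovery
count to the observed discovery count at threshold t, monotonized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import expit

logger = logging.getLogger("circpath.cit")

DEFAULT_N_PERM = 1000
DEFAULT_N_PERM_FDR = 50


@dataclass
class CitResult:
    p1: float
    p2: float
    p3: float
    p4: float
    p_omnibus: float
    q: Optional[float] = None
    n_perm_component: int = DEFAULT_N_PERM
    seed: Optional[int] = None
    separation_fallback: bool = False

    def passes(self, alpha: float = 0.05, q_cut: float = 0.05) -> bool:
        ok = self.p_omnibus < alpha
        if self.q is not None:
            ok = ok and self.q < q_cut
        return ok


# ---------------------------------------------------------------------------
# component fits


def _logistic_llf(X: np.ndarray, y: np.ndarray, ridge: float = 0.0) -> tuple:
    """Newton-Raphson logistic log-likelihood; returns (llf, converged)."""
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(50):
        eta = X @ beta
        mu = expit(eta)
        W = mu * (1 - mu)
        grad = X.T @ (y - mu) - ridge * beta
        H = (X * W[:, None]).T @ X + ridge * np.eye(k)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return -np.inf, False
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    else:
        return _loglike(X, y, beta), False
    if np.max(np.abs(beta)) > 30:  # quasi-separation: fitted probs pinned at 0/1
        return _loglike(X, y, beta), False
    return _loglike(X, y, beta), True


def _loglike(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # numerically stable Bernoulli log-likelihood
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def logistic_lrt(
    y: np.ndarray, full: np.ndarray, null: np.ndarray
) -> tuple:
    """Likelihood-ratio p comparing nested logistic models.

    Returns ``(p, fallback)``; on separation/non-convergence both models
    are refit with a small L2 penalty (ridge 1e-4) and the comparison
    flagged.
    """
    ll1, ok1 = _logistic_llf(full, y)
    ll0, ok0 = _logistic_llf(null, y)
    fallback = not (ok1 and ok0)
    if fallback:
        ll1, _ = _logistic_llf(full, y, ridge=1e-4)
        ll0, _ = _logistic_llf(null, y, ridge=1e-4)
        logger.debug("separation fallback: penalized logistic LRT")
    lr = max(2.0 * (ll1 - ll0), 0.0)
    df = full.shape[1] - null.shape[1]
    return float(stats.chi2.sf(lr, df)), fallback


def linear_ftest(
    y: np.ndarray, full: np.ndarray, null: np.ndarray
) -> float:
    """F-test p comparing nested linear models (columns incl. intercept)."""
    n = y.size

    def rss(X: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    rss1, rss0 = rss(full), rss(null)
    df1 = full.shape[1] - null.shape[1]
    df2 = n - full.shape[1]
    if df2 <= 0:
        return 1.0
    f = max(rss0 - rss1, 0.0) / df1 / (rss1 / df2)
    return float(stats.f.sf(f, df1, df2))


def _partial_f_L(L: np.ndarray, G_cols: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Partial F for L in T ~ 1 + L + G, batched over columns of G_cols.

    ``G_cols`` has shape (n_perm, n); returns one F per row.  Uses closed
    3x3 normal equations so thousands of permutations stay cheap.
    """
    n = L.size
    B, _ = G_cols.shape
    ones = np.ones(n)
    sL, sT = L.sum(), T.sum()
    LL, LT, TT = L @ L, L @ T, T @ T
    sG = G_cols.sum(axis=1)
    LG = G_cols @ L
    GG = np.einsum("ij,ij->i", G_cols, G_cols)
    GT = G_cols @ T

    A = np.empty((B, 3, 3))
    A[:, 0, 0] = n
    A[:, 0, 1] = A[:, 1, 0] = sL
    A[:, 0, 2] = A[:, 2, 0] = sG
    A[:, 1, 1] = LL
    A[:, 1, 2] = A[:, 2, 1] = LG
    A[:, 2, 2] = GG
    rhs = np.empty((B, 3))
    rhs[:, 0] = sT
    rhs[:, 1] = LT
    rhs[:, 2] = GT

    beta = np.linalg.solve(A, rhs[..., None])[..., 0]
    rss = TT - np.einsum("ij,ij->i", beta, rhs)
    df = n - 3
    s2 = np.maximum(rss, 0.0) / df
    Ainv = np.linalg.inv(A)
    varL = s2 * Ainv[:, 1, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        F = beta[:, 1] ** 2 / varL
    return np.where(np.isfinite(F), F, np.inf)


def cit_test(
    L: np.ndarray,
    G: np.ndarray,
    T: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> CitResult:
    """Four-component causal inference test for one (L, G, T) triple.

    ``T`` must be binary with both classes present and n >= 20.
    Deterministic given ``seed``.
    """
    L = np.asarray(L, dtype=float)
    G = np.asarray(G, dtype=float)
    T = np.asarray(T, dtype=float)
    n = L.size
    if n < 20:
        raise ValueError("cit_test needs at least 20 samples")
    classes = set(np.unique(T))
    if not classes == {0.0, 1.0}:
        raise ValueError(f"diagnosis must contain both classes 0 and 1, saw {sorted(classes)}")

    ones = np.ones(n)
    X1 = np.column_stack([ones, L])
    p1, fb1 = logistic_lrt(T, X1, ones[:, None])
    p2 = linear_ftest(G, np.column_stack([ones, L, T]), np.column_stack([ones, T]))
    p3, fb3 = logistic_lrt(T, np.column_stack([ones, G, L]), X1)

    # p4: equivalence test of L _||_ T | G
    f_obs = float(_partial_f_L(L, G[None, :], T)[0])
    rng = np.random.default_rng(seed)
    beta_g, *_ = np.linalg.lstsq(X1, G, rcond=None)
    fitted = X1 @ beta_g
    resid = G - fitted
    idx = np.array([rng.permutation(n) for _ in range(n_perm)])
    G_star = fitted[None, :] + resid[idx]
    f_perm = _partial_f_L(L, G_star, T)
    p4 = float((1.0 + np.sum(f_perm <= f_obs)) / (n_perm + 1.0))

    p_omnibus = max(p1, p2, p3, p4)
    return CitResult(
        p1=p1,
        p2=p2,
        p3=p3,
        p4=p4,
        p_omnibus=p_omnibus,
        n_perm_component=n_perm,
        seed=seed,
        separation_fallback=fb1 or fb3,
    )


def cit_fdr(
    triples: Sequence[tuple],
    results: Sequence[CitResult],
    n_perm_fdr: int = DEFAULT_N_PERM_FDR,
    seed: int = 0,
    n_perm_component: Optional[int] = None,
) -> np.ndarray:
    """Permutation-based FDR (q) for a collection of CIT results.

    For each of ``n_perm_fdr`` rounds the genotype vector of every triple
    is permuted (breaking all L links) and the omnibus p recomputed.  At a
    threshold t, q(t) = mean permuted #{p <= t} / observed #{p <= t},
    clipped to [0, 1] and monotonized in t; each result's q is evaluated
    at its own omnibus p (reported 1 where the observed count is 0).
    The q values are also written back onto ``results``.
    """
    if len(triples) == 0:
        return np.array([])
    if len(triples) != len(results):
        raise ValueError("triples and results must align")
    rng = np.random.default_rng(seed)
    obs = np.array([r.p_omnibus for r in results])
    n_comp = n_perm_component or results[0].n_perm_component

    perm_p = np.empty((n_perm_fdr, len(triples)))
    for r in range(n_perm_fdr):
        for j, (L, G, T) in enumerate(triples):
            Lp = np.asarray(L)[rng.permutation(len(L))]
            perm_p[r, j] = cit_test(
                Lp, G, T, n_perm=n_comp, seed=int(rng.integers(2**31 - 1))
            ).p_omnibus

    order = np.argsort(obs, kind="stable")
    fdr_sorted = np.empty(len(obs))
    for rank, i in enumerate(order):
        t = obs[i]
        n_obs = int(np.sum(obs <= t))
        mean_perm = float(np.mean(np.sum(perm_p <= t, axis=1)))
        fdr_sorted[rank] = min(mean_perm / n_obs, 1.0) if n_obs else 1.0
    # monotonize: q_i = min over thresholds >= p_i
    q_sorted = np.minimum.accumulate(fdr_sorted[::-1])[::-1]
    q = np.empty(len(obs))
    q[order] = q_sorted
    for r, qi in zip(results, q):
        r.q = float(qi)
    return q
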