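"""Linear causal mediation and Spearman partial correlation (the MPT filter).

For one axis (SNP g, circRNA m, gene y) the mediation analysis fits the
two linear models

    mediator:  m = a0 + a * g + e1
    outcome:   y = c0 + c' * g + b * m + e2

and draws ``n_draws`` coefficient vectors from each model's asymptotic
normal distribution (quasi-Bayesian approximation).  Per draw the average
causal mediation effect is ACME = a*b, the average direct effect
ADE = c', and the total effect their sum, so the per-draw identity
ACME + ADE = total holds exactly.  Point estimates are medians of the
draws and p-values two-sided tail proportions of draws crossing zero.

The partial-correlation side is nonparametric: Spearman rho between circRNA
and gene expression, before and after regressing the conditioning
variable(s) (the circQTL dosages, or a miRNA) out of the ranks.  An axis
passes MPT iff both the ACME p-value and the post-adjustment partial
correlation p-value fall below alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

PROP_CLIP = 2.0  # reporting clip for the heavy-tailed mediated proportion
DEFAULT_N_DRAWS = 1000


@dataclass
class MediationResult:
    acme: float
    ade: float
    total: float
    prop_mediated: float
    p_acme: float
    p_ade: float
    ci_acme: tuple
    n_draws: int
    seed: Optional[int] = None

    def passes(self, alpha: float = 0.05) -> bool:
        return self.p_acme < alpha


@dataclass
class PartialCorrelation:
    rho_pre: float
    p_pre: float
    rho_post: float
    p_post: float
    degenerate: bool = False

    def passes(self, alpha: float = 0.05) -> bool:
        return self.p_post < alpha


def _ols_fit(X: np.ndarray, y: np.ndarray) -> tuple:
    """OLS coefficients and their covariance (classical, homoskedastic)."""
    n, k = X.shape
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    df = n - k
    s2 = float(resid @ resid) / df
    return beta, s2 * XtX_inv


def _tail_p(draws: np.ndarray) -> float:
    """Two-sided p as twice the smaller zero-crossing tail, floored at 1/n."""
    n = draws.size
    pos = float(np.mean(draws > 0))
    neg = float(np.mean(draws < 0))
    return float(min(max(2.0 * min(pos, neg), 1.0 / n), 1.0))


def mediate(
    g: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int = 0,
    return_draws: bool = False,
):
    """Quasi-Bayesian linear mediation of the g -> m -> y axis.

    Dosage is treated as a continuous treatment, so effects are per
    allele.  Inputs should be covariate-residualized expression; vectors
    must be sample-aligned.  With ``return_draws`` the per-draw
    (acme, ade, total) arrays are returned alongside the result.
    """
    g = np.asarray(g, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    n = g.size
    if not (m.size == n == y.size):
        raise ValueError("g, m, y must be aligned")
    if n < 10:
        raise ValueError("mediation needs at least 10 samples")
    if np.var(m) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in mediator or outcome")

    rng = np.random.default_rng(seed)
    ones = np.ones(n)
    Xm = np.column_stack([ones, g])
    bm, Vm = _ols_fit(Xm, m)
    Xy = np.column_stack([ones, g, m])
    by, Vy = _ols_fit(Xy, y)

    draws_m = rng.multivariate_normal(bm, Vm, size=n_draws, method="cholesky")
    draws_y = rng.multivariate_normal(by, Vy, size=n_draws, method="cholesky")
    a = draws_m[:, 1]
    cprime = draws_y[:, 1]
    b = draws_y[:, 2]
    acme = a * b
    ade = cprime
    total = acme + ade
    with np.errstate(divide="ignore", invalid="ignore"):
        prop = np.where(total != 0, acme / total, np.nan)
    prop = np.clip(prop, -PROP_CLIP, PROP_CLIP)

    lo, hi = np.percentile(acme, [2.5, 97.5])
    result = MediationResult(
        acme=float(np.median(acme)),
        ade=float(np.median(ade)),
        total=float(np.median(total)),
        prop_mediated=float(np.nanmedian(prop)),
        p_acme=_tail_p(acme),
        p_ade=_tail_p(ade),
        ci_acme=(float(lo), float(hi)),
        n_draws=n_draws,
        seed=seed,
    )
    if return_draws:
        return result, {"acme": acme, "ade": ade, "total": total}
    return result


def _rank(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v, method="average")


def spearman_partial(
    x: np.ndarray,
    y: np.ndarray,
    controls: Optional[np.ndarray] = None,
) -> PartialCorrelation:
    """Spearman correlation of x and y before/after adjusting the controls.

    Ranks (average for ties) of x, y, and each control are computed; the
    partial rho is the Pearson correlation of the rank residuals after
    regressing on [intercept | control ranks], with p from a t
    distribution on n - 2 - k df.  Controls with zero rank variance are
    dropped with a warning; if a residual ends up with zero variance the
    result is flagged degenerate with rho_post = 0, p_post = 1 (keeps
    batch runs alive rather than erroring).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 5:
        raise ValueError("spearman_partial needs at least 5 samples")
    rho_pre, p_pre = stats.spearmanr(x, y)
    rho_pre = float(rho_pre)
    p_pre = float(p_pre)

    if controls is None or (hasattr(controls, "size") and controls.size == 0):
        return PartialCorrelation(rho_pre, p_pre, rho_pre, p_pre)

    C = np.atleast_2d(np.asarray(controls, dtype=float))
    if C.shape[0] == n and C.ndim == 2 and C.shape[1] != n:
        pass  # already samples x k
    elif C.shape[1] == n:
        C = C.T
    keep = [j for j in range(C.shape[1]) if np.ptp(_rank(C[:, j])) > 0]
    if len(keep) < C.shape[1]:
        import logging

        logging.getLogger("circpath.mediation").warning(
            "dropped %d constant controls", C.shape[1] - len(keep)
        )
    C = C[:, keep]
    k = C.shape[1]
    if k == 0:
        return PartialCorrelation(rho_pre, p_pre, rho_pre, p_pre)

    rx, ry = _rank(x), _rank(y)
    D = np.column_stack([np.ones(n)] + [_rank(C[:, j]) for j in range(k)])
    bx, *_ = np.linalg.lstsq(D, rx, rcond=None)
    by_, *_ = np.linalg.lstsq(D, ry, rcond=None)
    ex = rx - D @ bx
    ey = ry - D @ by_
    if np.allclose(ex, 0) or np.allclose(ey, 0):
        return PartialCorrelation(rho_pre, p_pre, 0.0, 1.0, degenerate=True)
    rho = float(np.corrcoef(ex, ey)[0, 1])
    df = n - 2 - k
    if df <= 0:
        return PartialCorrelation(rho_pre, p_pre, rho, 1.0, degenerate=True)
    t = rho * np.sqrt(df / max(1.0 - rho * rho, np.finfo(float).tiny))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return PartialCorrelation(rho_pre, p_pre, rho, max(p, np.finfo(float).tiny))


def mpt_filter(
    axes: pd.DataFrame,
    mediation: dict,
    partial: dict,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Keep axes passing BOTH the mediation and partial-correlation tests.

    ``axes`` needs columns ``snp_id``, ``circ_id``, ``gene_id``; the two
    dicts map (snp_id, circ_id, gene_id) -> result objects.  Axes with a
    missing result are excluded and counted in the returned frame's attrs.
    """
    rows, missing = [], 0
    for _, ax in axes.iterrows():
        key = (ax["snp_id"], ax["circ_id"], ax["gene_id"])
        med = mediation.get(key)
        par = partial.get(key)
        if med is None or par is None:
            missing += 1
            continue
        rows.append(
            {
                **ax,
                "p_acme": med.p_acme,
                "p_post": par.p_post,
                "mediation_pass": med.p_acme < alpha,
                "partial_pass": par.p_post < alpha,
                "mpt_pass": (med.p_acme < alpha) and (par.p_post < alpha),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_missing"] = missing
    return out


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> float:
    """Two-sided p for the difference of two independent correlations.

    Fisher z-transform both and refer
    Z = (z1 - z2) / sqrt(1/(n1-3) + 1/(n2-3)) to the standard normal.
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("|r| must be < 1 (Fisher z diverges)")
    for n in (n1, n2):
        if n <= 3:
            raise ValueError("n must exceed 3")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    z = (z1 - z2) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return float(2.0 * stats.norm.sf(abs(z)))


def mediation_by_bins(
    corr_p: np.ndarray,
    mediation_pass: np.ndarray,
    bin_edges: Sequence[float] = (0.05, 0.005, 0.0005),
) -> pd.DataFrame:
    """Fraction of axes passing mediation per correlation-significance bin.

    ``bin_edges`` are strictly decreasing significance thresholds; the
    bins are (edge1, 1], (edge2, edge1], ..., (0, edge_last].  Empty bins
    report a missing (NaN) fraction, not zero.
    """
    edges = list(bin_edges)
    if any(b >= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly decreasing")
    corr_p = np.asarray(corr_p, dtype=float)
    passed = np.asarray(mediation_pass, dtype=bool)
    bounds = [1.0] + edges + [0.0]
    rows = []
    for hi, lo in zip(bounds[:-1], bounds[1:]):
        sel = (corr_p > lo) & (corr_p <= hi)
        n = int(sel.sum())
        frac = float(passed[sel].mean()) if n else np.nan
        if hi == 1.0:
            label = f"p > {lo:g}"
        elif lo == 0.0:
            label = f"p <= {hi:g}"
        else:
            label = f"{lo:g} < p <= {hi:g}"
        rows.append({"bin": label, "n_axes": n, "frac_mediation_pass": frac})
    return pd.DataFrame(rows)
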