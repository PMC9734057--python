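"""cis circQTL and trans eQTL discovery.

The scan follows the Matrix-eQTL-style additive linear model: expression is
residualized against the covariates once, then each (SNP, feature) pair is
tested by simple OLS of the residualized expression on the dosage.  Nominal
p-values are calibrated by a permutation empirical p-value

    empP = (1 + #{P_i < P_obs}) / (n_perm + 1)

where the P_i come from re-running the scan after permuting the sample
labels of the whole residualized expression matrix (one shared permutation
per round, genotypes fixed, which preserves feature-feature correlation).
circRNAs are gated on the Storey q-value of their minimal empP; within
q-passing circRNAs, associations with empP < 0.005 are retained, and a
forward-stepwise conditional analysis on the individual-level data reduces
each circRNA's retained SNPs to statistically independent signals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline

from .types import (
    CovariateTable,
    ExpressionMatrix,
    GenotypeMatrix,
    PermutationNull,
)

logger = logging.getLogger("circpath.qtl")

DEFAULT_WINDOW_BP = 200_000
DEFAULT_TRANS_DIST_BP = 5_000_000
DEFAULT_N_PERM = 10_000
DEFAULT_EMPP_CUT = 0.005
DEFAULT_Q_CUT = 0.05
DEFAULT_TRANS_P_CUT = 1e-4
COJO_P_ENTER = 1e-3
COJO_R2_MAX = 0.9


# ---------------------------------------------------------------------------
# covariate adjustment


def residualize(expr: ExpressionMatrix, covariates: CovariateTable) -> ExpressionMatrix:
    """Replace each feature by its OLS residuals against [intercept | covariates].

    The returned residuals are orthogonal to every covariate column (and
    mean-centered).  Raises on a rank-deficient design, naming the
    dependent columns.
    """
    common = list(expr.sample_ids)
    if list(covariates.sample_ids) != common:
        covariates = covariates.subset_samples(common)
    X = covariates.design()
    Y = expr.values.to_numpy(dtype=float).T  # samples x features
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    R = Y - X @ beta
    values = pd.DataFrame(R.T, index=expr.feature_ids, columns=expr.sample_ids)
    return ExpressionMatrix(values, expr.loci.copy(), expr.role)


# ---------------------------------------------------------------------------
# single-pair additive model


def additive_test(y: np.ndarray, g: np.ndarray) -> tuple:
    """Simple OLS of expression ``y`` on dosage ``g``.

    Returns ``(beta, se, t, p)`` with the two-sided p from a t
    distribution on n - 2 degrees of freedom.  Raises on monomorphic
    dosage (zero variance) — callers skip and log such SNPs.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    n = y.size
    if n < 4:
        raise ValueError("additive_test needs at least 4 samples")
    gc = g - g.mean()
    yc = y - y.mean()
    sxx = float(gc @ gc)
    if sxx <= 0:
        raise ValueError("monomorphic SNP (zero dosage variance)")
    sxy = float(gc @ yc)
    syy = float(yc @ yc)
    beta = sxy / sxx
    df = n - 2
    rss = max(syy - beta * sxy, 0.0)
    s2 = rss / df
    if s2 == 0.0:
        return beta, 0.0, np.inf if beta != 0 else 0.0, float(np.finfo(float).tiny)
    se = np.sqrt(s2 / sxx)
    t = beta / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return beta, se, t, max(p, np.finfo(float).tiny)


def _standardize(M: np.ndarray) -> tuple:
    """Column z-scores (ddof=0) and the columns' sd; zero-variance -> sd 0."""
    mu = M.mean(axis=0)
    sd = M.std(axis=0)
    Z = np.zeros_like(M, dtype=float)
    ok = sd > 0
    Z[:, ok] = (M[:, ok] - mu[ok]) / sd[ok]
    return Z, sd


def _r_to_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for a Pearson r with n-2 df (vectorized, monotone in |r|)."""
    df = n - 2
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(r) * np.sqrt(df / np.maximum(1.0 - r * r, np.finfo(float).tiny))
    return np.maximum(2.0 * stats.t.sf(t, df), np.finfo(float).tiny)


def _pair_table(
    G: np.ndarray,
    Y: np.ndarray,
    mask: np.ndarray,
    snp_ids: Sequence[str],
    feature_ids: Sequence[str],
    mode: str,
) -> pd.DataFrame:
    """Full association table for the masked (SNP, feature) pairs.

    ``G`` is samples x SNPs, ``Y`` samples x features, ``mask`` SNPs x
    features.  Statistics are computed from the correlation form of the
    simple-OLS slope, which matches :func:`additive_test` exactly.
    """
    n = G.shape[0]
    Gz, gsd = _standardize(G)
    Yz, ysd = _standardize(Y)
    poly = gsd == 0
    if poly.any():
        logger.info("skipping %d monomorphic SNPs", int(poly.sum()))
        mask = mask & ~poly[:, None]
    R = (Gz.T @ Yz) / n
    si, fi = np.nonzero(mask)
    r = R[si, fi]
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.maximum(1.0 - r * r, np.finfo(float).tiny)
        t = r * np.sqrt(df / denom)
    scale = ysd[fi] / np.where(gsd[si] > 0, gsd[si], np.nan)
    beta = r * scale
    se = scale * np.sqrt(denom / df)
    p = np.maximum(2.0 * stats.t.sf(np.abs(t), df), np.finfo(float).tiny)
    return pd.DataFrame(
        {
            "snp_id": np.asarray(snp_ids)[si],
            "feature_id": np.asarray(feature_ids)[fi],
            "beta": beta,
            "se": se,
            "t_stat": t,
            "p_nominal": p,
            "mode": mode,
        }
    )


# ---------------------------------------------------------------------------
# pair eligibility


def cis_pair_mask(
    genotypes: GenotypeMatrix, circ_expr: ExpressionMatrix, window_bp: int = DEFAULT_WINDOW_BP
) -> np.ndarray:
    """SNPs x circRNAs mask: SNP within ``window_bp`` (inclusive) of the
    back-splice donor OR acceptor coordinate, same chromosome."""
    snp_chrom = genotypes.positions["chrom"].to_numpy()
    snp_pos = genotypes.positions["pos"].to_numpy()
    loci = circ_expr.loci
    same_chrom = snp_chrom[:, None] == loci["chrom"].to_numpy()[None, :]
    d_donor = np.abs(snp_pos[:, None] - loci["start"].to_numpy()[None, :])
    d_acceptor = np.abs(snp_pos[:, None] - loci["end"].to_numpy()[None, :])
    near = np.minimum(d_donor, d_acceptor) <= window_bp
    return same_chrom & near


def trans_pair_mask(
    genotypes: GenotypeMatrix,
    gene_expr: ExpressionMatrix,
    trans_dist_bp: int = DEFAULT_TRANS_DIST_BP,
) -> np.ndarray:
    """SNPs x genes mask: different chromosome, or gap between the SNP and
    the gene's [start, end] interval strictly greater than ``trans_dist_bp``.
    A SNP inside the interval has gap 0 and is never tested."""
    snp_chrom = genotypes.positions["chrom"].to_numpy()
    snp_pos = genotypes.positions["pos"].to_numpy()
    loci = gene_expr.loci
    start = loci["start"].to_numpy()[None, :]
    end = loci["end"].to_numpy()[None, :]
    pos = snp_pos[:, None]
    gap = np.where(pos < start, start - pos, np.where(pos > end, pos - end, 0))
    diff_chrom = snp_chrom[:, None] != loci["chrom"].to_numpy()[None, :]
    return diff_chrom | (gap > trans_dist_bp)


def distance_to_backsplice(
    genotypes: GenotypeMatrix, circ_expr: ExpressionMatrix
) -> pd.DataFrame:
    """Min distance (bp) of every SNP to each circRNA's donor/acceptor site."""
    snp_pos = genotypes.positions["pos"].to_numpy()
    loci = circ_expr.loci
    d = np.minimum(
        np.abs(snp_pos[:, None] - loci["start"].to_numpy()[None, :]),
        np.abs(snp_pos[:, None] - loci["end"].to_numpy()[None, :]),
    )
    return pd.DataFrame(d, index=genotypes.snp_ids, columns=circ_expr.feature_ids)


# ---------------------------------------------------------------------------
# scans


def cis_scan(
    circ_expr: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> pd.DataFrame:
    """Test every SNP within the cis window of each circRNA.

    ``circ_expr`` should already be covariate-residualized.  circRNAs with
    zero SNPs in their window are logged and produce no rows.
    """
    mask = cis_pair_mask(genotypes, circ_expr, window_bp)
    empty = ~mask.any(axis=0)
    if empty.any():
        logger.info(
            "%d circRNAs with no SNP in the +/-%d bp window",
            int(empty.sum()),
            window_bp,
        )
    return _pair_table(
        genotypes.dosages.to_numpy(dtype=float),
        circ_expr.values.to_numpy(dtype=float).T,
        mask,
        list(genotypes.snp_ids),
        list(circ_expr.feature_ids),
        "cis",
    )


def build_null(
    expr: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    mask: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    unit_axis: str = "feature",
) -> PermutationNull:
    """Permutation null of per-unit minimum nominal P.

    Each permutation applies ONE shared sample-label permutation to the
    whole (residualized) expression matrix, re-runs the masked scan, and
    records the per-feature (cis) or per-SNP (trans) minimum nominal P.
    Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    G = genotypes.dosages.to_numpy(dtype=float)
    Y = expr.values.to_numpy(dtype=float).T
    n = G.shape[0]
    Gz, gsd = _standardize(G)
    Yz, _ = _standardize(Y)
    mask = mask & (gsd > 0)[:, None]
    units = list(expr.feature_ids) if unit_axis == "feature" else list(genotypes.snp_ids)
    reduce_axis = 0 if unit_axis == "feature" else 1
    null_p = np.ones((n_perm, len(units)))
    absR = np.empty_like(mask, dtype=float)
    for b in range(n_perm):
        perm = rng.permutation(n)
        np.abs(Gz.T @ Yz[perm], out=absR)
        absR /= n
        absR[~mask] = -1.0
        rmax = absR.max(axis=reduce_axis)
        has = rmax >= 0
        null_p[b, has] = _r_to_p(rmax[has], n)
    return PermutationNull(null_p, units, unit_axis, seed=seed)


def empirical_p(p_obs, null_p: np.ndarray):
    """empP = (1 + #{null strictly < p_obs}) / (n_perm + 1).

    Strict inequality; ties count as "not smaller".  ``p_obs`` may be a
    scalar or an array (vectorized by sorting the null once).
    """
    null_p = np.asarray(null_p, dtype=float).ravel()
    if null_p.size == 0:
        raise ValueError("empty permutation null")
    sorted_null = np.sort(null_p)
    counts = np.searchsorted(sorted_null, np.asarray(p_obs, dtype=float), side="left")
    emp = (1.0 + counts) / (null_p.size + 1.0)
    return float(emp) if np.isscalar(p_obs) else emp


def storey_q(
    p: np.ndarray, lambdas: Optional[np.ndarray] = None
) -> np.ndarray:
    """Storey q-values with smoother-based pi0 estimation.

    pi0 is estimated on the lambda grid 0.05..0.95 with a cubic smoothing
    spline extrapolated to the largest lambda, clipped to (0, 1].  With
    fewer than 10 p-values the estimator is unstable, so the function
    falls back to Benjamini-Hochberg (pi0 = 1), logged.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    pi0 = estimate_pi0(p, lambdas)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]  # monotone via cumulative minimum
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def estimate_pi0(p: np.ndarray, lambdas: Optional[np.ndarray] = None) -> float:
    """Smoother-based estimate of the null proportion pi0.

    With fewer than 10 p-values pi0 is fixed at 1 (Storey then reduces to
    Benjamini-Hochberg), logged.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    if lambdas is None:
        lambdas = np.arange(0.05, 0.951, 0.05)
    if m < 10:
        logger.info("fewer than 10 features: Storey pi0 fixed to 1 (BH fallback)")
        return 1.0
    pi0s = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambdas])
    if np.allclose(pi0s, pi0s[0]):
        pi0 = float(pi0s[0])
    else:
        spl = UnivariateSpline(lambdas, pi0s, k=3)
        pi0 = float(spl(lambdas[-1]))
    return min(max(pi0, 1.0 / m), 1.0)


@dataclass
class CircQtlCallSet:
    """Result of circQTL calling on one cis scan.

    ``associations`` carries every tested pair with ``emp_p``;
    ``feature_stats`` one row per circRNA (min empP and Storey q);
    ``retained`` the circQTLs with empP < cut on q-passing circRNAs;
    ``independent`` the post-conditional-selection subset.
    """

    associations: pd.DataFrame
    feature_stats: pd.DataFrame
    retained: pd.DataFrame
    independent: pd.DataFrame = field(default_factory=pd.DataFrame)
    null: Optional[PermutationNull] = None


def assign_empirical_p(
    assoc: pd.DataFrame, null: PermutationNull, pooling: str = "per_feature"
) -> pd.DataFrame:
    """Attach ``emp_p`` to an association table.

    ``pooling='per_feature'`` compares each pair's nominal p against the
    permuted minima of its own unit (feature column for cis, SNP column
    for trans); ``pooling='pooled'`` compares against all permuted minima
    flattened together.
    """
    assoc = assoc.copy()
    key = "feature_id" if null.unit_axis == "feature" else "snp_id"
    if pooling == "pooled":
        assoc["emp_p"] = empirical_p(assoc["p_nominal"].to_numpy(), null.null_p)
        return assoc
    if pooling != "per_feature":
        raise ValueError(f"unknown pooling {pooling!r}")
    emp = np.ones(len(assoc))
    col = {u: j for j, u in enumerate(null.unit_ids)}
    for unit, idx in assoc.groupby(key).groups.items():
        emp[assoc.index.get_indexer(idx)] = empirical_p(
            assoc.loc[idx, "p_nominal"].to_numpy(), null.null_p[:, col[unit]]
        )
    assoc["emp_p"] = emp
    return assoc


def call_circqtls(
    cis_assoc: pd.DataFrame,
    null: PermutationNull,
    q_cut: float = DEFAULT_Q_CUT,
    empp_cut: float = DEFAULT_EMPP_CUT,
    pooling: str = "per_feature",
) -> CircQtlCallSet:
    """Gate circRNAs on Storey q of their minimal empP, then retain
    associations with empP < ``empp_cut`` for the q-passing circRNAs."""
    assoc = assign_empirical_p(cis_assoc, null, pooling=pooling)
    feat = (
        assoc.groupby("feature_id")["emp_p"].min().rename("min_emp_p").reset_index()
    )
    feat["q"] = storey_q(feat["min_emp_p"].to_numpy())
    passing = set(feat.loc[feat["q"] < q_cut, "feature_id"])
    retained = assoc[
        assoc["feature_id"].isin(passing) & (assoc["emp_p"] < empp_cut)
    ].reset_index(drop=True)
    return CircQtlCallSet(assoc, feat, retained, null=null)


# ---------------------------------------------------------------------------
# conditional (independent-SNP) selection


def _joint_pvalues(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided coefficient p-values of OLS y ~ [1 | X] (excl. intercept)."""
    n, k = X.shape
    D = np.column_stack([np.ones(n), X])
    XtX = D.T @ D
    beta = np.linalg.solve(XtX, D.T @ y)
    resid = y - D @ beta
    df = n - k - 1
    if df <= 0:
        return np.ones(k)
    s2 = float(resid @ resid) / df
    cov = s2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[1:] / se
    return 2.0 * stats.t.sf(np.abs(t), df)


def _r2_on(X_sel: np.ndarray, x: np.ndarray) -> float:
    """Multiple R^2 of candidate dosage on the already-selected set."""
    n = X_sel.shape[0]
    D = np.column_stack([np.ones(n), X_sel])
    beta, *_ = np.linalg.lstsq(D, x, rcond=None)
    fitted = D @ beta
    tot = float(np.var(x))
    if tot == 0:
        return 1.0
    return float(1.0 - np.var(x - fitted) / tot)


def conditional_selection(
    snp_ids: Sequence[str],
    genotypes: GenotypeMatrix,
    y: np.ndarray,
    p_enter: float = COJO_P_ENTER,
    r2_max: float = COJO_R2_MAX,
) -> list:
    """Forward stepwise conditional regression on individual-level data.

    Seeds with the minimum-p SNP, then iteratively adds the SNP with the
    smallest conditional p (< ``p_enter``) given the selected set,
    skipping candidates whose R^2 against the selected dosages exceeds
    ``r2_max``.  A final backward pass drops SNPs that lose conditional
    significance in the joint model.
    """
    snp_ids = list(snp_ids)
    if not snp_ids:
        return []
    y = np.asarray(y, dtype=float)
    G = genotypes.dosages[snp_ids].to_numpy(dtype=float)

    marg = np.array([additive_test(y, G[:, j])[3] for j in range(G.shape[1])])
    selected = [int(np.argmin(marg))]
    while True:
        remaining = [j for j in range(len(snp_ids)) if j not in selected]
        best_j, best_p = None, np.inf
        X_sel = G[:, selected]
        for j in remaining:
            r2 = _r2_on(X_sel, G[:, j])
            if r2 > r2_max:
                logger.debug("skip %s: R2=%.3f with selected set", snp_ids[j], r2)
                continue
            pvals = _joint_pvalues(np.column_stack([X_sel, G[:, j]]), y)
            if not np.isfinite(pvals[-1]):
                continue
            if pvals[-1] < best_p:
                best_j, best_p = j, pvals[-1]
        if best_j is None or best_p >= p_enter:
            break
        selected.append(best_j)

    # backward: joint model must keep every selected SNP conditionally significant
    while len(selected) > 1:
        pvals = _joint_pvalues(G[:, selected], y)
        worst = int(np.argmax(pvals))
        if pvals[worst] < p_enter:
            break
        selected.pop(worst)
    return [snp_ids[j] for j in selected]


def select_independent(
    callset: CircQtlCallSet,
    genotypes: GenotypeMatrix,
    circ_expr: ExpressionMatrix,
    p_enter: float = COJO_P_ENTER,
    r2_max: float = COJO_R2_MAX,
) -> CircQtlCallSet:
    """Run conditional selection per retained circRNA; fills ``independent``."""
    rows = []
    Y = circ_expr.values
    for feat, grp in callset.retained.groupby("feature_id"):
        keep = conditional_selection(
            grp["snp_id"].tolist(),
            genotypes,
            Y.loc[feat].to_numpy(dtype=float),
            p_enter=p_enter,
            r2_max=r2_max,
        )
        rows.append(grp[grp["snp_id"].isin(keep)])
    callset.independent = (
        pd.concat(rows, ignore_index=True) if rows else callset.retained.iloc[0:0]
    )
    return callset


# ---------------------------------------------------------------------------
# trans scan


def trans_scan(
    genotypes: GenotypeMatrix,
    gene_expr: ExpressionMatrix,
    trans_dist_bp: int = DEFAULT_TRANS_DIST_BP,
    p_cut: float = DEFAULT_TRANS_P_CUT,
    empp_cut: float = DEFAULT_EMPP_CUT,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    pooling: str = "per_feature",
) -> tuple:
    """Scan candidate (circQTL) SNPs against distant genes.

    ``genotypes`` should already be subset to the candidate SNPs and
    ``gene_expr`` covariate-residualized.  Pairs must be on different
    chromosomes or separated by strictly more than ``trans_dist_bp``.
    Returns ``(associations with emp_p and 'retained' flag, PermutationNull)``;
    retained means nominal p < ``p_cut`` AND empP < ``empp_cut``.
    """
    mask = trans_pair_mask(genotypes, gene_expr, trans_dist_bp)
    assoc = _pair_table(
        genotypes.dosages.to_numpy(dtype=float),
        gene_expr.values.to_numpy(dtype=float).T,
        mask,
        list(genotypes.snp_ids),
        list(gene_expr.feature_ids),
        "trans",
    )
    null = build_null(
        gene_expr, genotypes, mask, n_perm=n_perm, seed=seed, unit_axis="snp"
    )
    assoc = assign_empirical_p(assoc, null, pooling=pooling)
    assoc["retained"] = (assoc["p_nominal"] < p_cut) & (assoc["emp_p"] < empp_cut)
    return assoc, null


# ---------------------------------------------------------------------------
# MAF/distance-matched control SNPs


def max_circqtls(callset: CircQtlCallSet) -> pd.DataFrame:
    """Most significant retained circQTL per circRNA (by nominal p)."""
    retained = callset.retained
    if retained.empty:
        return retained.iloc[0:0]
    idx = retained.groupby("feature_id")["p_nominal"].idxmin()
    return retained.loc[idx].reset_index(drop=True)


def select_control_snps(
    circqtls: pd.DataFrame,
    cis_assoc: pd.DataFrame,
    genotypes: GenotypeMatrix,
    circ_expr: ExpressionMatrix,
    maf_tol: float = 0.05,
    p_floor: float = 0.05,
) -> pd.DataFrame:
    """MAF- and distance-matched non-circQTL control SNPs.

    The eligible pool is every scanned SNP whose minimal nominal p across
    circRNAs exceeds ``p_floor``.  For each (max-)circQTL the control is
    the pool SNP with |dMAF| <= ``maf_tol`` minimizing the difference in
    distance-to-back-splice-site, chosen without replacement.  circQTLs
    with no eligible match are dropped (counted in the log).
    """
    if circqtls.empty:
        return pd.DataFrame(
            columns=["snp_id", "feature_id", "control_snp_id", "d_maf", "d_distance"]
        )
    min_p = cis_assoc.groupby("snp_id")["p_nominal"].min()
    pool = set(min_p[min_p > p_floor].index)
    if not pool:
        logger.warning("no eligible control SNPs (all scanned SNPs have min p <= %g)", p_floor)
    dist = distance_to_backsplice(genotypes, circ_expr)
    maf = genotypes.maf

    used, rows, dropped = set(), [], 0
    for _, row in circqtls.iterrows():
        feat = row["feature_id"]
        target_maf = maf[row["snp_id"]]
        target_dist = dist.loc[row["snp_id"], feat]
        cands = sorted(pool - used)
        cands = [s for s in cands if abs(maf[s] - target_maf) <= maf_tol]
        if not cands:
            dropped += 1
            continue
        dd = np.array([abs(dist.loc[s, feat] - target_dist) for s in cands])
        dm = np.array([abs(maf[s] - target_maf) for s in cands])
        order = np.lexsort((np.array(cands, dtype=object), dm, dd))
        best = cands[order[0]]
        used.add(best)
        rows.append(
            {
                "snp_id": row["snp_id"],
                "feature_id": feat,
                "control_snp_id": best,
                "d_maf": abs(maf[best] - target_maf),
                "d_distance": abs(dist.loc[best, feat] - target_dist),
            }
        )
    if dropped:
        logger.info("%d circQTLs had no eligible MAF-matched control", dropped)
    return pd.DataFrame(rows)
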