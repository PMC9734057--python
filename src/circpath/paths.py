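"""Axis construction, path integration, miRNA-mediator screen, enrichment.

An *axis* is a circQTL -> circRNA -> trans-eGene triple built by joining
the cis and trans call sets on the shared SNP.  A *propagation path* is an
axis that passed MPT (mediation + partial correlation) whose (SNP, gene)
pair also passed CIT against the diagnosis, i.e. a fully qualified
circQTL -> circRNA -> trans-eGene -> diagnosis record.  The miRNA screen
asks whether a miRNA with target sites on BOTH the circRNA and the gene
can explain their correlation: the circ-gene Spearman correlation must be
significant before adjustment and become non-significant after
controlling the miRNA (note this is the OPPOSITE pass direction of the
SNP-adjusted MPT rule).
"""

from __future__ import annotations

import logging
from typing import Dict

import numpy as np
import pandas as pd
from scipy import stats

from .mediation import spearman_partial
from .types import ExpressionMatrix, MirnaTargetTable

logger = logging.getLogger("circpath.paths")


def build_axes(cis_calls: pd.DataFrame, trans_calls: pd.DataFrame) -> pd.DataFrame:
    """Join cis (snp, circRNA) and trans (snp, gene) calls on the SNP.

    Cartesian per SNP, deduplicated: one row per distinct
    (snp_id, circ_id, gene_id).
    """
    if cis_calls.empty or trans_calls.empty:
        return pd.DataFrame(columns=["snp_id", "circ_id", "gene_id"])
    cis = cis_calls.rename(columns={"feature_id": "circ_id"})[
        ["snp_id", "circ_id"]
    ].drop_duplicates()
    trans = trans_calls.rename(columns={"feature_id": "gene_id"})[
        ["snp_id", "gene_id"]
    ].drop_duplicates()
    axes = cis.merge(trans, on="snp_id").drop_duplicates().reset_index(drop=True)
    return axes[["snp_id", "circ_id", "gene_id"]]


def integrate_paths(mpt_axes: pd.DataFrame, cit_table: pd.DataFrame) -> pd.DataFrame:
    """Emit propagation paths: MPT-passing axes whose (snp, gene) passed CIT.

    ``mpt_axes`` needs ``snp_id``, ``circ_id``, ``gene_id``, ``mpt_pass``;
    ``cit_table`` needs ``snp_id``, ``gene_id``, ``cit_pass`` (omnibus
    p < 0.05 AND q < 0.05 upstream).
    """
    cols = ["snp_id", "circ_id", "gene_id", "mpt_pass", "cit_pass"]
    if mpt_axes.empty or cit_table.empty:
        return pd.DataFrame(columns=cols)
    cit_pass = cit_table.loc[cit_table["cit_pass"], ["snp_id", "gene_id"]].drop_duplicates()
    paths = mpt_axes.loc[mpt_axes["mpt_pass"]].merge(
        cit_pass, on=["snp_id", "gene_id"], how="inner"
    )
    paths = paths.drop_duplicates(subset=["snp_id", "circ_id", "gene_id"]).reset_index(
        drop=True
    )
    paths["cit_pass"] = True
    return paths[[c for c in cols if c in paths.columns]]


def mirna_screen(
    circ_gene_pairs: pd.DataFrame,
    targets: MirnaTargetTable,
    mirna_expr: ExpressionMatrix,
    circ_expr: ExpressionMatrix,
    gene_expr: ExpressionMatrix,
    alpha: float = 0.05,
    post_alpha: float = 0.05,
) -> pd.DataFrame:
    """Screen candidate miRNA mediators of circRNA-gene correlations.

    For each (circ, gene) pair and each miRNA with target sites on BOTH:

    1. gate: Spearman p of circ vs gene must be < ``alpha``;
    2. partial correlation controlling the miRNA's expression;
    3. the candidate passes iff the post-adjustment p >= ``post_alpha``
       (the residuals are "unrelated" once the miRNA is controlled).

    Candidates whose miRNA is absent from the expression matrix are
    skipped and counted (``attrs['n_skipped_missing_mirna']``).  The three
    expression matrices are aligned to their shared samples, so a miRNA
    layer assayed on a cohort subset is handled (the screen then runs at
    that smaller n).
    """
    shared = sorted(
        set(circ_expr.sample_ids)
        & set(gene_expr.sample_ids)
        & set(mirna_expr.sample_ids)
    )
    if not shared:
        raise ValueError("no samples shared across circRNA/gene/miRNA matrices")
    circ_expr = circ_expr.subset_samples(shared)
    gene_expr = gene_expr.subset_samples(shared)
    mirna_expr = mirna_expr.subset_samples(shared)
    rows, skipped = [], 0
    by_reg: Dict[str, set] = {}
    for _, r in targets.pairs.iterrows():
        by_reg.setdefault(r["regulator_id"], set()).add(r["mirna_id"])
    for _, pair in circ_gene_pairs.drop_duplicates(
        subset=["circ_id", "gene_id"]
    ).iterrows():
        circ_id, gene_id = pair["circ_id"], pair["gene_id"]
        shared = by_reg.get(circ_id, set()) & by_reg.get(gene_id, set())
        if not shared:
            continue
        x = circ_expr.values.loc[circ_id].to_numpy(dtype=float)
        y = gene_expr.values.loc[gene_id].to_numpy(dtype=float)
        for mirna_id in sorted(shared):
            if mirna_id not in mirna_expr.feature_ids:
                skipped += 1
                continue
            z = mirna_expr.values.loc[mirna_id].to_numpy(dtype=float)
            pc = spearman_partial(x, y, z[:, None])
            if pc.p_pre >= alpha:
                continue  # correlation gate: never tested further
            rows.append(
                {
                    "circ_id": circ_id,
                    "mirna_id": mirna_id,
                    "gene_id": gene_id,
                    "rho_pre": pc.rho_pre,
                    "p_pre": pc.p_pre,
                    "rho_post": pc.rho_post,
                    "p_post": pc.p_post,
                    "mirna_pass": pc.p_post >= post_alpha,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "circ_id",
            "mirna_id",
            "gene_id",
            "rho_pre",
            "p_pre",
            "rho_post",
            "p_post",
            "mirna_pass",
        ],
    )
    out.attrs["n_skipped_missing_mirna"] = skipped
    if skipped:
        logger.info("%d miRNA candidates missing from the expression matrix", skipped)
    return out


def attach_mirna(paths: pd.DataFrame, mirna_axes: pd.DataFrame) -> pd.DataFrame:
    """Join miRNA-passing axes onto propagation paths by (circ, gene)."""
    if paths.empty or mirna_axes.empty:
        out = paths.copy()
        out["mirna_id"] = pd.Series(dtype=object)
        out["mirna_pass"] = False
        return out
    passing = mirna_axes.loc[mirna_axes["mirna_pass"], ["circ_id", "gene_id", "mirna_id"]]
    out = paths.merge(passing, on=["circ_id", "gene_id"], how="left")
    out["mirna_pass"] = out["mirna_id"].notna()
    return out


def enrich(
    query: set,
    target_lists: Dict[str, set],
    background: set,
) -> pd.DataFrame:
    """One-tailed Fisher enrichment of ``query`` in each target list.

    Each target list is intersected with the ``background`` universe
    first; ``query`` must be a subset of the background.  The odds ratio
    is ad/bc with a 0.5 continuity correction only when a cell is zero
    (flagged in ``or_corrected``).  p-values are BH-adjusted across the
    provided lists.
    """
    if not background:
        raise ValueError("empty background universe")
    query = set(query)
    if not query <= set(background):
        raise ValueError("query must be a subset of the background")
    rows = []
    for name, tset in target_lists.items():
        t = set(tset) & set(background)
        a = len(query & t)
        b = len(query - t)
        c = len(t - query)
        d = len(set(background) - t - query)
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        corrected = 0 in (a, b, c, d)
        if corrected:
            a_, b_, c_, d_ = (x + 0.5 for x in (a, b, c, d))
        else:
            a_, b_, c_, d_ = a, b, c, d
        rows.append(
            {
                "target_set": name,
                "overlap": a,
                "odds_ratio": (a_ * d_) / (b_ * c_),
                "or_corrected": corrected,
                "p_one_tailed": float(p),
            }
        )
    out = pd.DataFrame(rows)
    out["fdr_bh"] = bh_adjust(out["p_one_tailed"].to_numpy())
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, idempotent)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out
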