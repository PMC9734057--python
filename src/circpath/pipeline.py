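"""End-to-end orchestration: simulate/load -> scans -> MPT -> CIT -> paths.

One :class:`RunConfig` holds every threshold with its canonical default
(cis window 200 kb, 10,000 permutations, empP < 0.005, Storey q < 0.05,
trans nominal P < 1e-4, trans distance > 5 Mb, alpha 0.05) plus a single
master seed from which each stage derives its own deterministic
substream.  ``run_pipeline`` writes per-stage TSVs and a JSON manifest
with the filter tallies; identical config + seed reproduces identical
outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as cio
from . import qtl
from .cit import cit_fdr, cit_test
from .mediation import mediate, mpt_filter, spearman_partial
from .paths import attach_mirna, build_axes, integrate_paths, mirna_screen
from .simulate import ScenarioConfig, simulate_cohort

logger = logging.getLogger("circpath.pipeline")


@dataclass
class RunConfig:
    """All inputs and thresholds of one reproducible run."""

    # inputs: either a directory of cohort files or a simulation config
    input_dir: Optional[str] = None
    simulate: Optional[ScenarioConfig] = None
    out_dir: str = "circpath_run"

    window_bp: int = qtl.DEFAULT_WINDOW_BP
    n_perm: int = qtl.DEFAULT_N_PERM
    empp_cut: float = qtl.DEFAULT_EMPP_CUT
    q_cut: float = qtl.DEFAULT_Q_CUT
    trans_p_cut: float = qtl.DEFAULT_TRANS_P_CUT
    trans_dist_bp: int = qtl.DEFAULT_TRANS_DIST_BP
    alpha: float = 0.05
    maf_min: float = cio.DEFAULT_MAF_MIN
    n_draws: int = 1000
    cit_n_perm: int = 1000
    cit_n_perm_fdr: int = 50
    pooling: str = "per_feature"
    mirna_post_alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = ScenarioConfig(**sim)
        return cfg


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage substream seed derived from the master seed."""
    ss = np.random.SeedSequence(entropy=master, spawn_key=(zlib.crc32(stage.encode()),))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _load_inputs(config: RunConfig) -> dict:
    if config.simulate is not None:
        cohort = simulate_cohort(config.simulate)
        return {
            "genotypes": cohort.genotypes,
            "circ_expr": cohort.circ_expr,
            "gene_expr": cohort.gene_expr,
            "mirna_expr": cohort.mirna_expr,
            "covariates": cohort.covariates,
            "truth": cohort.truth,
            "mirna_targets": cohort.mirna_targets,
        }
    if config.input_dir is None:
        raise ValueError("RunConfig needs input_dir or simulate")
    return cio.read_cohort(config.input_dir, maf_min=config.maf_min)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order; returns the run manifest (also written).

    Stage failure aborts with the stage name; TSVs written by earlier
    stages are retained for inspection.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "thresholds": {
            k: v
            for k, v in asdict(config).items()
            if k not in ("input_dir", "simulate", "out_dir")
        },
        "seed": config.seed,
        "counts": {},
    }
    counts = manifest["counts"]
    stage = "load"
    try:
        data = _load_inputs(config)
        genotypes, covariates = data["genotypes"], data["covariates"]
        # the miRNA layer may cover only a sample subset; it is aligned
        # separately inside the screen rather than shrinking the cohort
        genotypes, (circ_expr, gene_expr), covariates, sample_ids = cio.align_samples(
            genotypes, [data["circ_expr"], data["gene_expr"]], covariates
        )
        mirna_expr = data["mirna_expr"]
        diagnosis = covariates.diagnosis
        counts["n_samples"] = len(sample_ids)
        counts["n_snps"] = int(genotypes.dosages.shape[1])
        counts["n_circ"] = int(circ_expr.values.shape[0])
        counts["n_genes"] = int(gene_expr.values.shape[0])

        stage = "residualize"
        circ_resid = qtl.residualize(circ_expr, covariates)
        gene_resid = qtl.residualize(gene_expr, covariates)

        stage = "scan-cis"
        cis_assoc = qtl.cis_scan(circ_resid, genotypes, config.window_bp)
        mask = qtl.cis_pair_mask(genotypes, circ_resid, config.window_bp)
        null = qtl.build_null(
            circ_resid,
            genotypes,
            mask,
            n_perm=config.n_perm,
            seed=stage_seed(config.seed, "cis-null"),
            unit_axis="feature",
        )
        callset = qtl.call_circqtls(
            cis_assoc,
            null,
            q_cut=config.q_cut,
            empp_cut=config.empp_cut,
            pooling=config.pooling,
        )
        callset = qtl.select_independent(callset, genotypes, circ_resid)
        cio.write_results(callset.associations, out / "cis_associations.tsv")
        cio.write_results(callset.feature_stats, out / "circ_feature_stats.tsv")
        cio.write_results(callset.retained, out / "circqtls_retained.tsv")
        cio.write_results(callset.independent, out / "circqtls_independent.tsv")
        counts["cis_pairs_tested"] = int(len(cis_assoc))
        counts["circqtls_retained"] = int(len(callset.retained))
        counts["circqtls_independent"] = int(len(callset.independent))
        counts["circqtl_circRNAs"] = int(callset.retained["feature_id"].nunique())

        stage = "scan-trans"
        snp_ids = callset.independent["snp_id"].unique().tolist()
        if snp_ids:
            trans_assoc, _ = qtl.trans_scan(
                genotypes.subset_snps(snp_ids),
                gene_resid,
                trans_dist_bp=config.trans_dist_bp,
                p_cut=config.trans_p_cut,
                empp_cut=config.empp_cut,
                n_perm=config.n_perm,
                seed=stage_seed(config.seed, "trans-null"),
                pooling=config.pooling,
            )
        else:
            trans_assoc = pd.DataFrame(
                columns=[
                    "snp_id",
                    "feature_id",
                    "beta",
                    "se",
                    "t_stat",
                    "p_nominal",
                    "mode",
                    "emp_p",
                    "retained",
                ]
            )
        cio.write_results(trans_assoc, out / "trans_associations.tsv")
        trans_calls = trans_assoc.loc[trans_assoc.get("retained", pd.Series(dtype=bool)).fillna(False).astype(bool)]
        counts["trans_pairs_tested"] = int(len(trans_assoc))
        counts["trans_calls"] = int(len(trans_calls))

        stage = "build-axes"
        axes = build_axes(callset.independent, trans_calls)
        counts["axes"] = int(len(axes))

        stage = "mediate"
        med_results, par_results = {}, {}
        med_seed = stage_seed(config.seed, "mediation")
        for i, ax in axes.iterrows():
            g = genotypes.dosages[ax["snp_id"]].to_numpy(dtype=float)
            m = circ_resid.values.loc[ax["circ_id"]].to_numpy(dtype=float)
            y = gene_resid.values.loc[ax["gene_id"]].to_numpy(dtype=float)
            key = (ax["snp_id"], ax["circ_id"], ax["gene_id"])
            med_results[key] = mediate(
                g, m, y, n_draws=config.n_draws, seed=(med_seed + i) % (2**31 - 1)
            )
            par_results[key] = spearman_partial(m, y, g[:, None])
        mpt = mpt_filter(axes, med_results, par_results, alpha=config.alpha)
        if not mpt.empty:
            cio.write_results(mpt, out / "mpt_axes.tsv")
        counts["mpt_axes"] = int(mpt["mpt_pass"].sum()) if not mpt.empty else 0

        stage = "cit"
        if diagnosis is None:
            raise ValueError("CIT requires a diagnosis column in the covariates")
        pairs = (
            trans_calls[["snp_id", "feature_id"]]
            .drop_duplicates()
            .rename(columns={"feature_id": "gene_id"})
            .reset_index(drop=True)
        )
        T = diagnosis.to_numpy(dtype=float)
        triples, results = [], []
        cit_seed = stage_seed(config.seed, "cit")
        for i, pr in pairs.iterrows():
            L = genotypes.dosages[pr["snp_id"]].to_numpy(dtype=float)
            G = gene_resid.values.loc[pr["gene_id"]].to_numpy(dtype=float)
            triples.append((L, G, T))
            results.append(
                cit_test(
                    L, G, T, n_perm=config.cit_n_perm, seed=(cit_seed + i) % (2**31 - 1)
                )
            )
        if results:
            cit_fdr(
                triples,
                results,
                n_perm_fdr=config.cit_n_perm_fdr,
                seed=stage_seed(config.seed, "cit-fdr"),
            )
        cit_table = pairs.copy()
        for name in ("p1", "p2", "p3", "p4", "p_omnibus", "q"):
            cit_table[name] = [getattr(r, name) for r in results] if results else []
        cit_table["cit_pass"] = [
            r.passes(config.alpha, config.q_cut) for r in results
        ] if results else []
        cio.write_results(cit_table, out / "cit_results.tsv")
        counts["cit_pairs_tested"] = int(len(cit_table))
        counts["cit_pairs"] = int(cit_table["cit_pass"].sum()) if len(cit_table) else 0

        stage = "build-paths"
        paths = integrate_paths(mpt, cit_table)
        counts["paths"] = int(len(paths))

        stage = "mirna-screen"
        if mirna_expr is not None and data.get("mirna_targets") is not None and not mpt.empty:
            cand = mpt.loc[mpt["mpt_pass"], ["circ_id", "gene_id"]].drop_duplicates()
            mirna_axes = mirna_screen(
                cand,
                data["mirna_targets"],
                mirna_expr,
                circ_resid,
                gene_resid,
                alpha=config.alpha,
                post_alpha=config.mirna_post_alpha,
            )
            cio.write_results(mirna_axes, out / "mirna_axes.tsv")
            counts["mirna_axes"] = int(mirna_axes["mirna_pass"].sum()) if len(mirna_axes) else 0
            paths = attach_mirna(paths, mirna_axes)
            counts["paths_with_mirna"] = int(paths["mirna_pass"].sum()) if len(paths) else 0
        cio.write_results(paths, out / "propagation_paths.tsv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", json.dumps(counts))
    return manifest
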