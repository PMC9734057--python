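"""Readers and writers for every on-disk artifact.

Conventions
-----------
* TSV matrices carry features/SNPs in rows and samples in columns.
* BED-like circRNA annotation is 0-based half-open on disk; internally all
  coordinates are 1-based inclusive, so a BED row ``(chr1, 999, 2000)``
  becomes donor/acceptor coordinates ``(1000, 2000)``.
* Sample alignment across files is the *sorted intersection* of sample
  ids, applied identically to every matrix, so the aligned cohort does not
  depend on the column order of any input file.
* Missing dosages ("NA"/empty) are imputed with the SNP mean; SNPs with
  MAF below ``maf_min`` (default 0.05) are dropped and counted.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    CovariateTable,
    ExpressionMatrix,
    GenotypeMatrix,
    MirnaTargetTable,
    SyntheticCohort,
)

logger = logging.getLogger("circpath.io")

DEFAULT_MAF_MIN = 0.05


def bed_to_internal(start0: int, end: int) -> tuple:
    """Convert one BED half-open interval to 1-based inclusive coordinates."""
    return int(start0) + 1, int(end)


def read_genotypes(
    path, maf_min: float = DEFAULT_MAF_MIN
) -> GenotypeMatrix:
    """Read a TSV dosage matrix (rows: SNPs; leading columns chrom, pos).

    Missing cells are imputed with the SNP mean; SNPs whose folded allele
    frequency falls below ``maf_min`` are dropped (and the drop is logged).
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    except OSError as exc:  # pragma: no cover - propagated with context
        raise OSError(f"cannot read genotypes from {path}: {exc}") from exc
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate SNP ids in {path}: {dups}")
    if not {"chrom", "pos"} <= set(df.columns):
        raise ValueError(f"{path} lacks required 'chrom'/'pos' columns")
    positions = df[["chrom", "pos"]].copy()
    positions["pos"] = positions["pos"].astype(int)
    dos = df.drop(columns=["chrom", "pos"]).astype(float)

    n_missing = int(dos.isna().sum().sum())
    if n_missing:
        dos = dos.apply(lambda row: row.fillna(row.mean()), axis=1)
        logger.info("imputed %d missing dosage cells with SNP means", n_missing)

    af = dos.mean(axis=1) / 2.0
    maf = np.minimum(af, 1 - af)
    keep = maf >= maf_min
    if (~keep).any():
        logger.info("dropped %d SNPs with MAF < %g", int((~keep).sum()), maf_min)
    dos = dos.loc[keep]
    # sort positions within chromosome on load
    positions = positions.loc[dos.index].sort_values(["chrom", "pos"], kind="stable")
    dos = dos.loc[positions.index].T
    dos.index.name = "sample_id"
    dos.columns.name = None
    return GenotypeMatrix(dos, positions, maf.loc[dos.columns])


def read_vcf_genotypes(path, maf_min: float = DEFAULT_MAF_MIN) -> GenotypeMatrix:
    """Minimal VCF reader: uses the DS FORMAT field if present, else GT.

    Provided for convenience; the primary genotype format is the TSV
    dosage matrix.
    """
    import io as _stdio

    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids, chroms, pos, rows = [], [], [], []
    for var in vcf:
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        if "DS" in (var.FORMAT or []):
            ds = np.asarray(var.format("DS"), dtype=float).reshape(-1)
        else:
            # cyvcf2 gt_types: 0=HOM_REF 1=HET 2=UNKNOWN 3=HOM_ALT
            gts = np.asarray(var.gt_types, dtype=float)
            ds = np.select(
                [gts == 0, gts == 1, gts == 3], [0.0, 1.0, 2.0], default=np.nan
            )
        snp_ids.append(vid)
        chroms.append(var.CHROM)
        pos.append(var.POS)
        rows.append(ds)
    df = pd.DataFrame(rows, index=pd.Index(snp_ids, name="snp_id"), columns=samples)
    df.insert(0, "chrom", chroms)
    df.insert(1, "pos", pos)
    # route through the TSV path for imputation/filter consistency
    buf = _stdio.StringIO()
    df.to_csv(buf, sep="\t")
    buf.seek(0)
    return read_genotypes(buf, maf_min=maf_min)


def read_expression(path, role: str, bed: Optional[object] = None) -> ExpressionMatrix:
    """Read a features x samples expression TSV.

    With ``bed`` given (circRNA back-splice annotation, BED6), feature
    loci come from the BED file with half-open -> 1-based conversion;
    otherwise the TSV must embed ``chrom``, ``start``, ``end``, ``strand``
    columns (already 1-based inclusive).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate feature ids in {path}: {dups}")
    if bed is not None:
        loci = read_bed_annotation(bed)
        values = df.astype(float)
    else:
        need = {"chrom", "start", "end", "strand"}
        if not need <= set(df.columns):
            raise ValueError(f"{path} lacks loci columns {sorted(need)} and no BED given")
        loci = df[["chrom", "start", "end", "strand"]].copy()
        loci[["start", "end"]] = loci[["start", "end"]].astype(int)
        values = df.drop(columns=list(need)).astype(float)
    if values.isna().any().any():
        n_bad = int(values.isna().any(axis=1).sum())
        logger.info("dropping %d features with missing expression", n_bad)
        values = values.dropna(axis=0)
    missing = set(values.index) - set(loci.index)
    if missing:
        raise ValueError(f"features without annotation: {sorted(missing)[:5]}")
    return ExpressionMatrix(values, loci.loc[values.index], role)


def read_bed_annotation(path) -> pd.DataFrame:
    """Read BED6 circRNA annotation into 1-based inclusive loci."""
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start0", "end", "name", "score", "strand"],
        comment="#",
    )
    if bed["name"].duplicated().any():
        dups = bed.loc[bed["name"].duplicated(), "name"].tolist()
        raise ValueError(f"duplicate feature ids in BED: {dups}")
    starts = [bed_to_internal(s, e) for s, e in zip(bed["start0"], bed["end"])]
    loci = pd.DataFrame(
        {
            "chrom": bed["chrom"].to_numpy(),
            "start": [a for a, _ in starts],
            "end": [b for _, b in starts],
            "strand": bed["strand"].to_numpy(),
        },
        index=pd.Index(bed["name"], name="feature_id"),
    )
    return loci


def read_covariates(path) -> CovariateTable:
    """Read per-sample covariates (rows: samples); optional ``diagnosis`` column.

    Categorical (non-numeric) covariates are one-hot encoded with one
    reference level dropped, levels in sorted order, so the encoding is
    deterministic.
    """
    df = pd.read_csv(Path(path), sep="\t", index_col=0)
    diag = None
    if "diagnosis" in df.columns:
        diag = df["diagnosis"].astype(int)
        df = df.drop(columns=["diagnosis"])
    encoded = []
    for col in df.columns:
        if pd.api.types.is_numeric_dtype(df[col]):
            encoded.append(df[[col]].astype(float))
        else:
            levels = sorted(df[col].astype(str).unique())
            for lev in levels[1:]:
                encoded.append(
                    (df[col].astype(str) == lev).astype(float).to_frame(f"{col}={lev}")
                )
    data = pd.concat(encoded, axis=1) if encoded else pd.DataFrame(index=df.index)
    return CovariateTable(data, diag)


def read_mirna_targets(path) -> MirnaTargetTable:
    df = pd.read_csv(Path(path), sep="\t")
    if not {"regulator_id", "mirna_id"} <= set(df.columns):
        raise ValueError(f"{path} must have columns regulator_id, mirna_id")
    return MirnaTargetTable(df)


def write_results(table: pd.DataFrame, path, float_format: str = "%.6g") -> Path:
    """Write a results table as TSV (column schema documented per stage)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, float_format=float_format)
    return path


def align_samples(
    genotypes: GenotypeMatrix,
    expressions: Sequence[ExpressionMatrix],
    covariates: Optional[CovariateTable] = None,
) -> tuple:
    """Subset every component to the sorted intersection of sample ids.

    Raises if the intersection is empty.  Returns
    ``(genotypes, [expressions...], covariates, sample_ids)``.
    """
    common = set(genotypes.sample_ids)
    for e in expressions:
        common &= set(e.sample_ids)
    if covariates is not None:
        common &= set(covariates.sample_ids)
    if not common:
        raise ValueError("no overlapping samples across inputs")
    ids = sorted(common)
    logger.info("aligned %d shared samples", len(ids))
    return (
        genotypes.subset_samples(ids),
        [e.subset_samples(ids) for e in expressions],
        covariates.subset_samples(ids) if covariates is not None else None,
        ids,
    )


# ---------------------------------------------------------------------------
# cohort-level round trip


def write_cohort(cohort: SyntheticCohort, directory) -> dict:
    """Write a cohort to ``directory`` in the formats the pipeline reads.

    Dosages round-trip bit-exactly (full float repr); expression is written
    with 6 decimals.  With no miRNA layer, no miRNA files are emitted.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = {}

    g = cohort.genotypes
    gdf = g.dosages.T  # SNPs x samples
    gdf = pd.concat([g.positions.loc[gdf.index, ["chrom", "pos"]], gdf], axis=1)
    gdf.index.name = "snp_id"
    out["genotypes"] = directory / "genotypes.tsv"
    gdf.to_csv(out["genotypes"], sep="\t")

    # circRNA: BED6 annotation (0-based half-open) + bare expression matrix
    loci = cohort.circ_expr.loci
    bed = pd.DataFrame(
        {
            "chrom": loci["chrom"],
            "start0": loci["start"] - 1,
            "end": loci["end"],
            "name": loci.index,
            "score": ".",
            "strand": loci["strand"],
        }
    )
    out["circ_bed"] = directory / "circ_annotation.bed"
    bed.to_csv(out["circ_bed"], sep="\t", header=False, index=False)
    out["circ_expr"] = directory / "circ_expr.tsv"
    cohort.circ_expr.values.round(6).to_csv(
        out["circ_expr"], sep="\t", index_label="feature_id", float_format="%.6f"
    )

    for name, expr in (("gene", cohort.gene_expr), ("mirna", cohort.mirna_expr)):
        if expr is None:
            continue
        df = pd.concat([expr.loci, expr.values.round(6)], axis=1)
        df.index.name = "feature_id"
        out[f"{name}_expr"] = directory / f"{name}_expr.tsv"
        df.to_csv(out[f"{name}_expr"], sep="\t", float_format="%.6f")

    cov = cohort.covariates.data.copy()
    cov["diagnosis"] = cohort.diagnosis
    cov.index.name = "sample_id"
    out["covariates"] = directory / "covariates.tsv"
    cov.to_csv(out["covariates"], sep="\t", float_format="%.10g")

    out["truth"] = directory / "truth.tsv"
    cohort.truth.to_csv(out["truth"], sep="\t", index=False)

    if cohort.mirna_targets is not None:
        out["mirna_targets"] = directory / "mirna_targets.tsv"
        cohort.mirna_targets.pairs.to_csv(out["mirna_targets"], sep="\t", index=False)
    return {k: Path(v) for k, v in out.items()}


def read_cohort(directory, maf_min: float = 0.0) -> dict:
    """Read back a directory written by :func:`write_cohort`.

    Returns a dict with keys ``genotypes``, ``circ_expr``, ``gene_expr``,
    ``mirna_expr`` (None if absent), ``covariates``, ``truth``,
    ``mirna_targets`` (None if absent).  No MAF filtering by default so
    the round trip is lossless.
    """
    directory = Path(directory)
    genotypes = read_genotypes(directory / "genotypes.tsv", maf_min=maf_min)
    circ = read_expression(
        directory / "circ_expr.tsv", "circRNA", bed=directory / "circ_annotation.bed"
    )
    gene = read_expression(directory / "gene_expr.tsv", "gene")
    mirna_path = directory / "mirna_expr.tsv"
    mirna = read_expression(mirna_path, "miRNA") if mirna_path.exists() else None
    covariates = read_covariates(directory / "covariates.tsv")
    truth_path = directory / "truth.tsv"
    truth = pd.read_csv(truth_path, sep="\t") if truth_path.exists() else None
    tpath = directory / "mirna_targets.tsv"
    targets = read_mirna_targets(tpath) if tpath.exists() else None
    return {
        "genotypes": genotypes,
        "circ_expr": circ,
        "gene_expr": gene,
        "mirna_expr": mirna,
        "covariates": covariates,
        "truth": truth,
        "mirna_targets": targets,
    }
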