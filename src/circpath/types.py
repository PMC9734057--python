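"""Core in-memory containers shared by every pipeline stage.

All containers wrap :class:`pandas.DataFrame` / :class:`pandas.Series`
objects and enforce the invariants the pipeline relies on (unique
identifiers, dosage bounds, shared sample ordering).  Coordinates are
1-based inclusive internally; conversion from on-disk BED happens in
:mod:`circpath.io`.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class Scenario(str, Enum):
    """Planted causal structure of a synthetic (SNP, circRNA, gene) triple.

    MEDIATION   SNP -> circRNA -> gene (plus optional direct SNP -> gene edge);
                diagnosis downstream of gene expression.
    PLEIOTROPY  SNP -> circRNA and SNP -> gene independently; no
                circRNA -> gene edge.
    INDEPENDENT SNP -> gene, diagnosis independent of everything.
    REVERSE     diagnosis drawn from the SNP first, gene expression
                downstream of diagnosis (trait-as-mediator).
    NULL        no planted genetic or causal effects at all.
    """

    MEDIATION = "MEDIATION"
    PLEIOTROPY = "PLEIOTROPY"
    INDEPENDENT = "INDEPENDENT"
    REVERSE = "REVERSE"
    NULL = "NULL"


class InvalidParameterError(ValueError):
    """Raised when a user-supplied parameter violates a documented precondition."""


@dataclass
class GenotypeMatrix:
    """Additive dosages for samples x SNPs plus SNP genomic positions.

    Parameters
    ----------
    dosages
        DataFrame indexed by sample id with one column per SNP; values in
        [0, 2] (fractional dosages from imputation are allowed).
    positions
        DataFrame indexed by SNP id with columns ``chrom`` and ``pos``
        (1-based).
    maf
        Per-SNP minor allele frequency.  If not given it is computed from
        the dosages (folded to the minor allele).
    """

    dosages: pd.DataFrame
    positions: pd.DataFrame
    maf: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.dosages.columns.duplicated().any():
            dups = self.dosages.columns[self.dosages.columns.duplicated()].tolist()
            raise ValueError(f"duplicate SNP ids: {dups}")
        if not set(self.dosages.columns) <= set(self.positions.index):
            missing = sorted(set(self.dosages.columns) - set(self.positions.index))
            raise ValueError(f"SNPs without positions: {missing[:5]}")
        vals = self.dosages.to_numpy(dtype=float)
        if vals.size and (np.nanmin(vals) < -1e-9 or np.nanmax(vals) > 2 + 1e-9):
            raise ValueError("dosages outside [0, 2]")
        self.dosages.index.name = "sample_id"
        self.dosages.columns.name = None
        self.positions = self.positions.loc[self.dosages.columns]
        if self.maf is None:
            af = self.dosages.mean(axis=0) / 2.0
            self.maf = np.minimum(af, 1.0 - af)
        else:
            self.maf = self.maf.loc[self.dosages.columns]

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def snp_ids(self) -> pd.Index:
        return self.dosages.columns

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages.loc[list(sample_ids)], self.positions.copy(), self.maf.copy()
        )

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        ids = list(snp_ids)
        return GenotypeMatrix(
            self.dosages[ids], self.positions.loc[ids], self.maf.loc[ids]
        )


@dataclass
class ExpressionMatrix:
    """Normalized abundances for features x samples with feature coordinates.

    For circRNAs ``start``/``end`` in :attr:`loci` are the back-splice
    acceptor/donor genomic coordinates (1-based inclusive); for genes and
    miRNAs they delimit the annotated feature body.
    """

    values: pd.DataFrame  # features x samples
    loci: pd.DataFrame  # index feature_id: chrom, start, end, strand
    role: str  # "circRNA" | "gene" | "miRNA"

    def __post_init__(self) -> None:
        if self.role not in ("circRNA", "gene", "miRNA"):
            raise ValueError(f"unknown expression role {self.role!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains NaN after loading")
        if not set(self.values.index) <= set(self.loci.index):
            missing = sorted(set(self.values.index) - set(self.loci.index))
            raise ValueError(f"features without loci: {missing[:5]}")
        self.loci = self.loci.loc[self.values.index]
        self.values.index.name = "feature_id"
        self.loci.index.name = "feature_id"

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[list(sample_ids)], self.loci.copy(), self.role
        )


@dataclass
class CovariateTable:
    """Numeric covariates per sample, optionally with a binary diagnosis."""

    data: pd.DataFrame  # samples x covariates, numeric
    diagnosis: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.diagnosis is not None:
            self.diagnosis = self.diagnosis.loc[self.data.index]
            uniq = set(pd.unique(self.diagnosis.dropna()))
            if not uniq <= {0, 1}:
                raise ValueError(f"diagnosis must be binary 0/1, saw {sorted(uniq)}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    def design(self) -> np.ndarray:
        """Design matrix [intercept | covariates]; raises if rank deficient."""
        X = np.column_stack(
            [np.ones(len(self.data)), self.data.to_numpy(dtype=float)]
        )
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # identify offending columns for the error message
            bad = []
            for j, col in enumerate(self.data.columns):
                sub = np.delete(X, j + 1, axis=1)
                if np.linalg.matrix_rank(sub) == rank:
                    bad.append(col)
            raise ValueError(
                f"rank-deficient covariate design (rank {rank} < {X.shape[1]}); "
                f"linearly dependent columns: {bad}"
            )
        return X

    def subset_samples(self, sample_ids: Sequence[str]) -> "CovariateTable":
        ids = list(sample_ids)
        diag = self.diagnosis.loc[ids] if self.diagnosis is not None else None
        return CovariateTable(self.data.loc[ids], diag)


@dataclass
class MirnaTargetTable:
    """Unique (regulator feature, miRNA) target-site pairs.

    A row means the miRNA has a (CLIP-supported) target site on that
    circRNA or gene, so the miRNA can in principle bridge the two.
    """

    pairs: pd.DataFrame  # columns regulator_id, mirna_id

    def __post_init__(self) -> None:
        self.pairs = (
            self.pairs[["regulator_id", "mirna_id"]]
            .drop_duplicates()
            .reset_index(drop=True)
        )

    def mirnas_targeting(self, regulator_id: str) -> list:
        sel = self.pairs["regulator_id"] == regulator_id
        return self.pairs.loc[sel, "mirna_id"].tolist()


@dataclass
class PermutationNull:
    """Permutation null distribution for empirical p-values.

    ``null_p`` holds, for each permutation, the per-unit minimum nominal P:
    units are circRNA features for the cis scan and SNPs for the trans
    scan.  Shape ``(n_perm, n_units)``.
    """

    null_p: np.ndarray
    unit_ids: list
    unit_axis: str  # "feature" (cis) | "snp" (trans)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.null_p = np.asarray(self.null_p, dtype=float)
        if self.null_p.ndim != 2 or self.null_p.shape[1] != len(self.unit_ids):
            raise ValueError("null_p must be (n_perm, n_units)")
        if self.null_p.shape[0] < 1:
            raise ValueError("empty permutation null")

    @property
    def n_perm(self) -> int:
        return self.null_p.shape[0]

    def column(self, unit_id) -> np.ndarray:
        j = self.unit_ids.index(unit_id)
        return self.null_p[:, j]


@dataclass
class SyntheticCohort:
    """A simulated cohort with its planted ground truth."""

    genotypes: GenotypeMatrix
    circ_expr: ExpressionMatrix
    gene_expr: ExpressionMatrix
    mirna_expr: Optional[ExpressionMatrix]
    covariates: CovariateTable
    diagnosis: pd.Series
    truth: pd.DataFrame
    mirna_targets: Optional[MirnaTargetTable] = None

    def __post_init__(self) -> None:
        ref = list(self.genotypes.sample_ids)
        parts = [self.circ_expr.sample_ids, self.gene_expr.sample_ids,
                 self.covariates.sample_ids, self.diagnosis.index]
        for p in parts:
            if list(p) != ref:
                raise ValueError("cohort components disagree on sample ordering")
        if self.mirna_expr is not None:
            # the miRNA layer may cover a subset, but in consistent order
            pos = {s: i for i, s in enumerate(ref)}
            idx = [pos.get(s, -1) for s in self.mirna_expr.sample_ids]
            if -1 in idx or any(b <= a for a, b in zip(idx, idx[1:])):
                raise ValueError(
                    "miRNA samples must be an order-consistent subset of the cohort"
                )
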