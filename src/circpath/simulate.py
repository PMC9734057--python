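"""Synthetic cohorts with planted causal structure.

The generator emulates the data the pipeline is designed for: imputed
genotype dosages under Hardy-Weinberg equilibrium, covariate-confounded
circRNA/gene/miRNA expression, cis genetic effects on circRNAs, trans
effects on distant genes that are either mediated by the circRNA or
pleiotropic, and a binary diagnosis causally downstream (or upstream, or
independent) of gene expression.  Every planted (SNP, circRNA, gene,
miRNA) triple is recorded in a truth table so each inference stage can be
scored against ground truth.

Expression is emitted already normalized (unit-variance residual noise on
a continuous scale); read-count sampling and library-size normalization
are deliberately out of scope.

Geometry: each triple lives on its own chromosome region.  The planted
cis SNP and its decoys are placed within +/-200 kb of the back-splice
site; the trans gene is placed 20 Mb downstream on the same chromosome,
so both the cis-window rule and the >5 Mb trans-distance rule are
exercised by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .types import (
    CovariateTable,
    ExpressionMatrix,
    GenotypeMatrix,
    InvalidParameterError,
    MirnaTargetTable,
    Scenario,
    SyntheticCohort,
)

#: genomic layout constants (bp)
_BS_DONOR0 = 10_000_000  # back-splice donor of the first triple
_BS_SPAN = 5_000  # circRNA genomic span (donor .. acceptor)
_TRIPLE_SPACING = 40_000_000  # distance between triples sharing a chromosome
_GENE_OFFSET = 20_000_000  # trans gene placed this far from the donor
_GENE_SPAN = 50_000
_N_CHROMS = 22


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic cohort.

    Effect sizes are in residual-SD units: ``beta_cis`` is the change in
    circRNA expression per alternative allele, ``beta_med`` the change in
    gene expression per circRNA expression unit, and ``theta_trait`` the
    change in diagnosis log-odds per gene expression unit.
    """

    n_samples: int = 105
    n_snps: int = 10
    n_circ: int = 1
    n_genes: int = 1
    n_mirna: int = 0
    maf_range: Tuple[float, float] = (0.1, 0.5)
    beta_cis: float = 0.8
    beta_med: float = 0.6
    beta_direct: float = 0.0
    beta_pleio: float = 0.48
    theta_trait: float = 0.0
    scenario: Scenario = Scenario.MEDIATION
    noise_sd: float = 1.0
    gene_noise_sd: Optional[float] = None  # defaults to noise_sd
    n_covariates: int = 2
    covariate_loading: float = 0.5
    ld_rho: float = 0.0  # pairwise latent correlation within LD blocks
    ld_block_size: int = 1
    mirna_bridge: bool = True  # route MEDIATION circ->gene effect through the miRNA
    n_mirna_samples: Optional[int] = None  # miRNA assayed on a sample subset
    scenarios: Optional[Sequence[Scenario]] = None  # per-triple override
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_snps", "n_circ", "n_genes"):
            if getattr(self, name) < 1:
                raise InvalidParameterError(f"{name} must be >= 1")
        if self.n_mirna < 0 or self.n_covariates < 0:
            raise InvalidParameterError("n_mirna and n_covariates must be >= 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise InvalidParameterError(f"maf_range {self.maf_range} outside (0, 0.5]")
        self.scenario = Scenario(self.scenario)
        if self.scenarios is not None:
            self.scenarios = [Scenario(s) for s in self.scenarios]
            if len(self.scenarios) != self.n_circ:
                raise InvalidParameterError("scenarios must have one entry per circRNA")
            if Scenario.REVERSE in self.scenarios and len(set(self.scenarios)) > 1:
                raise InvalidParameterError(
                    "REVERSE cannot be mixed with other scenarios in one cohort"
                )
        if self.noise_sd <= 0:
            raise InvalidParameterError("noise_sd must be positive")
        if not (-1.0 < self.ld_rho < 1.0):
            raise InvalidParameterError("ld_rho must lie in (-1, 1)")
        if self.ld_block_size < 1:
            raise InvalidParameterError("ld_block_size must be >= 1")

    @property
    def triple_scenarios(self) -> list:
        if self.scenarios is not None:
            return list(self.scenarios)
        return [self.scenario] * self.n_circ


def default_snp_positions(n_snps: int, n_circ: int = 1) -> pd.DataFrame:
    """Place ``n_snps`` round-robin in the cis windows of ``n_circ`` triples.

    SNP ``i`` belongs to triple ``i % n_circ``; within a triple the SNPs
    are spread uniformly over [donor - 200 kb, acceptor + 200 kb].  The
    first SNP of each triple sits 1 kb downstream of the donor and is the
    one that carries any planted cis effect.
    """
    chroms, positions, snp_ids = [], [], []
    per_triple = [0] * n_circ
    for i in range(n_snps):
        t = i % n_circ
        k = per_triple[t]
        per_triple[t] += 1
        donor, acceptor, chrom = _triple_coords(t)
        if k == 0:
            pos = donor + 1_000
        else:
            span = (acceptor + 200_000) - (donor - 200_000)
            pos = donor - 200_000 + (k * 37_337) % span
        chroms.append(chrom)
        positions.append(int(pos))
        snp_ids.append(f"snp_{t}_{k}")
    df = pd.DataFrame({"chrom": chroms, "pos": positions}, index=pd.Index(snp_ids, name="snp_id"))
    return df.sort_values(["chrom", "pos"], kind="stable")


def _triple_coords(t: int) -> Tuple[int, int, str]:
    chrom = f"chr{t % _N_CHROMS + 1}"
    donor = _BS_DONOR0 + (t // _N_CHROMS) * _TRIPLE_SPACING
    return donor, donor + _BS_SPAN, chrom


def simulate_genotypes(
    n_samples: int,
    snp_positions: pd.DataFrame,
    maf_range: Tuple[float, float] = (0.1, 0.5),
    seed: int = 0,
    mafs: Optional[np.ndarray] = None,
    ld_rho: float = 0.0,
    ld_block_size: int = 1,
) -> GenotypeMatrix:
    """Draw Hardy-Weinberg dosages Binomial(2, maf) for each SNP.

    Parameters
    ----------
    snp_positions
        DataFrame indexed by SNP id with ``chrom`` and ``pos`` columns;
        positions must be strictly increasing within each chromosome.
    mafs
        Optional explicit per-SNP allele frequencies; otherwise drawn
        uniformly from ``maf_range``.
    ld_rho, ld_block_size
        Optional LD: haplotypes are generated through a Gaussian copula
        with pairwise latent correlation ``ld_rho`` inside consecutive
        blocks of ``ld_block_size`` SNPs (per chromosome), which preserves
        the Binomial(2, maf) margins.
    """
    if n_samples < 2:
        raise InvalidParameterError("n_samples must be >= 2")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise InvalidParameterError(f"maf_range {maf_range} outside (0, 0.5]")
    for chrom, grp in snp_positions.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise InvalidParameterError(f"positions not strictly increasing on {chrom}")

    rng = np.random.default_rng(seed)
    n_snps = len(snp_positions)
    if mafs is None:
        mafs = rng.uniform(lo, hi, size=n_snps)
    else:
        mafs = np.asarray(mafs, dtype=float)
        if np.any((mafs <= 0) | (mafs > 0.5)):
            raise InvalidParameterError("explicit mafs outside (0, 0.5]")

    if ld_rho == 0.0 or ld_block_size <= 1:
        dosages = rng.binomial(2, mafs[None, :], size=(n_samples, n_snps)).astype(float)
    else:
        dosages = np.zeros((n_samples, n_snps))
        # two latent haplotype draws per sample; block-equicorrelated copula
        col_of = {s: j for j, s in enumerate(snp_positions.index)}
        for chrom, grp in snp_positions.groupby("chrom", sort=False):
            cols = np.array([col_of[s] for s in grp.index])
            m = len(cols)
            sq = np.sqrt(ld_rho)
            for hap in range(2):
                shared = rng.standard_normal((n_samples, (m + ld_block_size - 1) // ld_block_size))
                own = rng.standard_normal((n_samples, m))
                block_idx = np.arange(m) // ld_block_size
                z = sq * shared[:, block_idx] + np.sqrt(1 - ld_rho) * own
                from scipy.stats import norm

                alleles = (norm.cdf(z) < mafs[cols][None, :]).astype(float)
                dosages[:, cols] += alleles

    sample_ids = pd.Index([f"s{i:04d}" for i in range(n_samples)], name="sample_id")
    dos = pd.DataFrame(dosages, index=sample_ids, columns=snp_positions.index)
    realized = dos.mean(axis=0) / 2.0
    return GenotypeMatrix(dos, snp_positions.copy(), np.minimum(realized, 1 - realized))


def _solve_alpha(linear: np.ndarray) -> float:
    """Intercept of logit P(D=1) = alpha + linear giving mean prevalence 0.5."""
    if np.allclose(linear, linear[0]):
        return -float(linear[0])

    def f(a: float) -> float:
        return float(np.mean(expit(a + linear)) - 0.5)

    lo, hi = -50.0, 50.0
    return float(brentq(f, lo, hi, xtol=1e-10))


def simulate_cohort(config: ScenarioConfig) -> SyntheticCohort:
    """Generate one cohort under ``config``.

    Structural equations (per planted triple, effects zero under NULL)::

        circ = beta_cis * g + load * covariates + eps
        MEDIATION:    gene = beta_med * circ + beta_direct * g + load * cov + eps
        PLEIOTROPY:   gene = beta_pleio * g + load * cov + eps
        INDEPENDENT:  gene = beta_pleio * g + load * cov + eps   (diagnosis independent)
        REVERSE:      D ~ Bernoulli(expit(alpha + theta * g));  gene = beta_med * D + eps
        otherwise:    logit P(D=1) = alpha + sum_i theta_i * gene_i,
                      alpha solved numerically for expected prevalence 0.5.

    ``theta_i`` is ``theta_trait`` for MEDIATION triples (diagnosis is
    downstream of the mediated gene) and 0 for PLEIOTROPY, INDEPENDENT and
    NULL triples.  With ``n_mirna > 0`` and
    ``mirna_bridge`` the MEDIATION circ->gene edge is routed through a miRNA
    (``circ -> miRNA -> gene`` with sqrt(beta_med) on each leg), so the
    marginal circ->gene slope is preserved while giving the miRNA screen a
    true mediator.
    """
    rng = np.random.default_rng(config.seed)
    scenarios = config.triple_scenarios
    n = config.n_samples
    gene_noise = config.gene_noise_sd if config.gene_noise_sd is not None else config.noise_sd

    snp_positions = default_snp_positions(config.n_snps, config.n_circ)
    genotypes = simulate_genotypes(
        n,
        snp_positions,
        config.maf_range,
        seed=rng.integers(2**31 - 1),
        ld_rho=config.ld_rho,
        ld_block_size=config.ld_block_size,
    )

    cov = rng.standard_normal((n, config.n_covariates))
    cov_cols = [f"cov{i+1}" for i in range(config.n_covariates)]
    load = config.covariate_loading
    cov_effect = load * cov.sum(axis=1) if config.n_covariates else np.zeros(n)

    samples = genotypes.sample_ids
    circ_vals = np.zeros((config.n_circ, n))
    gene_vals = np.zeros((config.n_genes, n))
    mirna_vals = rng.standard_normal((config.n_mirna, n)) if config.n_mirna else None

    # planted cis SNP of triple t is "snp_{t}_0" (present whenever n_snps >= n_circ)
    truth_rows = []
    circ_loci, gene_loci, mirna_loci = [], [], []
    planted_g = {}
    for t in range(config.n_circ):
        donor, acceptor, chrom = _triple_coords(t)
        circ_loci.append((f"circ_{t}", chrom, donor, acceptor, "+"))
        snp_id = f"snp_{t}_0"
        scen = scenarios[t]
        has_snp = snp_id in genotypes.snp_ids
        g = genotypes.dosages[snp_id].to_numpy() if has_snp else np.zeros(n)
        planted_g[t] = g
        b_cis = config.beta_cis if (scen is not Scenario.NULL and has_snp) else 0.0
        circ_vals[t] = b_cis * g + cov_effect + config.noise_sd * rng.standard_normal(n)
        truth_rows.append(
            {
                "snp_id": snp_id if has_snp else "",
                "circ_id": f"circ_{t}",
                "gene_id": f"gene_{t}" if t < config.n_genes else "",
                "mirna_id": f"mirna_{t}"
                if (config.n_mirna > t and config.mirna_bridge and scen is Scenario.MEDIATION)
                else "",
                "scenario": scen.value,
                "beta_cis": b_cis,
                "beta_med": config.beta_med if scen in (Scenario.MEDIATION, Scenario.REVERSE) else 0.0,
                "beta_direct": config.beta_direct if scen is Scenario.MEDIATION else 0.0,
                "beta_pleio": config.beta_pleio
                if scen in (Scenario.PLEIOTROPY, Scenario.INDEPENDENT)
                else 0.0,
                "theta": config.theta_trait
                if scen in (Scenario.MEDIATION, Scenario.REVERSE)
                else 0.0,
            }
        )

    for j in range(config.n_mirna):
        donor, _, chrom = _triple_coords(j)
        mirna_loci.append((f"mirna_{j}", chrom, donor + 1_000_000, donor + 1_000_100, "+"))

    target_pairs = []
    diagnosis = None

    if scenarios and all(s is Scenario.REVERSE for s in scenarios):
        # trait-as-mediator: diagnosis from the SNP first, genes downstream
        linear = np.zeros(n)
        for t in range(min(config.n_circ, config.n_genes)):
            linear += config.theta_trait * planted_g[t]
        alpha = _solve_alpha(linear)
        diagnosis = (rng.uniform(size=n) < expit(alpha + linear)).astype(int)
        for t in range(config.n_genes):
            eps = gene_noise * rng.standard_normal(n)
            d_eff = config.beta_med * diagnosis if t < config.n_circ else 0.0
            gene_vals[t] = d_eff + cov_effect + eps
    else:
        for t in range(config.n_genes):
            eps = gene_noise * rng.standard_normal(n)
            if t >= config.n_circ:
                gene_vals[t] = cov_effect + eps
                continue
            scen = scenarios[t]
            g = planted_g[t]
            if scen is Scenario.MEDIATION:
                bridged = config.mirna_bridge and config.n_mirna > t
                if bridged:
                    leg = np.sqrt(config.beta_med) if config.beta_med >= 0 else np.nan
                    mirna_vals[t] = leg * circ_vals[t] + config.noise_sd * rng.standard_normal(n)
                    gene_vals[t] = (
                        leg * mirna_vals[t]
                        + config.beta_direct * g
                        + cov_effect
                        + eps
                    )
                    target_pairs.append((f"circ_{t}", f"mirna_{t}"))
                    target_pairs.append((f"gene_{t}", f"mirna_{t}"))
                else:
                    gene_vals[t] = (
                        config.beta_med * circ_vals[t]
                        + config.beta_direct * g
                        + cov_effect
                        + eps
                    )
            elif scen in (Scenario.PLEIOTROPY, Scenario.INDEPENDENT):
                gene_vals[t] = config.beta_pleio * g + cov_effect + eps
            else:  # NULL
                gene_vals[t] = cov_effect + eps

        linear = np.zeros(n)
        for row_idx, t in enumerate(range(min(config.n_circ, config.n_genes))):
            if truth_rows[t]["theta"] != 0.0:
                linear += truth_rows[t]["theta"] * gene_vals[t]
        alpha = _solve_alpha(linear) if np.any(linear != 0) else 0.0
        diagnosis = (rng.uniform(size=n) < expit(alpha + linear)).astype(int)

    for t in range(config.n_genes):
        src = t % config.n_circ
        donor, _, chrom = _triple_coords(src if t < config.n_circ else t)
        if t >= config.n_circ:
            donor, _, chrom = _triple_coords(t % _N_CHROMS)
        start = donor + _GENE_OFFSET + (t // config.n_circ) * (2 * _GENE_SPAN)
        gene_loci.append((f"gene_{t}", chrom, start, start + _GENE_SPAN, "+"))

    def _loci_frame(rows):
        return pd.DataFrame(
            rows, columns=["feature_id", "chrom", "start", "end", "strand"]
        ).set_index("feature_id")

    circ_expr = ExpressionMatrix(
        pd.DataFrame(circ_vals, index=[r[0] for r in circ_loci], columns=samples),
        _loci_frame(circ_loci),
        "circRNA",
    )
    gene_expr = ExpressionMatrix(
        pd.DataFrame(gene_vals, index=[r[0] for r in gene_loci], columns=samples),
        _loci_frame(gene_loci),
        "gene",
    )
    mirna_expr = None
    if config.n_mirna:
        # the miRNA layer may be assayed on only a subset of the cohort
        # (partial sample overlap, as with a separate small-RNA library)
        k = config.n_mirna_samples or n
        if not (1 <= k <= n):
            raise InvalidParameterError("n_mirna_samples must be in [1, n_samples]")
        mirna_expr = ExpressionMatrix(
            pd.DataFrame(
                mirna_vals[:, :k],
                index=[r[0] for r in mirna_loci],
                columns=samples[:k],
            ),
            _loci_frame(mirna_loci),
            "miRNA",
        )

    diag = pd.Series(diagnosis, index=samples, name="diagnosis")
    covariates = CovariateTable(
        pd.DataFrame(cov, index=samples, columns=cov_cols), diag
    )
    truth = pd.DataFrame(truth_rows)
    targets = (
        MirnaTargetTable(pd.DataFrame(target_pairs, columns=["regulator_id", "mirna_id"]))
        if target_pairs
        else None
    )
    return SyntheticCohort(
        genotypes=genotypes,
        circ_expr=circ_expr,
        gene_expr=gene_expr,
        mirna_expr=mirna_expr,
        covariates=covariates,
        diagnosis=diag,
        truth=truth,
        mirna_targets=targets,
    )


def write_cohort(cohort: SyntheticCohort, directory) -> dict:
    """Write a cohort in the pipeline's on-disk formats; returns file paths."""
    from . import io as _io

    return _io.write_cohort(cohort, directory)
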