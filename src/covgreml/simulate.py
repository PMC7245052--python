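"""Synthetic mother-offspring dyad generators with known ground truth.

Two generating processes are provided:

``model`` mode
    Data drawn exactly under the bivariate GREML model: offspring genotypes
    at independent SNPs, per-SNP effect pairs drawn so the two traits'
    genome-wide genetic values have a target 2x2 genetic (co)variance
    matrix, plus bivariate-normal residuals.  Every variance component the
    estimator targets is therefore known by construction.

``mechanistic`` mode
    The genetic-confounding causal diagram: maternal and paternal genotypes
    drawn at Hardy-Weinberg proportions, offspring genotypes produced by
    Mendelian transmission (one allele from each parent, Bernoulli(g/2) per
    parent per SNP), a maternal phenotype with heritability h2, and an
    offspring phenotype combining the same causal SNP effects with an
    environmental transmission path c_env * maternal phenotype.  Under
    random mating the mother-offspring genotypic correlation at a SNP is
    1/2, so pure genetic confounding (c_env = 0) induces a mother-offspring
    phenotypic covariance of h2 / 2.

Both modes emit two equal-sized synthetic cohorts (labels via a half split)
and neutral sex / age / gestational-age covariates so downstream fixed
effects and meta-analysis can be exercised; the covariates have no effect
on the phenotypes, keeping the closed-form expectations exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .panel import GenotypePanel, write_plink


@dataclass
class SimulationTruth:
    """Ground-truth record for a simulated dyad dataset."""

    mode: str  # "model" | "mechanistic"
    n_dyads: int
    n_snps: int
    maf_low: float
    maf_high: float
    seed: int
    # model mode
    theta_true: np.ndarray | None = None  # (sg1, sg12, sg2, se1, se12, se2)
    # mechanistic mode
    n_causal: int | None = None
    h2: float | None = None
    c_env: float | None = None
    causal_indices: np.ndarray | None = field(default=None, repr=False)
    beta: np.ndarray | None = field(default=None, repr=False)
    maternal_calls: np.ndarray | None = field(default=None, repr=False)
    paternal_calls: np.ndarray | None = field(default=None, repr=False)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "mode": self.mode,
            "n_dyads": self.n_dyads,
            "n_snps": self.n_snps,
            "maf_low": self.maf_low,
            "maf_high": self.maf_high,
            "seed": self.seed,
        }
        if self.theta_true is not None:
            doc["theta_true"] = [float(v) for v in self.theta_true]
        if self.mode == "mechanistic":
            doc.update(
                n_causal=self.n_causal, h2=self.h2, c_env=self.c_env,
                causal_indices=[int(i) for i in self.causal_indices],
            )
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def _check_maf_bounds(maf_low: float, maf_high: float) -> None:
    if not (0 < maf_low <= maf_high <= 0.5):
        raise ValueError("maf bounds must satisfy 0 < low <= high <= 0.5")


def _snp_metadata(n_snps: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": [f"snp{i + 1}" for i in range(n_snps)],
            "chrom": 1 + (np.arange(n_snps) % 22),
            "pos": 1 + np.arange(n_snps) * 1000,
            "allele1": "A",
            "allele2": "G",
            "maf": np.nan,
            "info_r2": np.nan,
            "hwe_p": np.nan,
        }
    )


def _draw_nondegenerate_genotypes(
    rng: np.random.Generator, p: np.ndarray, n: int
) -> np.ndarray:
    """Binomial(2, p_i) draws, redrawing any column that comes out monomorphic
    so sample standardization is always defined."""
    g = rng.binomial(2, p[None, :], size=(n, p.size)).astype(np.int8)
    for _ in range(100):
        mono = np.flatnonzero(g.min(axis=0) == g.max(axis=0))
        if mono.size == 0:
            break
        g[:, mono] = rng.binomial(2, p[None, mono], size=(n, mono.size)).astype(np.int8)
    return g


def _covariate_columns(rng: np.random.Generator, n: int) -> dict:
    """Neutral dyad covariates: two synthetic cohorts by a half split, sex,
    an adolescent measurement age and a gestational age at birth."""
    cohort = np.where(np.arange(n) < n // 2, "cohortA", "cohortB")
    return {
        "cohort": cohort,
        "sex": rng.integers(0, 2, size=n),
        "age": np.round(rng.normal(15.0, 0.5, size=n), 2),
        "gestage": np.round(rng.normal(40.0, 1.8, size=n), 1),
    }


def simulate_model_mode(
    n_dyads: int,
    n_snps: int,
    theta_true,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    seed: int = 0,
) -> tuple[GenotypePanel, pd.DataFrame, SimulationTruth]:
    """Simulate dyads exactly under the bivariate variance-component model.

    ``theta_true`` is (sg1, sg12, sg2, se1, se12, se2).  Per-SNP effect
    pairs (a_i, b_i) are bivariate normal with covariance Sigma_g / m on the
    column-standardized genotype scale, so the genetic values Z a and Z b
    have the target genetic (co)variances in expectation; residual pairs are
    bivariate normal with Sigma_e.  Trait 1 plays the offspring phenotype,
    trait 2 the maternal one (the maternal trait simply loads on the same
    offspring genotypes, which is the model the estimator assumes).
    """
    _check_maf_bounds(maf_low, maf_high)
    theta = np.asarray(theta_true, dtype=float)
    if theta.shape != (6,):
        raise ValueError("theta_true must have six components")
    sigma_g = np.array([[theta[0], theta[1]], [theta[1], theta[2]]])
    sigma_e = np.array([[theta[3], theta[4]], [theta[4], theta[5]]])
    total = sigma_g + sigma_e
    if np.any(np.linalg.eigvalsh(total) <= 0):
        raise ValueError("total covariance (Sigma_g + Sigma_e) must be positive definite")

    rng = np.random.default_rng(seed)
    p = rng.uniform(maf_low, maf_high, size=n_snps)
    calls = _draw_nondegenerate_genotypes(rng, p, n_dyads)

    z = calls.astype(float)
    z = (z - z.mean(axis=0)) / z.std(axis=0, ddof=1)
    # effect pairs with per-SNP covariance Sigma_g / m (zero matrix allowed)
    ab = rng.multivariate_normal(
        np.zeros(2), sigma_g / n_snps, size=n_snps, method="svd"
    )
    genetic = z @ ab  # (n, 2)
    resid = rng.multivariate_normal(np.zeros(2), sigma_e, size=n_dyads, method="svd")
    y = genetic + resid

    dyads = pd.DataFrame(
        {
            "dyad_id": [f"dyad{i + 1}" for i in range(n_dyads)],
            "y1": y[:, 0],
            "y2": y[:, 1],
            **_covariate_columns(rng, n_dyads),
        }
    )
    panel = GenotypePanel(
        list(dyads["dyad_id"]), _snp_metadata(n_snps), calls
    ).with_recomputed_metadata()
    truth = SimulationTruth(
        mode="model",
        n_dyads=n_dyads,
        n_snps=n_snps,
        maf_low=maf_low,
        maf_high=maf_high,
        seed=seed,
        theta_true=theta,
    )
    return panel, dyads, truth


def simulate_mechanistic(
    n_dyads: int,
    n_snps: int,
    n_causal: int,
    h2: float,
    c_env: float,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    seed: int = 0,
) -> tuple[GenotypePanel, pd.DataFrame, SimulationTruth]:
    """Simulate dyads under the genetic-confounding causal diagram.

    Maternal phenotype: y2 = sum_i beta_i z_m,i + e_m with genetic variance
    h2 and Var(e_m) = 1 - h2.  Offspring phenotype: y1 = sum_i beta_i z_o,i
    + c_env * y2 + e_o, with Var(e_o) chosen so Var(y1) = 1 in expectation
    (which requires h2 + c_env^2 + c_env * h2 <= 1).  Genotypes are
    standardized on the theoretical (2p, 2p(1-p)) scale so the maternal and
    offspring generations share one scale.  beta_i is nonzero for
    ``n_causal`` SNPs chosen uniformly at random, with equal per-SNP
    variance h2 / n_causal.
    """
    _check_maf_bounds(maf_low, maf_high)
    if not 0 <= h2 <= 1:
        raise ValueError("h2 must lie in [0, 1]")
    if not 1 <= n_causal <= n_snps:
        raise ValueError("n_causal must lie in [1, n_snps]")
    var_eo = 1.0 - h2 - c_env**2 - c_env * h2
    if var_eo < 0:
        raise ValueError(
            "h2 plus the variance implied by c_env exceeds 1; "
            "the offspring phenotype cannot be scaled to unit variance"
        )

    rng = np.random.default_rng(seed)
    p = rng.uniform(maf_low, maf_high, size=n_snps)
    gm = rng.binomial(2, p[None, :], size=(n_dyads, n_snps)).astype(np.int8)
    gf = rng.binomial(2, p[None, :], size=(n_dyads, n_snps)).astype(np.int8)
    # Mendelian transmission: one allele from each parent, Bernoulli(g/2)
    from_mother = rng.random((n_dyads, n_snps)) < gm / 2.0
    from_father = rng.random((n_dyads, n_snps)) < gf / 2.0
    go = (from_mother.astype(np.int8) + from_father.astype(np.int8)).astype(np.int8)

    causal = rng.choice(n_snps, size=n_causal, replace=False)
    beta = np.zeros(n_snps)
    beta[causal] = rng.normal(0.0, np.sqrt(h2 / n_causal), size=n_causal)

    scale = np.sqrt(2 * p * (1 - p))
    zm = (gm - 2 * p) / scale
    zo = (go - 2 * p) / scale
    y2 = zm @ beta + rng.normal(0.0, np.sqrt(1.0 - h2), size=n_dyads)
    y1 = zo @ beta + c_env * y2 + rng.normal(0.0, np.sqrt(var_eo), size=n_dyads)

    dyads = pd.DataFrame(
        {
            "dyad_id": [f"dyad{i + 1}" for i in range(n_dyads)],
            "y1": y1,
            "y2": y2,
            **_covariate_columns(rng, n_dyads),
        }
    )
    # offspring panel; redraw-protection is unnecessary here but monomorphic
    # columns can still occur at small n -- they are left for QC to drop
    panel = GenotypePanel(
        list(dyads["dyad_id"]), _snp_metadata(n_snps), go
    ).with_recomputed_metadata()
    truth = SimulationTruth(
        mode="mechanistic",
        n_dyads=n_dyads,
        n_snps=n_snps,
        maf_low=maf_low,
        maf_high=maf_high,
        seed=seed,
        n_causal=n_causal,
        h2=h2,
        c_env=c_env,
        causal_indices=causal,
        beta=beta,
        maternal_calls=gm,
        paternal_calls=gf,
    )
    return panel, dyads, truth


def expected_partition_mechanistic(truth: SimulationTruth):
    """Analytic expectations of the covariance partition under the
    mechanistic generator.

    Cov_P = h2/2 + c_env (the maternal phenotype has unit variance).  The
    genome-wide genetic covariance tagged by offspring SNPs is exactly 0
    when h2 = 0 and asymptotically h2/2 when c_env = 0; for the mixed case
    the projection of both traits onto offspring standardized genotypes
    gives the approximation h2/2 * (1 + c_env/2).  Returns a
    :class:`covgreml.partition.CovariancePartition`.
    """
    from .partition import CovariancePartition

    if truth.mode != "mechanistic":
        raise ValueError("expected_partition_mechanistic requires a mechanistic truth")
    h2, c_env = truth.h2, truth.c_env
    cov_p = 0.5 * h2 + c_env
    if h2 == 0:
        cov_g = 0.0
    elif c_env == 0:
        cov_g = 0.5 * h2
    else:
        cov_g = 0.5 * h2 * (1.0 + 0.5 * c_env)
    ratio = cov_g / cov_p if cov_p != 0 else float("nan")
    return CovariancePartition(
        cov_p=cov_p,
        cov_g=cov_g,
        cov_e=cov_p - cov_g,
        ratio=ratio,
        model_cov_p=cov_p,
        ratio_defined=cov_p != 0,
    )


def write_dyad_dataset(
    panel: GenotypePanel,
    dyads: pd.DataFrame,
    truth: SimulationTruth,
    prefix: str | Path,
) -> None:
    """Write PLINK bed/bim/fam, a dyad TSV and a YAML truth sidecar."""
    prefix = str(prefix)
    write_plink(panel, prefix)
    dyads.to_csv(prefix + ".dyads.tsv", sep="\t", index=False)
    truth.to_yaml(prefix + ".truth.yaml")


__all__ = [
    "SimulationTruth",
    "simulate_model_mode",
    "simulate_mechanistic",
    "expected_partition_mechanistic",
    "write_dyad_dataset",
]
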