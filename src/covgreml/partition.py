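"""Covariance partition: Cov_P = Cov_G + Cov_E and the ratio Cov_G : Cov_P.

Cov_P is the sample covariance of the standardized trait pair (equal to the
Pearson correlation for standardized traits), Cov_G is the genetic
covariance component sigma_g12 from the bivariate GREML fit, and Cov_E is
defined residually as Cov_P - Cov_G, so additivity holds exactly by
construction.  The ratio Cov_G : Cov_P (bivariate heritability /
coheritability) is reported unclamped: under an unconstrained fit it may be
negative or exceed 1 when the two components have opposite signs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .greml import GREMLResults


@dataclass
class CovariancePartition:
    """Phenotypic covariance split into genetic and residual parts.

    ``model_cov_p`` stores the model-implied total covariance
    sigma_g12 + sigma_e12, kept as a consistency diagnostic against the
    sample ``cov_p`` (they estimate the same quantity in a correctly
    specified model).
    """

    cov_p: float
    cov_g: float
    cov_e: float
    ratio: float
    model_cov_p: float
    ratio_defined: bool = True

    def rounded(self, decimals: int = 2) -> dict:
        """Display rounding only; stored values are never rounded."""
        return {
            "cov_p": round(self.cov_p, decimals),
            "cov_g": round(self.cov_g, decimals),
            "cov_e": round(self.cov_e, decimals),
            "ratio": round(self.ratio, decimals) if self.ratio_defined else float("nan"),
        }


def sample_covariance(y1, y2) -> float:
    """Sample covariance with the n-1 denominator over complete pairs.

    For standardized inputs this equals the Pearson correlation
    coefficient, which is why the partition's Cov_P is directly comparable
    across offspring phenotypes measured in different units.
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if y1.shape != y2.shape:
        raise ValueError("trait vectors must have equal length")
    ok = ~(np.isnan(y1) | np.isnan(y2))
    if ok.sum() < 2:
        raise ValueError("need at least 2 complete pairs")
    a, b = y1[ok], y2[ok]
    return float(np.sum((a - a.mean()) * (b - b.mean())) / (ok.sum() - 1))


def partition(vc: GREMLResults, cov_p: float) -> CovariancePartition:
    """Partition the phenotypic covariance using a bivariate GREML fit.

    cov_g = sigma_g12; cov_e = cov_p - cov_g (exact additivity); ratio =
    cov_g / cov_p, flagged undefined when cov_p is zero.
    """
    if vc.n_traits != 2:
        raise ValueError("partition requires a bivariate fit")
    cov_g = vc.sigma_g12
    cov_e = cov_p - cov_g
    defined = cov_p != 0
    ratio = cov_g / cov_p if defined else float("nan")
    return CovariancePartition(
        cov_p=cov_p,
        cov_g=cov_g,
        cov_e=cov_e,
        ratio=ratio,
        model_cov_p=vc.sigma_g12 + vc.sigma_e12,
        ratio_defined=defined,
    )


__all__ = ["CovariancePartition", "sample_covariance", "partition"]
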