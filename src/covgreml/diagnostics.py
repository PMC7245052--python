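"""Inflation diagnostics for GRM-based heritability estimates.

Cryptic relatedness and population stratification act genome-wide: a
confounding signal is counted once in a heritability estimate from the full
genome but once in *each* estimate from two disjoint genome halves, so the
sum of the half-genome estimates exceeding the full-genome estimate
signals inflation.  The PC-sensitivity scan refits the covariance partition
with increasing numbers of ancestry PCs; estimates that attenuate as PCs
are added point to stratification confounding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grm import build_grm
from .greml import UnivariateGREML
from .panel import GenotypePanel
from .partition import sample_covariance
from .pipeline import DyadDataset
from .greml import BivariateGREML
from .phenotypes import build_design_pair


@dataclass
class InflationResult:
    """Half-genome SNP-heritability inflation test.

    delta = (h2_half1 + h2_half2) - h2_full; near zero in the absence of
    stratification / cryptic relatedness, positive under inflation.
    ``delta_se`` combines the three delta-method SEs in quadrature (the
    estimates are treated as independent, which is approximate).
    """

    h2_half1: float
    h2_half2: float
    h2_full: float
    se_half1: float
    se_half2: float
    se_full: float
    delta: float
    delta_se: float
    split_rule: str


def _h2_with_se(y, X, grm_values) -> tuple[float, float]:
    """Univariate fit -> (h2, delta-method SE of h2)."""
    vc = UnivariateGREML(y, grm_values, X=X).fit()
    sg, se_ = vc.sigma_g, vc.sigma_e
    total = sg + se_
    h2 = sg / total
    # gradient of sg/(sg+se) wrt (sg, se)
    grad = np.array([se_, -sg]) / total**2
    var = float(grad @ vc.sampling_cov @ grad)
    return float(h2), float(np.sqrt(max(var, 0.0)))


def split_snps(panel: GenotypePanel, split_rule: str, seed: int = 0):
    """Partition SNP indices into two disjoint halves."""
    m = panel.n_snps
    if m < 2:
        raise ValueError("need at least 2 SNPs to split")
    if split_rule == "alternating":
        # alternate by SNP index within each chromosome
        order_within = panel.snps.groupby("chrom").cumcount().to_numpy()
        first = np.flatnonzero(order_within % 2 == 0)
        second = np.flatnonzero(order_within % 2 == 1)
    elif split_rule == "by_position":
        order = np.lexsort((panel.snps["pos"].to_numpy(), panel.snps["chrom"].to_numpy()))
        half = m // 2
        first, second = np.sort(order[:half]), np.sort(order[half:])
    elif split_rule == "random":
        perm = np.random.default_rng(seed).permutation(m)
        half = m // 2
        first, second = np.sort(perm[:half]), np.sort(perm[half:])
    else:
        raise ValueError(f"unknown split rule {split_rule!r}")
    return first, second


def half_genome_test(
    panel: GenotypePanel,
    y: np.ndarray,
    X: np.ndarray | None,
    split_rule: str = "alternating",
    seed: int = 0,
) -> InflationResult:
    """Fit univariate GREML with each genome half and with the full SNP set."""
    first, second = split_snps(panel, split_rule, seed)
    results = []
    for idx in (first, second, np.arange(panel.n_snps)):
        sub = panel.subset_snps(idx)
        mono = sub.minor_allele_frequency() <= 0
        if mono.all():
            raise ValueError("a genome half contains only monomorphic SNPs")
        if mono.any():
            sub = sub.subset_snps(np.flatnonzero(~mono))
        grm = build_grm(sub)
        results.append(_h2_with_se(y, X, grm.values))
    (h1, s1), (h2_, s2), (hf, sf) = results
    delta = (h1 + h2_) - hf
    delta_se = float(np.sqrt(s1**2 + s2**2 + sf**2))
    return InflationResult(
        h2_half1=h1,
        h2_half2=h2_,
        h2_full=hf,
        se_half1=s1,
        se_half2=s2,
        se_full=sf,
        delta=float(delta),
        delta_se=delta_se,
        split_rule=split_rule,
    )


def pc_sensitivity(
    data: DyadDataset,
    n_pcs_grid=(0, 10, 20, 50),
    offspring_trait_is_birthweight: bool = False,
) -> pd.DataFrame:
    """Refit the covariance partition over a grid of ancestry PC counts.

    Returns one row per feasible grid point with cov_g, cov_p, ratio and
    the AI-based SE of cov_g; infeasible points (more PCs than available,
    or a design too wide for n) are skipped with a warning.
    """
    import warnings

    rows = []
    max_pcs = 0 if data.pcs is None else data.pcs.scores.shape[1]
    cov_p = sample_covariance(data.y1, data.y2)
    for k in n_pcs_grid:
        if k > max_pcs or data.n < 2 * (k + 4) + 6:
            warnings.warn(f"skipping infeasible PC count {k}")
            continue
        design = build_design_pair(
            data.dyads, data.pcs if k > 0 else None,
            offspring_trait_is_birthweight, n_pcs=k,
        )
        vc = BivariateGREML.from_design_pair(data.y1, data.y2, design, data.grm).fit()
        se_covg = float(np.sqrt(abs(vc.sampling_cov[1, 1])))
        rows.append(
            {
                "n_pcs": k,
                "cov_p": cov_p,
                "cov_g": vc.sigma_g12,
                "cov_g_se": se_covg,
                "ratio": vc.sigma_g12 / cov_p,
                "converged": vc.converged,
            }
        )
    return pd.DataFrame(rows)


__all__ = ["InflationResult", "half_genome_test", "split_snps", "pc_sensitivity"]
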