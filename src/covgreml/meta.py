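"""Cross-cohort synthesis: DerSimonian-Laird random effects and pooled IPD.

Two routes are provided, mirroring standard practice:

* one-stage pooled IPD — merge individual dyads from all cohorts, apply the
  pooled pipeline (shared SNP set, pooled relatedness pruning and PCA,
  cohort fixed effects, pooled standardization) and fit a single model;
* two-stage — fit per cohort, then combine the per-cohort estimates with
  the DerSimonian-Laird moment estimator of between-study heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .jackknife import JackknifeEstimate, jackknife
from .panel import GenotypePanel
from .partition import CovariancePartition
from .pipeline import DyadDataset, ratio_statistic


@dataclass
class MetaResult:
    """DerSimonian-Laird random-effects meta-analysis of k study estimates."""

    estimates: np.ndarray
    ses: np.ndarray
    q_statistic: float
    tau2: float
    weights: np.ndarray  # random-effects weights 1 / (se^2 + tau2)
    pooled: float
    pooled_se: float
    ci_low: float
    ci_high: float


def dl_random_effects(estimates, ses) -> MetaResult:
    """DerSimonian-Laird estimator.

    Fixed weights w_i = 1/se_i^2 give Cochran's Q; tau^2 = max(0,
    (Q - (k-1)) / (sum w - sum w^2 / sum w)); random-effects weights
    1/(se_i^2 + tau^2) give the pooled estimate and its SE; the CI is the
    usual +/- 1.96 * SE.
    """
    theta = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    k = theta.size
    if k < 2:
        raise ValueError(
            "meta-analysis needs at least 2 studies; report the single study directly"
        )
    if np.any(se <= 0):
        raise ValueError("all study SEs must be positive")
    w = 1.0 / se**2
    theta_fixed = np.sum(w * theta) / np.sum(w)
    q = float(np.sum(w * (theta - theta_fixed) ** 2))
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - (k - 1)) / denom)
    w_star = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(w_star * theta) / np.sum(w_star))
    pooled_se = float(np.sqrt(1.0 / np.sum(w_star)))
    return MetaResult(
        estimates=theta,
        ses=se,
        q_statistic=q,
        tau2=float(tau2),
        weights=w_star,
        pooled=pooled,
        pooled_se=pooled_se,
        ci_low=pooled - 1.96 * pooled_se,
        ci_high=pooled + 1.96 * pooled_se,
    )


@dataclass
class PooledIPDResult:
    """Pooled one-stage result plus the two-stage sensitivity comparison."""

    pooled_data: DyadDataset = field(repr=False)
    partition: CovariancePartition
    ratio_jackknife: JackknifeEstimate
    per_cohort: pd.DataFrame
    dl_ratio: MetaResult | None


def pooled_ipd_analysis(
    cohort_datasets: list[tuple[GenotypePanel, pd.DataFrame]],
    n_pcs: int = 20,
    rel_threshold: float | None = 0.05,
    scheme="block:20",
    seed: int = 0,
    offspring_trait_is_birthweight: bool = False,
) -> PooledIPDResult:
    """One-stage pooled IPD analysis across cohorts, plus the two-stage route.

    All cohorts must share an identical post-QC SNP set.  Dyads are merged,
    phenotypes standardized on the merged data, relatedness pruning and PCA
    run on the pooled GRM, and cohort enters the fixed effects.  The
    per-cohort fits feed a DerSimonian-Laird random-effects model for the
    Cov_G : Cov_P ratio as the sensitivity comparison (skipped for a single
    cohort, where the pooled result is the plain pipeline output).
    """
    if not cohort_datasets:
        raise ValueError("no cohorts supplied")
    ref_ids = list(cohort_datasets[0][0].snps["snp_id"])
    for panel, _ in cohort_datasets[1:]:
        ids = list(panel.snps["snp_id"])
        if ids != ref_ids:
            diff = sorted(set(ids) ^ set(ref_ids))
            raise ValueError(f"cohort SNP sets differ; symmetric difference: {diff}")

    merged_calls = np.vstack([p.calls for p, _ in cohort_datasets])
    merged_ids: list[str] = []
    tables = []
    for i, (panel, dyads) in enumerate(cohort_datasets):
        merged_ids.extend(panel.sample_ids)
        t = dyads.copy()
        if "cohort" not in t.columns or len(cohort_datasets) > 1:
            t["cohort"] = f"cohort{i + 1}"
        tables.append(t)
    merged_panel = GenotypePanel(
        merged_ids, cohort_datasets[0][0].snps.copy(), merged_calls
    ).with_recomputed_metadata()
    merged_dyads = pd.concat(tables, ignore_index=True)

    pooled_data = DyadDataset.from_panel(
        merged_panel,
        merged_dyads,
        n_pcs=n_pcs,
        rel_threshold=rel_threshold,
        offspring_trait_is_birthweight=offspring_trait_is_birthweight,
        seed=seed,
    )
    part = pooled_data.run_partition()
    ratio_jk = jackknife(
        lambda idx: ratio_statistic(pooled_data, idx),
        n=pooled_data.n,
        scheme=scheme,
        seed=seed,
    )

    rows = []
    for i, (panel, dyads) in enumerate(cohort_datasets):
        data = DyadDataset.from_panel(
            panel,
            dyads,
            n_pcs=min(n_pcs, max(0, len(dyads) // 4)),
            rel_threshold=rel_threshold,
            offspring_trait_is_birthweight=offspring_trait_is_birthweight,
            seed=seed + i + 1,
        )
        jk = jackknife(
            lambda idx: ratio_statistic(data, idx),
            n=data.n,
            scheme=scheme,
            seed=seed + i + 1,
        )
        p = data.run_partition()
        rows.append(
            {
                "cohort": f"cohort{i + 1}",
                "n": data.n,
                "cov_p": p.cov_p,
                "cov_g": p.cov_g,
                "ratio": jk.point,
                "ratio_se": jk.se,
            }
        )
    per_cohort = pd.DataFrame(rows)
    dl = (
        dl_random_effects(per_cohort["ratio"], per_cohort["ratio_se"])
        if len(per_cohort) >= 2
        else None
    )
    return PooledIPDResult(
        pooled_data=pooled_data,
        partition=part,
        ratio_jackknife=ratio_jk,
        per_cohort=per_cohort,
        dl_ratio=dl,
    )


__all__ = ["MetaResult", "dl_random_effects", "PooledIPDResult", "pooled_ipd_analysis"]
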