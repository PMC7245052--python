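"""End-to-end assembly: QC -> GRM -> pruning -> PCs -> fit -> partition.

:class:`DyadDataset` bundles the aligned pieces of one analysis (genotype
panel, dyad table with standardized traits, GRM, ancestry PCs and the
fixed-effect design pair) and is the unit that the jackknife, meta-analysis
and diagnostics operate on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grm import AncestryPCs, GRMatrix, build_grm, grm_pca, prune_related
from .greml import BivariateGREML, GREMLOptions, GREMLResults
from .panel import GenotypePanel
from .partition import CovariancePartition, partition, sample_covariance
from .phenotypes import DesignPair, build_design_pair, standardize
from .qc import FilterReport, filter_snps


@dataclass
class DyadDataset:
    """One analysis-ready mother-offspring dyad dataset."""

    dyads: pd.DataFrame
    y1: np.ndarray = field(repr=False)
    y2: np.ndarray = field(repr=False)
    grm: GRMatrix = field(repr=False)
    design: DesignPair = field(repr=False)
    pcs: AncestryPCs | None = field(default=None, repr=False)
    panel: GenotypePanel | None = field(default=None, repr=False)
    filter_report: FilterReport | None = None
    _full_fit: GREMLResults | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return len(self.y1)

    @classmethod
    def from_panel(
        cls,
        panel: GenotypePanel,
        dyads: pd.DataFrame,
        n_pcs: int = 20,
        maf_min: float = 0.01,
        info_min: float = 0.3,
        hwe_p_min: float = 1e-6,
        rel_threshold: float | None = 0.05,
        offspring_trait_is_birthweight: bool = False,
        standardize_traits: bool = True,
        seed: int = 0,
    ) -> "DyadDataset":
        """Run the standard pipeline: SNP QC, GRM, relatedness pruning,
        GRM PCA, pooled standardization and design assembly."""
        filtered, report = filter_snps(panel, maf_min, info_min, hwe_p_min)
        grm = build_grm(filtered)
        table = dyads.copy().reset_index(drop=True)
        if rel_threshold is not None:
            retained = prune_related(grm, threshold=rel_threshold, seed=seed)
            keep = set(retained)
            table = table[table["dyad_id"].astype(str).isin(keep)].reset_index(drop=True)
        grm = grm.align_to(list(table["dyad_id"].astype(str)))
        pcs = grm_pca(grm, k=n_pcs) if n_pcs > 0 else None
        y1 = np.asarray(table["y1"], dtype=float)
        y2 = np.asarray(table["y2"], dtype=float)
        if standardize_traits:
            y1 = standardize(y1)
            y2 = standardize(y2)
        design = build_design_pair(
            table, pcs, offspring_trait_is_birthweight, n_pcs=n_pcs
        )
        return cls(
            dyads=table,
            y1=y1,
            y2=y2,
            grm=grm,
            design=design,
            pcs=pcs,
            panel=filtered,
            filter_report=report,
        )

    def full_fit(self, options: GREMLOptions | None = None) -> GREMLResults:
        """Bivariate fit on the full dataset (cached)."""
        if self._full_fit is None:
            model = BivariateGREML.from_design_pair(self.y1, self.y2, self.design, self.grm)
            self._full_fit = model.fit(options=options)
        return self._full_fit

    def run_partition(self, options: GREMLOptions | None = None) -> CovariancePartition:
        vc = self.full_fit(options)
        return partition(vc, sample_covariance(self.y1, self.y2))


def fit_on_subset(
    data: DyadDataset, idx: np.ndarray, warm_start: bool = True
) -> GREMLResults:
    """Refit the bivariate model on a dyad subset (GRM rows/columns
    dropped), warm-starting from the full-data optimum by default."""
    idx = np.asarray(idx)
    model = BivariateGREML(
        data.y1[idx],
        data.y2[idx],
        data.grm.values[np.ix_(idx, idx)],
        X1=data.design.X1[idx],
        X2=data.design.X2[idx],
    )
    start = data.full_fit().params if warm_start else None
    return model.fit(start=start)


def ratio_statistic(data: DyadDataset, idx: np.ndarray, warm_start: bool = True) -> float:
    """Cov_G : Cov_P on a dyad subset — the jackknifed pipeline statistic."""
    idx = np.asarray(idx)
    vc = fit_on_subset(data, idx, warm_start=warm_start)
    cov_p = sample_covariance(data.y1[idx], data.y2[idx])
    return float(vc.sigma_g12 / cov_p)


def covg_statistic(data: DyadDataset, idx: np.ndarray, warm_start: bool = True) -> float:
    """Cov_G (sigma_g12) on a dyad subset."""
    return float(fit_on_subset(data, np.asarray(idx), warm_start=warm_start).sigma_g12)


def covp_statistic(data: DyadDataset, idx: np.ndarray) -> float:
    """Cov_P (sample covariance) on a dyad subset."""
    idx = np.asarray(idx)
    return sample_covariance(data.y1[idx], data.y2[idx])


__all__ = [
    "DyadDataset",
    "fit_on_subset",
    "ratio_statistic",
    "covg_statistic",
    "covp_statistic",
]
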