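"""SNP- and sample-level quality control.

Implements the QC applied before relatedness estimation: hard-calling of
genotype probabilities, the Hardy-Weinberg exact test, marker filtering on
minor allele frequency / imputation quality / HWE, and the dyad-level sample
exclusions (flagged records, one random member per sibling group, complete
cases on the trait pair).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .panel import MISSING, GenotypePanel

#: Marker filter defaults: MAF > 0.01, imputation info r^2 > 0.3, HWE P > 1e-6.
DEFAULT_MAF_MIN = 0.01
DEFAULT_INFO_MIN = 0.3
DEFAULT_HWE_P_MIN = 1e-6


def hard_call(probs: tuple[float, float, float] | np.ndarray) -> int:
    """Best-guess genotype from a (P0, P1, P2) probability triple.

    Returns the index of the largest probability; ties break toward the
    lower genotype index so the call is deterministic.
    """
    p = np.asarray(probs, dtype=float)
    if p.shape != (3,):
        raise ValueError("expected a (P0, P1, P2) triple")
    if (p < 0).any():
        raise ValueError("genotype probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"genotype probabilities sum to {p.sum():.8f}, not 1")
    return int(np.argmax(p))  # argmax takes the first maximum -> lower index


def hwe_exact_p(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums, over all heterozygote
    counts of matching parity, the probabilities of configurations no more
    probable than the observed one (two-sided by probability mass).
    Symmetric in ``n_hom1`` / ``n_hom2``; monomorphic markers return 1.
    """
    for c in (n_hom1, n_het, n_hom2):
        if c < 0 or int(c) != c:
            raise ValueError("genotype counts must be non-negative integers")
    n = n_hom1 + n_het + n_hom2
    if n < 1:
        raise ValueError("at least one individual required")
    n_rare = min(2 * n_hom1 + n_het, 2 * n_hom2 + n_het)
    if n_rare == 0:
        return 1.0
    # P(het = h | allele counts) via log-gamma; h runs over the parity class
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    rare_hom = (n_rare - hets) // 2
    common_hom = n - hets - rare_hom
    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(rare_hom + 1)
        - gammaln(common_hom + 1)
        + hets * np.log(2.0)
        + gammaln(n_rare + 1)
        + gammaln(2 * n - n_rare + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[hets == n_het][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


@dataclass
class FilterReport:
    """Retained/dropped counts from a marker filtering pass."""

    n_input: int
    n_retained: int
    n_dropped_maf: int
    n_dropped_info: int
    n_dropped_hwe: int

    def log_lines(self) -> list[str]:
        return [
            f"filter_snps input={self.n_input}",
            f"filter_snps dropped_maf={self.n_dropped_maf}",
            f"filter_snps dropped_info={self.n_dropped_info}",
            f"filter_snps dropped_hwe={self.n_dropped_hwe}",
            f"filter_snps retained={self.n_retained}",
        ]


def filter_snps(
    panel: GenotypePanel,
    maf_min: float = DEFAULT_MAF_MIN,
    info_min: float = DEFAULT_INFO_MIN,
    hwe_p_min: float = DEFAULT_HWE_P_MIN,
) -> tuple[GenotypePanel, FilterReport]:
    """Retain SNPs with maf > ``maf_min``, info r^2 > ``info_min`` (absent
    info passes: the SNP is treated as directly genotyped) and HWE
    p > ``hwe_p_min``.  SNP order is preserved.
    """
    if not (0 <= maf_min < 0.5 and 0 <= info_min <= 1 and 0 <= hwe_p_min < 1):
        raise ValueError("filter thresholds out of range")
    snps = panel.snps
    pass_maf = snps["maf"].to_numpy() > maf_min
    info = snps["info_r2"].to_numpy()
    pass_info = np.isnan(info) | (info > info_min)
    pass_hwe = snps["hwe_p"].to_numpy() > hwe_p_min
    keep = pass_maf & pass_info & pass_hwe
    report = FilterReport(
        n_input=panel.n_snps,
        n_retained=int(keep.sum()),
        n_dropped_maf=int((~pass_maf).sum()),
        n_dropped_info=int((~pass_info).sum()),
        n_dropped_hwe=int((~pass_hwe).sum()),
    )
    if report.n_retained == 0:
        raise ValueError("no SNPs survive filtering")
    return panel.subset_snps(np.flatnonzero(keep)), report


def apply_sample_exclusions(
    panel: GenotypePanel,
    dyads: pd.DataFrame,
    sibling_groups: list[list[str]] | None = None,
    flags: list[str] | None = None,
    seed: int = 0,
) -> tuple[GenotypePanel, pd.DataFrame]:
    """Apply dyad-level exclusions before analysis.

    Drops dyads flagged for exclusion (stillbirth / multiple-birth
    analogues), keeps exactly one member of each sibling group by a seeded
    uniform draw, then restricts to complete cases on the trait pair
    (``y1``, ``y2``).  Panel and table stay aligned on ``dyad_id``.
    """
    ids = list(dyads["dyad_id"].astype(str))
    panel_ids = set(panel.sample_ids)
    missing_ids = [i for i in ids if i not in panel_ids]
    if missing_ids:
        raise ValueError(f"dyad ids absent from genotype panel: {missing_ids}")

    rng = np.random.default_rng(seed)
    drop: set[str] = set(str(f) for f in (flags or []))
    for group in sibling_groups or []:
        group = [str(g) for g in group if str(g) not in drop]
        if len(group) > 1:
            keep_one = group[rng.integers(len(group))]
            drop.update(g for g in group if g != keep_one)

    table = dyads[~dyads["dyad_id"].astype(str).isin(drop)].copy()
    table = table.dropna(subset=["y1", "y2"]).reset_index(drop=True)
    keep_ids = list(table["dyad_id"].astype(str))
    pos = {s: i for i, s in enumerate(panel.sample_ids)}
    idx = np.array([pos[i] for i in keep_ids], dtype=int)
    return panel.subset_samples(idx), table


__all__ = [
    "hard_call",
    "hwe_exact_p",
    "filter_snps",
    "FilterReport",
    "apply_sample_exclusions",
    "MISSING",
]
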