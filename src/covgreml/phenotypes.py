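"""Phenotype cleaning, transformation, standardization and fixed-effect designs.

The analysis pipeline is: mark physiologically implausible values missing,
optionally transform (natural log or rank-based inverse-normal), standardize
to mean 0 / variance 1 over the pooled sample, then restrict to complete
cases per trait pair.  With standardized traits the phenotypic covariance of
a dyad pair equals their Pearson correlation, which is what makes covariance
components comparable across offspring phenotypes measured in different
units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from .grm import AncestryPCs

#: Default plausibility windows (configurable): maternal BMI and offspring BMI in
#: kg/m^2, birth weight in grams.
DEFAULT_BOUNDS = {
    "maternal_bmi": (13.0, 60.0),
    "offspring_bmi": (8.0, 60.0),
    "birth_weight": (200.0, 6500.0),
}


def mark_implausible(
    values: np.ndarray | pd.Series, lower_bound: float, upper_bound: float
) -> tuple[np.ndarray, int]:
    """Set values strictly outside [lower, upper] to NaN; return the new array
    and the number of values changed."""
    if not lower_bound < upper_bound:
        raise ValueError("lower bound must be below upper bound")
    out = np.asarray(values, dtype=float).copy()
    bad = (out < lower_bound) | (out > upper_bound)
    bad &= ~np.isnan(out)
    out[bad] = np.nan
    return out, int(bad.sum())


def standardize(values: np.ndarray | pd.Series) -> np.ndarray:
    """Z-score over the pooled non-missing sample: (x - mean) / sd, sd with
    the n-1 denominator.  Missing values are preserved as NaN."""
    out = np.asarray(values, dtype=float).copy()
    obs = out[~np.isnan(out)]
    if obs.size < 2:
        raise ValueError("need at least 2 non-missing values to standardize")
    sd = obs.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (out - obs.mean()) / sd


def transform(values: np.ndarray | pd.Series, method: str) -> np.ndarray:
    """Normalizing transformation applied before standardization.

    ``rank_inverse_normal`` maps the (average, for ties) rank r of n
    non-missing values to the standard-normal quantile at
    (r - 3/8) / (n + 1/4) (the Blom offset); ``natural_log`` is elementwise
    and requires strictly positive input.
    """
    out = np.asarray(values, dtype=float).copy()
    obs_mask = ~np.isnan(out)
    if method == "natural_log":
        nonpos = np.flatnonzero(obs_mask & (out <= 0))
        if nonpos.size:
            raise ValueError(
                f"natural_log requires positive values; offending rows: {nonpos.tolist()}"
            )
        out[obs_mask] = np.log(out[obs_mask])
        return out
    if method == "rank_inverse_normal":
        obs = out[obs_mask]
        ranks = rankdata(obs, method="average")
        out[obs_mask] = ndtri((ranks - 0.375) / (obs.size + 0.25))
        return out
    raise ValueError(f"unknown transform {method!r}")


@dataclass
class DesignPair:
    """Fixed-effect design matrices for the offspring (X1) and maternal (X2)
    traits of a dyad analysis, both including an intercept."""

    X1: np.ndarray = field(repr=False)
    X2: np.ndarray = field(repr=False)
    labels1: list[str] = field(default_factory=list)
    labels2: list[str] = field(default_factory=list)


def _drop_rank_deficient(X: np.ndarray, labels: list[str]) -> tuple[np.ndarray, list[str]]:
    keep: list[int] = []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand) == len(keep) + 1:
            keep.append(j)
    if len(keep) < X.shape[1]:
        dropped = [labels[j] for j in range(X.shape[1]) if j not in keep]
        import warnings

        warnings.warn(f"dropping rank-deficient design columns: {dropped}")
    return X[:, keep], [labels[j] for j in keep]


def build_design_pair(
    dyads: pd.DataFrame,
    pcs: AncestryPCs | None,
    offspring_trait_is_birthweight: bool = False,
    n_pcs: int = 20,
) -> DesignPair:
    """Assemble the two fixed-effect matrices of the bivariate model.

    The offspring-trait design X1 carries intercept, cohort dummies
    (reference level dropped), offspring sex, age at measurement — replaced
    by gestational age at birth for birth-weight models — and the leading
    ancestry PCs.  The maternal-trait design X2 carries intercept, cohort
    dummies and the PCs (sex and measurement age are offspring covariates).
    """
    n = len(dyads)
    ids = list(dyads["dyad_id"].astype(str))
    if pcs is not None:
        if list(map(str, pcs.sample_ids)) != ids:
            raise ValueError("ancestry PCs are not aligned to the dyad table")
        if n_pcs > pcs.scores.shape[1]:
            raise ValueError(f"requested {n_pcs} PCs, only {pcs.scores.shape[1]} available")
        pc_block = pcs.scores[:, :n_pcs]
    else:
        if n_pcs > 0:
            raise ValueError("n_pcs > 0 requires ancestry PCs")
        pc_block = np.empty((n, 0))
    pc_labels = [f"PC{i + 1}" for i in range(pc_block.shape[1])]

    cohorts = pd.Categorical(dyads["cohort"])
    cohort_dummies = pd.get_dummies(cohorts, drop_first=True, dtype=float)
    cohort_block = cohort_dummies.to_numpy()
    cohort_labels = [f"cohort[{c}]" for c in cohort_dummies.columns]

    intercept = np.ones((n, 1))
    sex = np.asarray(dyads["sex"], dtype=float)[:, None]
    if offspring_trait_is_birthweight:
        age = np.asarray(dyads["gestage"], dtype=float)[:, None]
        age_label = "gestational_age"
    else:
        age = np.asarray(dyads["age"], dtype=float)[:, None]
        age_label = "age_at_measurement"

    X1 = np.hstack([intercept, cohort_block, sex, age, pc_block])
    labels1 = ["intercept"] + cohort_labels + ["sex", age_label] + pc_labels
    X2 = np.hstack([intercept, cohort_block, pc_block])
    labels2 = ["intercept"] + cohort_labels + pc_labels
    X1, labels1 = _drop_rank_deficient(X1, labels1)
    X2, labels2 = _drop_rank_deficient(X2, labels2)
    return DesignPair(X1=X1, X2=X2, labels1=labels1, labels2=labels2)


def prevalence_ci(p_hat: float, n: int) -> tuple[float, float]:
    """95% Wald interval for a prevalence, in percent.

    Returns 100 * (p +/- 1.96 * sqrt(p (1 - p) / n)).
    """
    if not 0 < p_hat < 1:
        raise ValueError("p_hat must lie strictly between 0 and 1")
    if n < 1:
        raise ValueError("n must be at least 1")
    half = 1.96 * np.sqrt(p_hat * (1 - p_hat) / n)
    return 100 * (p_hat - half), 100 * (p_hat + half)


__all__ = [
    "mark_implausible",
    "standardize",
    "transform",
    "DesignPair",
    "build_design_pair",
    "prevalence_ci",
    "DEFAULT_BOUNDS",
]
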