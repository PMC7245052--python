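"""Jackknife standard errors, confidence intervals and the coverage check.

The leave-one-out (loo) jackknife deletes one dyad at a time and reruns the
full statistic (for the covariance partition that means subsetting the GRM
rows/columns and refitting the model); the delete-a-block variant
(``block(b)``) deletes one of b seeded-random blocks at a time, which keeps
the number of refits at b rather than n.  Confidence intervals are the
point estimate +/- 1.96 * SE throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

#: Replicate-failure fraction above which the estimate carries a warning flag.
MAX_FAILURE_FRACTION = 0.05


@dataclass
class JackknifeEstimate:
    """Point estimate with jackknife SE and 95% CI."""

    point: float
    se: float
    ci_low: float
    ci_high: float
    n_replicates: int
    scheme: str
    n_failed: int = 0
    unreliable: bool = False  # > 5% of replicates failed


def parse_scheme(scheme) -> tuple[str, int | None]:
    """Normalize a scheme spec: 'loo', 'block:B', or ('block', B)."""
    if scheme == "loo":
        return "loo", None
    if isinstance(scheme, (tuple, list)) and scheme[0] == "block":
        kind, b = "block", int(scheme[1])
    elif isinstance(scheme, str) and scheme.startswith("block"):
        kind, b = "block", int(scheme.split(":")[1])
    else:
        raise ValueError(f"unknown jackknife scheme {scheme!r}")
    if b < 2:
        raise ValueError("block jackknife needs at least 2 blocks")
    return kind, b


def jackknife(
    statistic_fn: Callable[[np.ndarray], float],
    n: int,
    scheme="loo",
    seed: int = 0,
) -> JackknifeEstimate:
    """Jackknife a statistic over n dyads.

    ``statistic_fn`` receives an integer index array of retained dyads and
    returns a scalar; it is called once with all indices for the point
    estimate and once per deletion replicate.  Delete-d variance:
    (n - d) / (d * g) * sum_j (theta_(j) - theta_bar)^2 over the g
    replicates, which reduces to the familiar (n-1)/n * sum for loo.
    Replicates that raise or return non-finite values are excluded and
    counted; more than 5% failures flags the estimate unreliable.
    """
    kind, b = parse_scheme(scheme)
    all_idx = np.arange(n)
    point = float(statistic_fn(all_idx))

    if kind == "loo":
        delete_sets = [np.array([i]) for i in range(n)]
        scheme_name = "loo"
    else:
        perm = np.random.default_rng(seed).permutation(n)
        delete_sets = [np.sort(chunk) for chunk in np.array_split(perm, b)]
        scheme_name = f"block({b})"

    reps = []
    n_failed = 0
    for dset in delete_sets:
        keep = np.setdiff1d(all_idx, dset, assume_unique=True)
        try:
            value = float(statistic_fn(keep))
        except Exception:
            value = float("nan")
        if np.isfinite(value):
            reps.append(value)
        else:
            n_failed += 1
    reps = np.asarray(reps)
    g = reps.size
    if g < 2:
        raise ValueError("too few successful jackknife replicates")
    d = n / len(delete_sets)  # average deletion size
    var = (n - d) / (d * g) * np.sum((reps - reps.mean()) ** 2)
    se = float(np.sqrt(var))
    return JackknifeEstimate(
        point=point,
        se=se,
        ci_low=point - 1.96 * se,
        ci_high=point + 1.96 * se,
        n_replicates=g,
        scheme=scheme_name,
        n_failed=n_failed,
        unreliable=n_failed > MAX_FAILURE_FRACTION * len(delete_sets),
    )


@dataclass
class CoverageResult:
    """Empirical CI coverage for the Cov_G : Cov_P ratio."""

    coverage: float
    coverage_se: float  # binomial SE
    n_replicates: int
    true_ratio: float
    mean_ci_width: float


def coverage_simulation(
    theta_true,
    n_dyads: int,
    n_snps: int,
    n_replicates: int,
    scheme="block:20",
    seed: int = 0,
) -> CoverageResult:
    """Monte-Carlo check that jackknife 95% CIs for the covariance ratio
    cover the true ratio at close to nominal rate.

    Each replicate simulates a model-mode dataset, builds the GRM, fits the
    bivariate model (intercept-plus-cohort fixed effects), forms the
    jackknife CI for Cov_G : Cov_P and records whether the true ratio
    sigma_g12 / (sigma_g12 + sigma_e12) falls inside.
    """
    from .pipeline import DyadDataset, ratio_statistic
    from .simulate import simulate_model_mode

    theta = np.asarray(theta_true, dtype=float)
    true_cov_p = theta[1] + theta[4]
    if true_cov_p == 0:
        raise ValueError("true ratio undefined: sigma_g12 + sigma_e12 is zero")
    true_ratio = theta[1] / true_cov_p

    rng = np.random.default_rng(seed)
    hits = 0
    widths = []
    for _ in range(n_replicates):
        rep_seed = int(rng.integers(2**31 - 1))
        panel, dyads, _ = simulate_model_mode(
            n_dyads, n_snps, theta, seed=rep_seed
        )
        # dyads are unrelated by construction; the relatedness prune is for
        # real panels whose GRM noise sits well below the 0.05 threshold
        data = DyadDataset.from_panel(panel, dyads, n_pcs=0, rel_threshold=None)
        est = jackknife(
            lambda idx: ratio_statistic(data, idx),
            n=data.n,
            scheme=scheme,
            seed=rep_seed,
        )
        hits += int(est.ci_low <= true_ratio <= est.ci_high)
        widths.append(est.ci_high - est.ci_low)
    coverage = hits / n_replicates
    return CoverageResult(
        coverage=coverage,
        coverage_se=float(np.sqrt(coverage * (1 - coverage) / n_replicates)),
        n_replicates=n_replicates,
        true_ratio=float(true_ratio),
        mean_ci_width=float(np.mean(widths)),
    )


__all__ = [
    "JackknifeEstimate",
    "jackknife",
    "parse_scheme",
    "CoverageResult",
    "coverage_simulation",
]
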