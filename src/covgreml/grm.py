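"""Genetic relatedness matrix construction, GCTA binary interop, cryptic
relatedness pruning and ancestry principal components.

The GRM entry for individuals j and k is

    A_jk = (1/m_jk) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))

over the m_jk SNPs non-missing in both individuals, with p_i the sample
allele1 frequency.  Under Hardy-Weinberg equilibrium the expected diagonal
is 1 and the expected off-diagonal for unrelated pairs is 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel


@dataclass
class GRMatrix:
    """Symmetric SNP-based relatedness matrix with per-pair SNP counts."""

    sample_ids: list[str]
    values: np.ndarray = field(repr=False)
    pair_snp_counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("GRM shape does not match sample ids")
        if not np.array_equal(self.values, self.values.T):
            raise ValueError("GRM must be exactly symmetric")
        if not np.isfinite(self.values).all():
            raise ValueError("GRM contains non-finite entries")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def subset(self, index: np.ndarray) -> "GRMatrix":
        index = np.asarray(index)
        return GRMatrix(
            sample_ids=[self.sample_ids[i] for i in index],
            values=self.values[np.ix_(index, index)].copy(),
            pair_snp_counts=self.pair_snp_counts[np.ix_(index, index)].copy(),
        )

    def align_to(self, ids: list[str]) -> "GRMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            idx = np.array([pos[str(i)] for i in ids], dtype=int)
        except KeyError as err:
            raise KeyError(f"sample {err} not present in GRM") from err
        return self.subset(idx)


@dataclass
class AncestryPCs:
    """Top-k eigenvectors of the GRM, used as ancestry covariates."""

    sample_ids: list[str]
    scores: np.ndarray = field(repr=False)  # (n, k), eigenvalue order
    eigenvalues: np.ndarray = field(repr=False)  # (k,), non-increasing


def build_grm(panel: GenotypePanel) -> GRMatrix:
    """Build the GRM from hard calls with pairwise-complete missing handling."""
    if panel.n_samples < 2 or panel.n_snps < 1:
        raise ValueError("need at least 2 samples and 1 SNP")
    calls = panel.calls.astype(float)
    mask = panel.calls != MISSING
    calls[~mask] = np.nan
    p = np.nanmean(calls, axis=0) / 2.0
    if np.any((p <= 0) | (p >= 1)):
        bad = panel.snps["snp_id"][np.flatnonzero((p <= 0) | (p >= 1))].tolist()
        raise ValueError(f"monomorphic SNPs cannot be scaled: {bad}")
    w = (calls - 2 * p) / np.sqrt(2 * p * (1 - p))
    w[~mask] = 0.0
    m = mask.astype(float)
    counts = m @ m.T
    if np.any(counts < 1):
        raise ValueError("some sample pair shares no genotyped SNP")
    values = (w @ w.T) / counts
    values = (values + values.T) / 2.0  # enforce exact symmetry
    return GRMatrix(list(panel.sample_ids), values, counts.astype(np.int64))


def write_grm_gcta(grm: GRMatrix, prefix: str | Path) -> None:
    """Write the GCTA binary triplet prefix.grm.bin / .grm.N.bin / .grm.id.

    Both binaries are little-endian float32, lower triangle including the
    diagonal, in row-major order: (0,0), (1,0), (1,1), (2,0), ...
    """
    prefix = str(prefix)
    n = grm.n
    tri = np.tril_indices(n)
    grm.values[tri].astype("<f4").tofile(prefix + ".grm.bin")
    grm.pair_snp_counts[tri].astype("<f4").tofile(prefix + ".grm.N.bin")
    pd.DataFrame({"fid": grm.sample_ids, "iid": grm.sample_ids}).to_csv(
        prefix + ".grm.id", sep="\t", header=False, index=False
    )


def read_grm_gcta(prefix: str | Path) -> GRMatrix:
    """Read a GCTA binary GRM triplet written by :func:`write_grm_gcta` or GCTA."""
    prefix = str(prefix)
    ids = pd.read_csv(
        prefix + ".grm.id", sep=r"\s+", header=None, names=["fid", "iid"], dtype=str
    )
    n = len(ids)
    n_elem = n * (n + 1) // 2
    lower = np.fromfile(prefix + ".grm.bin", dtype="<f4")
    if lower.size != n_elem:
        raise ValueError(
            f"{prefix}.grm.bin holds {lower.size} float32 values, "
            f"expected n(n+1)/2 = {n_elem} for n = {n}"
        )
    counts = np.fromfile(prefix + ".grm.N.bin", dtype="<f4")
    if counts.size != n_elem:
        raise ValueError(f"{prefix}.grm.N.bin has wrong element count")
    values = np.zeros((n, n))
    nmat = np.zeros((n, n))
    tri = np.tril_indices(n)
    values[tri] = lower
    nmat[tri] = counts
    values = values + np.tril(values, -1).T
    nmat = nmat + np.tril(nmat, -1).T
    return GRMatrix(list(ids["iid"]), values, np.round(nmat).astype(np.int64))


def prune_related(grm: GRMatrix, threshold: float = 0.05, seed: int = 0) -> list[str]:
    """Greedily remove individuals until no pair exceeds the relatedness threshold.

    Repeatedly drops the individual with the largest number of over-threshold
    partners (seeded uniform tie-break), so pairs sharing a "hub" relative
    lose only the hub.  Returns the retained sample ids in original order.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    rng = np.random.default_rng(seed)
    n = grm.n
    over = grm.values > threshold
    np.fill_diagonal(over, False)
    active = np.ones(n, dtype=bool)
    degree = over.sum(axis=1)
    while True:
        deg_active = np.where(active, degree, -1)
        max_deg = deg_active.max()
        if max_deg <= 0:
            break
        candidates = np.flatnonzero(deg_active == max_deg)
        victim = int(rng.choice(candidates))
        active[victim] = False
        partners = np.flatnonzero(over[victim] & active)
        degree[partners] -= 1
        degree[victim] = 0
    return [grm.sample_ids[i] for i in np.flatnonzero(active)]


def grm_pca(grm: GRMatrix, k: int = 20) -> AncestryPCs:
    """Top-k eigenvectors of the GRM, in non-increasing eigenvalue order."""
    if k > grm.n:
        raise ValueError(f"k = {k} exceeds sample size {grm.n}")
    if not np.allclose(grm.values, grm.values.T):
        raise ValueError("GRM must be symmetric for PCA")
    eigenvalues, eigenvectors = np.linalg.eigh(grm.values)
    order = np.argsort(eigenvalues)[::-1][:k]
    return AncestryPCs(
        sample_ids=list(grm.sample_ids),
        scores=eigenvectors[:, order].copy(),
        eigenvalues=eigenvalues[order].copy(),
    )


__all__ = [
    "GRMatrix",
    "AncestryPCs",
    "build_grm",
    "write_grm_gcta",
    "read_grm_gcta",
    "prune_related",
    "grm_pca",
]
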